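"""Sensitivity score γ and the perturbation protocols."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldcarb import (
    ConditionRealization,
    KineticParameters,
    PerturbationProtocol,
    SensitivityMatrix,
    find_steady_state,
    gamma_score,
    run_high_light_protocol,
    run_perturbation_sweep,
)
from coldcarb.kinetic_model import ValidationError
from coldcarb.sensitivity import MEASURES, _measure_values
from coldcarb.synthetic_data import BASE_PARAMETERS


def _literal_gamma(x0, xi, r0, ri):
    """Step-by-step reference: N-th root of the product of absolute
    log2 perturbation-normalized fold changes."""
    prod = 1.0
    for x, r in zip(xi, ri):
        prod *= abs(math.log2((x / x0) * (r0 / r)))
    return prod ** (1.0 / len(xi))


class TestGammaScore:
    def test_proportional_response_scores_zero(self):
        ri = [1.1, 0.9, 1.25]
        xi = [2.0 * r for r in ri]
        assert gamma_score(2.0, xi, 1.0, ri) == 0.0

    def test_single_doubling_scores_one(self):
        assert gamma_score(1.0, [2.0], 5.0, [5.0]) == pytest.approx(1.0)

    def test_geometric_mean_of_inner_terms(self):
        # inner |log2| terms 1 and 2 -> sqrt(2)
        assert gamma_score(1.0, [2.0, 4.0], 1.0, [1.0, 1.0]) == pytest.approx(
            math.sqrt(2.0))

    def test_matches_literal_product(self, rng):
        for _ in range(20):
            n = rng.integers(1, 15)
            x0, r0 = rng.uniform(0.1, 10, 2)
            xi = rng.uniform(0.1, 10, n)
            ri = rng.uniform(0.5, 2, n)
            expected = _literal_gamma(x0, xi, r0, ri)
            assert gamma_score(x0, xi, r0, ri) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_and_mismatched_inputs(self):
        with pytest.raises(ValidationError):
            gamma_score(0.0, [1.0], 1.0, [1.0])
        with pytest.raises(ValidationError):
            gamma_score(1.0, [1.0, -2.0], 1.0, [1.0, 1.0])
        with pytest.raises(ValidationError):
            gamma_score(1.0, [1.0, 2.0], 1.0, [1.0])
        with pytest.raises(ValidationError):
            gamma_score(1.0, [], 1.0, [])

    @given(st.permutations(list(range(6))))
    @settings(deadline=None, max_examples=25)
    def test_invariant_to_perturbation_order(self, perm):
        xi = np.array([1.2, 0.7, 2.3, 1.9, 0.4, 1.05])
        ri = np.array([1.05, 0.95, 1.1, 0.9, 1.2, 0.8])
        base = gamma_score(1.3, xi, 1.0, ri)
        assert gamma_score(1.3, xi[perm], 1.0, ri[perm]) == pytest.approx(
            base, rel=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0,
                     allow_nan=False, allow_infinity=False))
    @settings(deadline=None, max_examples=25)
    def test_invariant_to_common_rescaling_of_x(self, scale):
        xi = [1.2, 0.7, 2.3]
        ri = [1.05, 0.95, 1.1]
        base = gamma_score(1.3, xi, 1.0, ri)
        scaled = gamma_score(1.3 * scale, [x * scale for x in xi], 1.0, ri)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_doubling_log_fold_changes_doubles_gamma(self):
        x0, r0 = 1.3, 1.0
        xi = np.array([1.2, 0.7, 2.3])
        ri = np.array([1.05, 0.95, 1.1])
        base = gamma_score(x0, xi, r0, ri)
        # square each perturbation-normalized fold change in place
        xi2 = x0 * (ri / r0) * ((xi / x0) * (r0 / ri)) ** 2
        assert gamma_score(x0, xi2, r0, ri) == pytest.approx(2 * base, rel=1e-10)


class TestProtocol:
    def test_default_grid_is_plus_minus_five_to_thirty(self):
        proto = PerturbationProtocol()
        assert proto.n_perturbations == 12
        assert sorted(proto.relative_changes) == pytest.approx(
            [-0.30, -0.25, -0.20, -0.15, -0.10, -0.05,
             0.05, 0.10, 0.15, 0.20, 0.25, 0.30])

    def test_empty_and_degenerate_changes_rejected(self):
        with pytest.raises(ValidationError):
            PerturbationProtocol(relative_changes=())
        with pytest.raises(ValidationError):
            PerturbationProtocol(relative_changes=(-1.0,))
        with pytest.raises(ValidationError):
            PerturbationProtocol(pre_perturbation_time=4.0, total_time=2.0)

    def test_zero_change_warns_and_annihilates(self, base_realization):
        with pytest.warns(UserWarning, match="annihilates"):
            proto = PerturbationProtocol(relative_changes=(0.0, 0.1))
        res = run_perturbation_sweep(base_realization, proto)
        assert all(v == 0.0 for v in res.gamma.values())


class TestPerturbationSweep:
    def test_gamma_matches_recomputation_from_stored_readouts(
            self, base_realization):
        """γ equals a literal re-computation from the stored readout
        values and baseline, to machine precision."""
        res = run_perturbation_sweep(base_realization)
        changes = res.protocol.relative_changes
        ro = res.readouts
        for m in MEASURES:
            xi = [
                float(ro[(ro["rel_change"] == d) & (ro["measure"] == m)]
                      ["value"].iloc[0])
                for d in changes
            ]
            ri = [1.0 + d for d in changes]
            expected = _literal_gamma(res.baseline[m], xi, 1.0, ri)
            assert res.gamma[m] == pytest.approx(expected, rel=1e-12), m

    def test_readouts_are_final_time_course_points(self, base_realization):
        res = run_perturbation_sweep(base_realization)
        tc = res.time_courses
        t_end = res.protocol.total_time
        for d in res.protocol.relative_changes[:3]:
            final = tc.query("rel_change == @d and time == @t_end")
            merged = final.merge(
                res.readouts.query("rel_change == @d"), on="measure")
            np.testing.assert_allclose(merged["value_x"], merged["value_y"])

    def test_proportional_limit_scores_near_zero(self):
        """In a first-order regime every supported steady flux is
        proportional to the influx, so the relaxed-readout γ vanishes.

        The verbatim directional PGI pair gives the downstream pools no
        F6P-coupled source, so in the linear regime only the F6P branch
        (F6P, rPGI, r2, rANTHO) carries flux; γ is asserted there.
        """
        big = 1e6
        d = BASE_PARAMETERS.as_dict()
        d.update(k_NPS=30.0,
                 Km_a_SPS=1e8, Km_b_SPS=1e-3, Ki_SPS=1e-3, vmax_SPS=0.3e8,
                 Km_FRCK=big, Ki_FRCK=big, vmax_FRCK=0.5 * big,
                 Km_GLCK=big, Ki_GLCK=big, vmax_GLCK=0.5 * big,
                 Km_INV=big, Ki_INV1=big, Ki_INV2=big, vmax_INV=0.3 * big,
                 Km_PGI=big, Ki_PGI=big, vmax_PGI=0.2 * big)
        params = KineticParameters(**d)
        ss = find_steady_state(params, tol=1e-10)
        realization = ConditionRealization("toy", 0, params, ss)
        res = run_perturbation_sweep(
            realization, PerturbationProtocol(readout="relaxed"))
        for m in ("F6P", "rPGI", "r2", "rANTHO"):
            assert res.gamma[m] < 1e-3, m


class TestHighLightProtocol:
    def test_zero_step_scores_zero_everywhere(self, base_realization):
        gamma = run_high_light_protocol(base_realization, step_fraction=0.0)
        assert all(v == 0.0 for v in gamma.values())

    def test_matches_manual_two_point_computation(self, base_realization):
        """Default +25 % step with 3 h and 6 h readouts equals γ applied
        by hand to the two sampled states."""
        from coldcarb.kinetic_model import simulate

        step = 0.25
        gamma = run_high_light_protocol(base_realization, step_fraction=step)
        pert = base_realization.params.with_updates(
            k_NPS=base_realization.params.k_NPS * (1 + step))
        sol = simulate(pert, base_realization.steady_state, (0.0, 6.0),
                       t_eval=np.array([3.0, 6.0]))
        base = _measure_values(
            base_realization.steady_state.as_array(), base_realization.params,
            "rPGI1")
        for m in MEASURES:
            xi = [_measure_values(sol.y[:, j], pert, "rPGI1")[m] for j in (0, 1)]
            expected = gamma_score(base[m], xi, 1.0, [1 + step, 1 + step])
            assert gamma[m] == pytest.approx(expected, rel=1e-9), m

    def test_input_validation(self, base_realization):
        with pytest.raises(ValidationError):
            run_high_light_protocol(base_realization, step_fraction=-1.5)
        with pytest.raises(ValidationError):
            run_high_light_protocol(base_realization, readout_times=())


class TestSensitivityMatrix:
    def test_requires_canonical_measure_columns(self, base_realization):
        import pandas as pd

        bad = pd.DataFrame(np.ones((2, 3)), columns=["F6P", "G6P", "Suc"])
        meta = pd.DataFrame({"genotype": ["a", "b"], "day": [0, 1]})
        with pytest.raises(ValidationError, match="14 reported measures"):
            SensitivityMatrix(values=bad, meta=meta)

    def test_from_sweeps_builds_conditions_by_measures(self, small_study):
        from coldcarb import sweep_study

        matrix = sweep_study(small_study.realizations[:2])
        assert matrix.values.shape == (2, 14)
        assert tuple(matrix.values.columns) == MEASURES
        assert np.isfinite(matrix.values.to_numpy()).all()
        assert (matrix.values.to_numpy() >= 0).all()
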