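"""Rate laws, ODE assembly, steady-state solving and their invariants."""

import numpy as np
import pytest
import sympy as sp

from coldcarb import (
    ConditionRealization,
    KineticParameters,
    MetaboliteState,
    compute_fluxes,
    find_steady_state,
    ode_rhs,
    simulate,
)
from coldcarb.kinetic_model import (
    FLUX_NAMES,
    SCALING_CONSTANTS,
    STATE_NAMES,
    ConfigurationError,
    ConvergenceError,
    ValidationError,
    _rhs_array,
)
from coldcarb.synthetic_data import BASE_PARAMETERS


def _random_params(rng):
    return KineticParameters(
        k_NPS=rng.uniform(5, 60),
        vmax_SPS=rng.uniform(5, 60), Km_a_SPS=rng.uniform(1, 20),
        Km_b_SPS=rng.uniform(1, 20), Ki_SPS=rng.uniform(1, 20),
        k_udp=rng.uniform(0.2, 0.5),
        vmax_FRCK=rng.uniform(5, 80), Km_FRCK=rng.uniform(1, 20),
        Ki_FRCK=rng.uniform(1, 20),
        vmax_GLCK=rng.uniform(5, 80), Km_GLCK=rng.uniform(0.5, 10),
        Ki_GLCK=rng.uniform(1, 20),
        vmax_INV=rng.uniform(5, 40), Km_INV=rng.uniform(1, 20),
        Ki_INV1=rng.uniform(1, 20), Ki_INV2=rng.uniform(1, 20),
        vmax_PGI=rng.uniform(5, 60), Km_PGI=rng.uniform(0.5, 10),
        Ki_PGI=rng.uniform(1, 20),
        f=rng.uniform(0.1, 0.9),
        k1_exp=rng.uniform(0.05, 1), k2_exp=rng.uniform(0.05, 1),
        k_STA=rng.uniform(0.05, 1), k_ANT=rng.uniform(0.02, 0.5),
    )


def _random_state(rng):
    return MetaboliteState(*rng.uniform(0.05, 30, size=5))


class TestComputeFluxes:
    def test_zero_substrate_only_influx_flows(self, base_params):
        flux = compute_fluxes(MetaboliteState(0, 0, 0, 0, 0), base_params)
        assert flux.rNPS == pytest.approx(base_params.k_NPS / 6)
        for name in FLUX_NAMES:
            if name not in ("rNPS", "rSTAdeg"):
                assert getattr(flux, name) == 0.0

    def test_influx_is_one_sixth_of_its_scale(self, base_params):
        params = base_params.with_updates(k_NPS=6.0)
        assert compute_fluxes(MetaboliteState(1, 1, 1, 1, 1), params).rNPS == 1.0

    def test_half_saturation_of_fructokinase(self, base_params):
        state = MetaboliteState(0.0, 0.0, 0.0, base_params.Km_FRCK, 0.0)
        flux = compute_fluxes(state, base_params)
        assert flux.rFRCK == pytest.approx(base_params.vmax_FRCK / 2, rel=1e-12)

    def test_first_order_sucrose_export(self, base_params):
        params = base_params.with_updates(k1_exp=0.1)
        flux = compute_fluxes(MetaboliteState(0, 0, 2.0, 0, 0), params)
        assert flux.r1 == pytest.approx(0.2, rel=1e-12)

    def test_invalid_parameter_names_field(self, base_params):
        with pytest.raises(ValidationError, match="Km_FRCK"):
            base_params.with_updates(Km_FRCK=-1.0)
        with pytest.raises(ValidationError, match="vmax_INV"):
            base_params.with_updates(vmax_INV=0.0)

    def test_matches_symbolic_rederivation(self, rng):
        """Rate laws agree with an independent symbolic build to 1e-12."""
        F6P, G6P, Suc, Frc, Glc = sp.symbols("F6P G6P Suc Frc Glc", positive=True)
        names = ("k_NPS vmax_SPS Km_a_SPS Km_b_SPS Ki_SPS k_udp vmax_FRCK Km_FRCK "
                 "Ki_FRCK vmax_GLCK Km_GLCK Ki_GLCK vmax_INV Km_INV Ki_INV1 Ki_INV2 "
                 "vmax_PGI Km_PGI Ki_PGI f k1_exp k2_exp k_STA k_ANT").split()
        s = dict(zip(names, sp.symbols(" ".join(names), positive=True)))
        exprs = {
            "rNPS": sp.Rational(1, 6) * s["k_NPS"],
            "rSPS": s["vmax_SPS"] * F6P * s["k_udp"] * G6P
            / (s["Km_a_SPS"] * F6P + (s["Km_b_SPS"] + F6P) * s["k_udp"] * G6P
               + s["Ki_SPS"] * s["Km_a_SPS"]),
            "rFRCK": s["vmax_FRCK"] * Frc
            / ((s["Km_FRCK"] + Frc) * (1 + F6P / s["Ki_FRCK"])),
            "rGLCK": s["vmax_GLCK"] * Glc
            / ((s["Km_GLCK"] + Glc) * (1 + G6P / s["Ki_GLCK"])),
            "rINV": s["vmax_INV"] * Suc
            / ((s["Km_INV"] * (1 + Frc / s["Ki_INV1"]) + Suc)
               * (1 + Glc / s["Ki_INV2"])),
            "rPGI1": s["vmax_PGI"] * F6P
            / (s["Km_PGI"] * (1 + G6P / s["Ki_PGI"]) + F6P) * s["f"],
            "rPGI2": s["vmax_PGI"] * G6P
            / (s["Km_PGI"] * (1 + F6P / s["Ki_PGI"]) + G6P) * (1 - s["f"]),
            "r1": s["k1_exp"] * Suc,
            "r2": s["k2_exp"] * F6P,
            "rSTAsyn": s["k_STA"] * G6P,
            "rANTHO": s["k_ANT"] * F6P,
        }
        funcs = {
            name: sp.lambdify((F6P, G6P, Suc, Frc, Glc, *s.values()), e)
            for name, e in exprs.items()
        }
        for _ in range(100):
            params = _random_params(rng)
            state = _random_state(rng)
            flux = compute_fluxes(state, params).as_dict()
            args = (*state.as_array(), *(getattr(params, n) for n in names))
            for name, fn in funcs.items():
                expected = fn(*args)
                assert flux[name] == pytest.approx(expected, rel=1e-12), name


class TestOdeRhs:
    def test_scheme_consistent_sucrose_balance(self, rng):
        params = _random_params(rng)
        state = _random_state(rng)
        flux = compute_fluxes(state, params)
        rhs = ode_rhs(state, params, "scheme-consistent")
        assert rhs[2] == pytest.approx(flux.rSPS - flux.r1 - flux.rINV, rel=1e-12)
        # remaining balances assembled by hand from the flux vector
        assert rhs[0] == pytest.approx(
            flux.rNPS - flux.rSPS - flux.rPGI1 - flux.rANTHO - flux.r2 + flux.rFRCK)
        assert rhs[1] == pytest.approx(
            flux.rPGI2 - flux.rSPS - flux.rSTAsyn + flux.rGLCK)
        assert rhs[3] == pytest.approx(flux.rINV - flux.rFRCK)
        assert rhs[4] == pytest.approx(flux.rINV - flux.rGLCK + flux.rSTAdeg)

    def test_as_printed_variant_drains_sucrose_via_r2(self, rng):
        params = _random_params(rng)
        state = _random_state(rng)
        flux = compute_fluxes(state, params)
        rhs = ode_rhs(state, params, "as-printed")
        assert rhs[2] == pytest.approx(flux.rSPS - flux.r2 - flux.rINV, rel=1e-12)

    def test_unknown_mode_rejected(self, base_params):
        with pytest.raises(ConfigurationError):
            ode_rhs(MetaboliteState(1, 1, 1, 1, 1), base_params, "bogus")

    def test_empty_system_at_rest(self, base_params):
        params = base_params.with_updates(k_NPS=0.0)
        rhs = ode_rhs(MetaboliteState(0, 0, 0, 0, 0), params)
        assert np.all(rhs == 0.0)

    def test_vanishes_at_steady_state(self, base_realization):
        rhs = ode_rhs(base_realization.steady_state, base_realization.params)
        assert np.max(np.abs(rhs)) < 1e-9


class TestFindSteadyState:
    def test_no_influx_gives_empty_steady_state(self, base_params):
        # f = 1 switches off the G6P-producing PGI flux, which is taken
        # verbatim from the published rate law and is not mass-coupled
        # to its F6P-consuming twin — with it active, G6P self-feeds to
        # a nonzero pool even without influx (see the companion test)
        params = base_params.with_updates(k_NPS=0.0, f=1.0)
        ss = find_steady_state(params, tol=1e-10)
        assert np.max(ss.as_array()) < 1e-8

    def test_no_influx_pgi_pair_self_feeds_g6p(self, base_params):
        """The verbatim directional PGI pair is not mass-conserving:
        its G6P-producing branch acts as a source, so the no-influx
        system settles at vmax_PGI·(1−f)/(Km_PGI+G6P) = k_STA."""
        params = base_params.with_updates(k_NPS=0.0)
        ss = find_steady_state(params, tol=1e-10)
        expected = params.vmax_PGI * (1 - params.f) / params.k_STA - params.Km_PGI
        assert ss.G6P == pytest.approx(expected, rel=1e-8)
        assert ss.F6P < 1e-8 and ss.Suc < 1e-8

    def test_every_component_below_tolerance(self, rng):
        for _ in range(5):
            params = _random_params(rng)
            try:
                ss = find_steady_state(params, tol=1e-8)
            except ConvergenceError:
                continue  # not every random draw admits a steady state
            assert np.max(np.abs(ode_rhs(ss, params))) < 1e-8

    def test_two_method_agreement(self, base_params):
        """Pure long integration and integration+Newton land on the
        same state to < 1e-6 relative per metabolite."""
        refined = find_steady_state(base_params, tol=1e-10)
        sol = simulate(base_params, MetaboliteState(1, 1, 1, 1, 1), (0.0, 1e5),
                       rtol=1e-12, atol=1e-14)
        integrated = sol.y[:, -1]
        rel = np.abs(integrated - refined.as_array()) / np.abs(refined.as_array())
        assert np.max(rel) < 1e-6

    def test_nonconvergence_reports_residual(self, base_params):
        # an unreachable tolerance exercises the failure contract:
        # the error carries the final residual as a diagnostic
        with pytest.raises(ConvergenceError) as err:
            find_steady_state(base_params, t_long=10.0, tol=1e-18)
        assert err.value.residual is not None and err.value.residual > 0

    def test_positivity_preservation(self, base_params, rng):
        for _ in range(3):
            start = _random_state(rng)
            sol = simulate(base_params, start, (0.0, 50.0),
                           t_eval=np.linspace(0, 50, 101))
            assert sol.y.min() > -1e-9

    @pytest.mark.parametrize("lam", [0.25, 2.0, 7.5])
    def test_scaling_law(self, base_realization, lam):
        """Scaling the ten rate constants by λ leaves steady-state
        concentrations unchanged and scales all fluxes by λ."""
        scaled = base_realization.params.scaled(lam)
        ss = find_steady_state(scaled, base_realization.steady_state,
                               skip_integration=True, tol=1e-10)
        np.testing.assert_allclose(
            ss.as_array(), base_realization.steady_state.as_array(), rtol=1e-7)
        base_flux = np.array(list(base_realization.steady_fluxes().as_dict().values()))
        flux = np.array(list(compute_fluxes(ss, scaled).as_dict().values()))
        np.testing.assert_allclose(flux[:-1], lam * base_flux[:-1], rtol=1e-7)


class TestTypes:
    def test_state_rejects_negative_and_nonfinite(self):
        with pytest.raises(ValidationError, match="Suc"):
            MetaboliteState(1, 1, -0.1, 1, 1)
        with pytest.raises(ValidationError, match="G6P"):
            MetaboliteState(1, float("nan"), 1, 1, 1)

    def test_fraction_bounds(self, base_params):
        with pytest.raises(ValidationError, match="f"):
            base_params.with_updates(f=1.2)
        with pytest.raises(ValidationError, match="k_udp"):
            base_params.with_updates(k_udp=0.6)

    def test_realization_requires_steady_state(self, base_params):
        with pytest.raises(ValidationError, match="steady-state"):
            ConditionRealization("Col-0", 0, base_params,
                                 MetaboliteState(5, 5, 5, 5, 5))

    def test_realization_requires_zero_starch_degradation(self, base_realization):
        params = base_realization.params.with_updates(k_STAdeg=0.5)
        with pytest.raises(ValidationError, match="k_STAdeg"):
            ConditionRealization("Col-0", 0, params, base_realization.steady_state)

    def test_scaling_constants_cover_every_flux(self, base_params, rng):
        """Each flux is proportional to exactly one scaling constant."""
        state = _random_state(rng)
        base = compute_fluxes(state, base_params).as_dict()
        scaled = compute_fluxes(state, base_params.scaled(3.0)).as_dict()
        for name in FLUX_NAMES:
            if name == "rSTAdeg":
                continue
            assert scaled[name] == pytest.approx(3.0 * base[name], rel=1e-12)
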