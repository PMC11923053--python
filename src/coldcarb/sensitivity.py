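"""Perturbation protocols and the photosynthesis-sensitivity score.

The score γ_x^nps of a measure x (metabolite concentration or reaction
flux) quantifies how disproportionately x responds to perturbations of
the net-photosynthesis influx: it is the geometric mean, over the set
of applied perturbations, of |log2((x_i/x_0)·(r_0/r_i))|, where x_0 and
r_0 are the unperturbed steady-state value of x and the unperturbed
influx rate, and x_i, r_i the values under perturbation i. A measure
that scales exactly proportionally with the influx scores 0.

Two protocols are provided: a magnitude sweep (±5…30 % in 5 % steps,
readout at the end of a 4 h window with the step applied at 2 h) and a
high-light step protocol (+25 % influx, readouts after 3 h and 6 h of
exposure, durations playing the role of perturbations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetic_model import (
    STATE_NAMES,
    ConditionRealization,
    ValidationError,
    _flux_array,
    simulate,
)

#: The 14 reported measures: the 5 pools plus 9 reported fluxes.
MEASURES = (
    "F6P", "G6P", "Frc", "Glc", "Suc",
    "rSPS", "rPGI", "rFRCK", "rGLCK", "r1", "rINV", "r2", "rSTAsyn", "rANTHO",
)

_DEFAULT_CHANGES = tuple(
    s * k * 0.05 for k in range(1, 7) for s in (+1, -1)
)


@dataclass(frozen=True)
class PerturbationProtocol:
    """Magnitude-sweep protocol for the influx perturbation.

    ``relative_changes`` are signed fractions applied to the influx
    scale k_NPS (default ±0.05 … ±0.30 in 0.05 steps, N = 12);
    the step is applied at ``pre_perturbation_time`` (h) and the
    readout taken per ``readout``: ``"end"`` reads at ``total_time``,
    ``"relaxed"`` reads the post-perturbation steady state.
    """

    relative_changes: tuple[float, ...] = _DEFAULT_CHANGES
    pre_perturbation_time: float = 2.0
    total_time: float = 4.0
    readout: str = "end"
    pgi_report_mode: str = "rPGI1"

    def __post_init__(self):
        if len(self.relative_changes) < 1:
            raise ValidationError("relative_changes must contain at least one perturbation")
        for d in self.relative_changes:
            if d <= -1.0:
                raise ValidationError(
                    f"relative change {d} would make the influx non-positive"
                )
        if 0.0 in self.relative_changes:
            warnings.warn(
                "a relative change of 0 annihilates the geometric mean: "
                "every γ will be exactly 0",
                stacklevel=2,
            )
        if not (self.total_time > self.pre_perturbation_time > 0):
            raise ValidationError(
                "need total_time > pre_perturbation_time > 0, got "
                f"total={self.total_time}, pre={self.pre_perturbation_time}"
            )
        if self.readout not in ("end", "relaxed"):
            raise ValidationError(f"unknown readout rule {self.readout!r}")

    @property
    def n_perturbations(self) -> int:
        return len(self.relative_changes)


def gamma_score(x0: float, xi_list, r0: float, ri_list) -> float:
    """Geometric mean of |log2| perturbation-normalized fold changes.

    Returns the N-th root of ∏ᵢ |log2((xᵢ/x₀)·(r₀/rᵢ))|. All inputs
    must be strictly positive; the two lists must have equal length ≥ 1.
    """
    xi = np.asarray(xi_list, dtype=float)
    ri = np.asarray(ri_list, dtype=float)
    if xi.shape != ri.shape or xi.ndim != 1 or xi.size < 1:
        raise ValidationError(
            f"xi_list and ri_list must be equal-length 1-d sequences with N >= 1, "
            f"got shapes {xi.shape} and {ri.shape}"
        )
    for label, vals in (("x0", [x0]), ("r0", [r0]), ("xi", xi), ("ri", ri)):
        if not np.all(np.isfinite(vals)) or np.any(np.asarray(vals) <= 0):
            raise ValidationError(f"{label} must be strictly positive and finite")
    inner = np.abs(np.log2((xi / x0) * (r0 / ri)))
    # geometric mean via log-sum; exact 0 terms annihilate the product
    if np.any(inner == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(inner))))


def _measure_values(y: np.ndarray, params, pgi_mode: str) -> dict[str, float]:
    flux = _flux_array(y, params)
    out = dict(zip(STATE_NAMES, (float(v) for v in y)))
    named = dict(zip(
        ("rNPS", "rSPS", "rFRCK", "rGLCK", "rINV", "rPGI1", "rPGI2",
         "r1", "r2", "rSTAsyn", "rANTHO", "rSTAdeg"),
        (float(v) for v in flux),
    ))
    if pgi_mode == "rPGI1":
        named["rPGI"] = named["rPGI1"]
    elif pgi_mode == "rPGI2":
        named["rPGI"] = named["rPGI2"]
    elif pgi_mode == "mean":
        named["rPGI"] = 0.5 * (named["rPGI1"] + named["rPGI2"])
    else:
        raise ValidationError(f"unknown PGI report mode {pgi_mode!r}")
    out.update({m: named[m] for m in MEASURES if m in named})
    return {m: out[m] for m in MEASURES}


@dataclass
class SweepResult:
    """γ per measure plus the stored perturbation time courses."""

    gamma: dict[str, float]
    time_courses: pd.DataFrame  # columns: rel_change, time, measure, value
    baseline: dict[str, float]
    readouts: pd.DataFrame      # columns: rel_change, measure, value
    protocol: PerturbationProtocol
    condition: str = ""


def _integrate_step(realization, scaled_params, t_after, n_grid=41):
    """Integrate from the realization's steady state for t_after hours
    under the rescaled influx; returns (times, states) with the final
    time hit exactly."""
    t_eval = np.linspace(0.0, t_after, n_grid)
    sol = simulate(
        scaled_params, realization.steady_state, (0.0, t_after),
        t_eval=t_eval, mode=realization.mode,
    )
    return sol.t, sol.y


def run_perturbation_sweep(
    realization: ConditionRealization,
    protocol: PerturbationProtocol | None = None,
) -> SweepResult:
    """Apply the magnitude-sweep protocol to one condition realization.

    For each relative change δ the influx scale k_NPS is multiplied by
    (1+δ) at the pre-perturbation time and the system integrated to the
    end of the window; x_i is read at the protocol's readout point and
    r_i/r_0 = 1+δ (the influx is directly proportional to k_NPS). The
    baseline x_0 is the unperturbed steady-state value. Measures driven
    to zero or below at readout get γ = NaN with a warning rather than
    a silently clamped value.
    """
    if protocol is None:
        protocol = PerturbationProtocol()
    params = realization.params
    pgi = protocol.pgi_report_mode
    base = _measure_values(realization.steady_state.as_array(), params, pgi)

    post = protocol.total_time - protocol.pre_perturbation_time
    rows, readout_rows = [], []
    readout_vals: dict[str, list[float]] = {m: [] for m in MEASURES}
    ratios = []
    for delta in protocol.relative_changes:
        pert = params.with_updates(k_NPS=params.k_NPS * (1.0 + delta))
        if delta == 0.0:
            # unperturbed system stays at steady state exactly
            t = np.array([post])
            ys = realization.steady_state.as_array()[:, None]
        elif protocol.readout == "relaxed":
            from .kinetic_model import find_steady_state
            state = find_steady_state(
                pert, realization.steady_state, mode=realization.mode,
                skip_integration=False, t_long=1e4, tol=1e-8,
            )
            t, ys = np.array([post]), state.as_array()[:, None]
        else:
            t, ys = _integrate_step(realization, pert, post)
        for j, tj in enumerate(t):
            vals = _measure_values(ys[:, j], pert, pgi)
            rows.extend(
                {"rel_change": delta, "time": protocol.pre_perturbation_time + tj,
                 "measure": m, "value": v}
                for m, v in vals.items()
            )
        final = _measure_values(ys[:, -1], pert, pgi)
        readout_rows.extend(
            {"rel_change": delta, "measure": m, "value": v} for m, v in final.items()
        )
        for m in MEASURES:
            readout_vals[m].append(final[m])
        ratios.append(1.0 + delta)

    gamma: dict[str, float] = {}
    for m in MEASURES:
        xi = np.array(readout_vals[m])
        x0 = base[m]
        if x0 <= 0 or np.any(xi <= 0):
            warnings.warn(
                f"measure {m} non-positive at baseline or readout; γ undefined",
                stacklevel=2,
            )
            gamma[m] = float("nan")
        else:
            gamma[m] = gamma_score(x0, xi, 1.0, ratios)

    return SweepResult(
        gamma=gamma,
        time_courses=pd.DataFrame(rows),
        baseline=base,
        readouts=pd.DataFrame(readout_rows),
        protocol=protocol,
        condition=realization.label,
    )


def run_high_light_protocol(
    realization: ConditionRealization,
    step_fraction: float = 0.25,
    readout_times: tuple[float, ...] = (3.0, 6.0),
    pgi_report_mode: str = "rPGI1",
) -> dict[str, float]:
    """High-light step variant of the sensitivity score.

    A single step of ``step_fraction`` (default +25 %) is applied to the
    influx scale; the state is sampled at each readout time after the
    step, so exposure durations play the role of the perturbations i and
    r_i/r_0 = 1 + step_fraction for every i.
    """
    if step_fraction <= -1.0:
        raise ValidationError(f"step_fraction {step_fraction} would negate the influx")
    if len(readout_times) < 1:
        raise ValidationError("readout_times must be non-empty")
    params = realization.params
    base = _measure_values(realization.steady_state.as_array(), params, pgi_report_mode)
    if step_fraction == 0.0:
        return {m: 0.0 for m in MEASURES}
    pert = params.with_updates(k_NPS=params.k_NPS * (1.0 + step_fraction))
    t_end = max(readout_times)
    sol = simulate(
        pert, realization.steady_state, (0.0, t_end),
        t_eval=np.asarray(sorted(readout_times), dtype=float), mode=realization.mode,
    )
    sampled = [
        _measure_values(sol.y[:, j], pert, pgi_report_mode)
        for j in range(sol.y.shape[1])
    ]
    ratios = [1.0 + step_fraction] * len(readout_times)
    gamma: dict[str, float] = {}
    for m in MEASURES:
        xi = np.array([s[m] for s in sampled])
        x0 = base[m]
        if x0 <= 0 or np.any(xi <= 0):
            warnings.warn(f"measure {m} non-positive; γ undefined", stacklevel=2)
            gamma[m] = float("nan")
        else:
            gamma[m] = gamma_score(x0, xi, 1.0, ratios)
    return gamma


@dataclass
class SensitivityMatrix:
    """γ values for a set of conditions over the 14 reported measures.

    ``values`` is a conditions × measures DataFrame (index: condition
    label); ``meta`` carries genotype and day per condition; ``protocol``
    records provenance.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    protocol: PerturbationProtocol | None = None

    def __post_init__(self):
        if tuple(self.values.columns) != MEASURES:
            raise ValidationError(
                "sensitivity matrix columns must be exactly the 14 reported measures "
                f"in canonical order; got {list(self.values.columns)}"
            )
        if not self.values.index.equals(self.meta.index):
            raise ValidationError("values and meta must share the same condition index")

    @classmethod
    def from_sweeps(cls, realizations, results) -> "SensitivityMatrix":
        rows = {r.label: res.gamma for r, res in zip(realizations, results)}
        values = pd.DataFrame.from_dict(rows, orient="index")[list(MEASURES)]
        meta = pd.DataFrame(
            {"genotype": [r.genotype for r in realizations],
             "day": [r.day for r in realizations]},
            index=[r.label for r in realizations],
        )
        proto = results[0].protocol if results else None
        return cls(values=values, meta=meta, protocol=proto)

    def dropna(self) -> "SensitivityMatrix":
        keep = self.values.dropna().index
        dropped = self.values.index.difference(keep)
        if len(dropped):
            warnings.warn(
                f"excluding {len(dropped)} condition(s) with undefined γ: "
                f"{list(dropped)}",
                stacklevel=2,
            )
        return SensitivityMatrix(
            self.values.loc[keep], self.meta.loc[keep], self.protocol
        )


def sweep_study(realizations, protocol: PerturbationProtocol | None = None) -> SensitivityMatrix:
    """Run the magnitude sweep over a list of condition realizations."""
    if protocol is None:
        protocol = PerturbationProtocol()
    results = [run_perturbation_sweep(r, protocol) for r in realizations]
    return SensitivityMatrix.from_sweeps(realizations, results)
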