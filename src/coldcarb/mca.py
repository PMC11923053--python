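"""Metabolic control analysis at steady state.

The control coefficient C_p^X = dln(X)/dln(p) measures the fractional
change of a steady-state measure X (concentration or flux) per
fractional change of a parameter p, with the system fully relaxed to
its new steady state after the parameter change. Two routes are
provided: a central finite difference in log-log space with a
steady-state re-solve per perturbed parameter (the default), and an
implicit-function-theorem route through the Jacobian that serves as an
independent cross-check.

Because every reaction flux is proportional to exactly one of the ten
rate-scaling constants, the summation theorems hold structurally: flux
control coefficients over those constants sum to 1 and concentration
control coefficients to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetic_model import (
    PARAMETER_NAMES,
    STATE_NAMES,
    ConditionRealization,
    ConvergenceError,
    MetaboliteState,
    ValidationError,
    _flux_array,
    _rhs_array,
    find_steady_state,
)
from .sensitivity import MEASURES, _measure_values

#: Parameters analysed by default: everything except the constant
#: starch-degradation input (fixed 0 in realizations, log-perturbation
#: undefined).
MCA_PARAMETERS = tuple(p for p in PARAMETER_NAMES if p != "k_STAdeg")

# multiplicative admissible ranges for the two bounded fractions
_PARAM_BOUNDS = {"f": (0.0, 1.0), "k_udp": (0.2, 0.5)}


def _resolve_steady_state(realization, params, tol=1e-10):
    """Re-solve the steady state after a parameter change, starting the
    Newton iteration from the base steady state (the 'relaxed system')."""
    try:
        return find_steady_state(
            params, realization.steady_state, mode=realization.mode,
            tol=tol, skip_integration=True,
        )
    except ConvergenceError:
        return find_steady_state(
            params, realization.steady_state, mode=realization.mode, tol=tol,
        )


def _effective_step(p_val: float, name: str, rel_step: float) -> float:
    """Shrink the relative step so both p·(1±h) stay inside admissible
    bounds; perturbations are always two-sided."""
    h = rel_step
    if name in _PARAM_BOUNDS:
        lo, hi = _PARAM_BOUNDS[name]
        if p_val * (1 + h) > hi:
            h = min(h, 0.5 * (hi / p_val - 1.0))
        if p_val * (1 - h) < lo:
            h = min(h, 0.5 * (1.0 - lo / p_val))
        if h <= 0:
            raise ValidationError(
                f"parameter {name}={p_val} leaves no room for a two-sided "
                "perturbation within its admissible bounds"
            )
    return h


def _measure_at(params, state: MetaboliteState, measure: str, pgi_mode: str) -> float:
    y = state.as_array()
    if measure in STATE_NAMES:
        return float(y[STATE_NAMES.index(measure)])
    vals = _measure_values(y, params, pgi_mode)
    if measure in vals:
        return vals[measure]
    flux_names = ("rNPS", "rSPS", "rFRCK", "rGLCK", "rINV", "rPGI1", "rPGI2",
                  "r1", "r2", "rSTAsyn", "rANTHO", "rSTAdeg")
    if measure in flux_names:
        return float(_flux_array(y, params)[flux_names.index(measure)])
    raise ValidationError(
        f"unknown measure {measure!r}; valid measures: {MEASURES + flux_names}"
    )


def fd_control_coefficient(solve_measure, rel_step: float = 1e-4) -> float:
    """Generic dln(X)/dln(p) by central finite difference.

    ``solve_measure(scale)`` must return the steady-state measure after
    the parameter of interest is multiplied by ``scale``; the
    coefficient is (ln X₊ − ln X₋)/(ln(1+h) − ln(1−h)) with h the
    relative step. This is the shared core of the model-specific
    routines and is directly checkable against closed-form coefficients
    of simple reaction chains.
    """
    xp = solve_measure(1.0 + rel_step)
    xm = solve_measure(1.0 - rel_step)
    if xp <= 0 or xm <= 0:
        return float("nan")
    return float((np.log(xp) - np.log(xm)) / (np.log1p(rel_step) - np.log1p(-rel_step)))


def control_coefficient(
    realization: ConditionRealization,
    p: str,
    X: str,
    rel_step: float = 1e-4,
    pgi_mode: str = "rPGI1",
) -> float:
    """C_p^X by central finite difference in log-log space.

    The parameter is perturbed multiplicatively by (1±rel_step), the
    steady state re-solved for each side, and the coefficient returned
    as (ln X₊ − ln X₋) / (ln p₊ − ln p₋). Returns NaN (with a warning)
    if X vanishes at the base point or either perturbed point.
    """
    if p not in PARAMETER_NAMES:
        raise ValidationError(f"unknown parameter {p!r}")
    params = realization.params
    p_val = getattr(params, p)
    if p_val <= 0:
        raise ValidationError(f"parameter {p}={p_val} cannot be log-perturbed")
    x_base = _measure_at(params, realization.steady_state, X, pgi_mode)
    if x_base == 0:
        warnings.warn(f"measure {X} is 0 at the base steady state; C undefined",
                      stacklevel=2)
        return float("nan")
    h = _effective_step(p_val, p, rel_step)

    def solve_measure(scale: float) -> float:
        pert = params.with_updates(**{p: p_val * scale})
        ss = _resolve_steady_state(realization, pert)
        return _measure_at(pert, ss, X, pgi_mode)

    c = fd_control_coefficient(solve_measure, h)
    if math.isnan(c):
        warnings.warn(f"measure {X} non-positive under perturbation of {p}; C undefined",
                      stacklevel=2)
    return c


def control_coefficient_analytic(
    realization: ConditionRealization,
    p: str,
    X: str,
    pgi_mode: str = "rPGI1",
    fd_step: float = 1e-7,
) -> float:
    """C_p^X through the implicit function theorem (cross-check route).

    At steady state F(S, p) = 0, so dS/dp = −J⁻¹ ∂F/∂p with J the state
    Jacobian; for a flux measure the direct parameter dependence is
    added via the chain rule. Partial derivatives are central
    differences of the rate laws only — no steady-state re-solve.
    """
    if p not in PARAMETER_NAMES:
        raise ValidationError(f"unknown parameter {p!r}")
    params = realization.params
    mode = realization.mode
    y0 = realization.steady_state.as_array()
    p_val = getattr(params, p)

    def rhs(y, prm):
        return _rhs_array(y, prm, mode)

    # state Jacobian
    J = np.empty((5, 5))
    for j in range(5):
        dy = max(abs(y0[j]), 1.0) * fd_step
        yp, ym = y0.copy(), y0.copy()
        yp[j] += dy
        ym[j] -= dy
        J[:, j] = (rhs(yp, params) - rhs(ym, params)) / (2 * dy)

    dp = p_val * fd_step
    prm_p = params.with_updates(**{p: p_val + dp})
    prm_m = params.with_updates(**{p: p_val - dp})
    dF_dp = (rhs(y0, prm_p) - rhs(y0, prm_m)) / (2 * dp)
    dS_dp = np.linalg.solve(J, -dF_dp)

    x_base = _measure_at(params, realization.steady_state, X, pgi_mode)
    if x_base == 0:
        return float("nan")
    if X in STATE_NAMES:
        i = STATE_NAMES.index(X)
        return float(p_val / x_base * dS_dp[i])

    def meas(y, prm):
        return _measure_values(np.asarray(y, dtype=float), prm, pgi_mode)[X]

    # direct parameter dependence of the flux
    dX_dp_direct = (meas(y0, prm_p) - meas(y0, prm_m)) / (2 * dp)
    # dependence through the state
    grad = np.empty(5)
    for j in range(5):
        dy = max(abs(y0[j]), 1.0) * fd_step
        yp, ym = y0.copy(), y0.copy()
        yp[j] += dy
        ym[j] -= dy
        grad[j] = (meas(yp, params) - meas(ym, params)) / (2 * dy)
    dX_dp = dX_dp_direct + grad @ dS_dp
    return float(p_val / x_base * dX_dp)


@dataclass
class ControlCoefficientTensor:
    """Long-format control coefficients over conditions × parameters × measures.

    ``data`` columns: condition, genotype, day, parameter, measure,
    value. Missing entries (undefined logs, failed re-solves) are kept
    as NaN with their reason in ``failures``.
    """

    data: pd.DataFrame
    rel_step: float
    method: str = "finite-difference"
    failures: pd.DataFrame | None = None

    def matrix(self, condition: str) -> pd.DataFrame:
        sub = self.data[self.data["condition"] == condition]
        return sub.pivot(index="parameter", columns="measure", values="value")


def full_mca(
    realization: ConditionRealization,
    parameters: tuple[str, ...] = MCA_PARAMETERS,
    measures: tuple[str, ...] = MEASURES,
    rel_step: float = 1e-4,
    pgi_mode: str = "rPGI1",
) -> pd.DataFrame:
    """Control coefficients over the full parameter × measure grid for
    one condition; returns a parameters × measures DataFrame."""
    out = pd.DataFrame(index=list(parameters), columns=list(measures), dtype=float)
    for p in parameters:
        p_val = getattr(realization.params, p)
        h = _effective_step(p_val, p, rel_step)
        prm_p = realization.params.with_updates(**{p: p_val * (1 + h)})
        prm_m = realization.params.with_updates(**{p: p_val * (1 - h)})
        try:
            ss_p = _resolve_steady_state(realization, prm_p)
            ss_m = _resolve_steady_state(realization, prm_m)
        except ConvergenceError as err:
            warnings.warn(f"steady-state re-solve failed for {p}: {err}", stacklevel=2)
            out.loc[p] = np.nan
            continue
        vals_p = _measure_values(ss_p.as_array(), prm_p, pgi_mode)
        vals_m = _measure_values(ss_m.as_array(), prm_m, pgi_mode)
        denom = np.log1p(h) - np.log1p(-h)
        for X in measures:
            xp, xm = vals_p[X], vals_m[X]
            base = _measure_at(realization.params, realization.steady_state, X, pgi_mode)
            if base <= 0 or xp <= 0 or xm <= 0:
                out.loc[p, X] = np.nan
            else:
                out.loc[p, X] = (np.log(xp) - np.log(xm)) / denom
    return out


def mca_study(
    realizations,
    parameters: tuple[str, ...] = MCA_PARAMETERS,
    measures: tuple[str, ...] = MEASURES,
    rel_step: float = 1e-4,
    pgi_mode: str = "rPGI1",
) -> ControlCoefficientTensor:
    """Run full_mca over a set of condition realizations."""
    rows = []
    for r in realizations:
        mat = full_mca(r, parameters, measures, rel_step, pgi_mode)
        for p in parameters:
            for X in measures:
                rows.append({
                    "condition": r.label, "genotype": r.genotype, "day": r.day,
                    "parameter": p, "measure": X, "value": mat.loc[p, X],
                })
    return ControlCoefficientTensor(
        data=pd.DataFrame(rows), rel_step=rel_step, method="finite-difference",
    )


def high_cc_frequency(
    tensor: ControlCoefficientTensor,
    threshold: float = 1.5,
    group_by: str = "genotype",
) -> pd.Series:
    """Count control coefficients of magnitude above ``threshold`` per
    genotype or per day (parameter control coefficients by default —
    whatever the tensor holds). Missing entries are excluded with a
    logged count."""
    if group_by not in ("genotype", "day"):
        raise ValidationError(f"group_by must be 'genotype' or 'day', got {group_by!r}")
    df = tensor.data
    n_missing = int(df["value"].isna().sum())
    if n_missing:
        warnings.warn(f"excluding {n_missing} missing control coefficient(s)",
                      stacklevel=2)
    df = df.dropna(subset=["value"])
    exceed = df[np.abs(df["value"]) > threshold]
    counts = exceed.groupby(group_by).size()
    # include empty groups with count 0
    all_groups = df[group_by].unique()
    return counts.reindex(all_groups, fill_value=0).sort_index()


def f_dominance_ratio(tensor: ControlCoefficientTensor, aggregate: str = "mean") -> float:
    """Ratio of the aggregated |C| of the hexose-phosphate balance
    fraction f to the largest aggregated |C| among all other parameters.

    ``aggregate`` is the statistic pooled over conditions and measures
    (mean or median of absolute values).
    """
    df = tensor.data.dropna(subset=["value"]).copy()
    df["absval"] = df["value"].abs()
    agg = getattr(df.groupby("parameter")["absval"], aggregate)()
    if "f" not in agg.index:
        raise ValidationError("tensor does not contain coefficients for f")
    others = agg.drop("f")
    return float(agg["f"] / others.max())
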