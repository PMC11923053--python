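"""Condensed kinetic model of leaf central carbohydrate metabolism.

The model tracks five metabolite pools — fructose 6-phosphate (F6P),
glucose 6-phosphate (G6P), sucrose (Suc), fructose (Frc) and glucose
(Glc), all in µmol gDW⁻¹ — connected by twelve reactions: a constant
photosynthetic influx (rNPS), sucrose phosphate synthase (rSPS),
fructokinase/glucokinase (rFRCK/rGLCK), invertase (rINV), the two
directional phosphoglucoisomerase fluxes (rPGI1/rPGI2) balanced by the
fraction ``f``, two first-order exports (r1 to sink organs, r2 to other
pathways), lumped starch synthesis (rSTAsyn), lumped anthocyanin
synthesis (rANTHO) and a constant starch-degradation input (rSTAdeg,
fixed at zero in steady-state realizations).

Time is measured in hours and fluxes in µmol gDW⁻¹ h⁻¹ throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root


class ValidationError(ValueError):
    """A state, parameter set or table failed validation."""


class ConfigurationError(ValueError):
    """An unknown mode or inconsistent configuration was requested."""


class ConvergenceError(RuntimeError):
    """An iterative solve did not reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


#: Order of the state variables, matching the order of the ODE system.
STATE_NAMES = ("F6P", "G6P", "Suc", "Frc", "Glc")

#: ODE variants for the sucrose balance. ``scheme-consistent`` drains
#: sucrose through its export flux r1 = k1_exp·Suc; ``as-printed`` uses
#: the F6P export r2 instead (a variant kept for literal reproduction).
ODE_MODES = ("scheme-consistent", "as-printed")

#: Rate-scaling constants: each flux is proportional to exactly one of
#: these, which forces the metabolic-control summation theorems.
SCALING_CONSTANTS = (
    "k_NPS", "vmax_SPS", "vmax_FRCK", "vmax_GLCK", "vmax_INV",
    "vmax_PGI", "k1_exp", "k2_exp", "k_STA", "k_ANT",
)

FLUX_NAMES = (
    "rNPS", "rSPS", "rFRCK", "rGLCK", "rINV", "rPGI1", "rPGI2",
    "r1", "r2", "rSTAsyn", "rANTHO", "rSTAdeg",
)

#: Valid definitions for the reported net PGI measure.
PGI_REPORT_MODES = ("rPGI1", "rPGI2", "mean")


@dataclass(frozen=True)
class MetaboliteState:
    """The five metabolite pools, µmol gDW⁻¹ (non-negative, finite)."""

    F6P: float
    G6P: float
    Suc: float
    Frc: float
    Glc: float

    def __post_init__(self):
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"state variable {name} is not finite: {v}")
            if v < 0:
                raise ValidationError(f"state variable {name} is negative: {v}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y) -> "MetaboliteState":
        y = np.asarray(y, dtype=float)
        if y.shape != (5,):
            raise ValidationError(f"state vector must have 5 entries, got shape {y.shape}")
        return cls(**dict(zip(STATE_NAMES, y)))

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in STATE_NAMES}


# parameters that must be strictly positive (k_NPS may be 0: darkness)
_POSITIVE_PARAMS = (
    "vmax_SPS", "Km_a_SPS", "Km_b_SPS", "Ki_SPS",
    "vmax_FRCK", "Km_FRCK", "Ki_FRCK",
    "vmax_GLCK", "Km_GLCK", "Ki_GLCK",
    "vmax_INV", "Km_INV", "Ki_INV1", "Ki_INV2",
    "vmax_PGI", "Km_PGI", "Ki_PGI",
    "k1_exp", "k2_exp", "k_STA", "k_ANT",
)


@dataclass(frozen=True)
class KineticParameters:
    """Full parameter set of the rate equations.

    ``f`` (0–1) balances the two directional PGI fluxes; ``k_udp``
    (0.2–0.5) is the fraction of G6P available to the SPS reaction,
    standing in for the omitted UDP-glucose intermediate. ``k_STAdeg``
    is a constant starch-degradation input with no rate equation of its
    own; it is fixed at 0 in steady-state condition realizations.
    """

    k_NPS: float
    vmax_SPS: float
    Km_a_SPS: float
    Km_b_SPS: float
    Ki_SPS: float
    k_udp: float
    vmax_FRCK: float
    Km_FRCK: float
    Ki_FRCK: float
    vmax_GLCK: float
    Km_GLCK: float
    Ki_GLCK: float
    vmax_INV: float
    Km_INV: float
    Ki_INV1: float
    Ki_INV2: float
    vmax_PGI: float
    Km_PGI: float
    Ki_PGI: float
    f: float
    k1_exp: float
    k2_exp: float
    k_STA: float
    k_ANT: float
    k_STAdeg: float = 0.0

    def __post_init__(self):
        for name in _POSITIVE_PARAMS:
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"parameter {name} must be > 0, got {v}")
        if not (math.isfinite(self.k_NPS) and self.k_NPS >= 0):
            raise ValidationError(f"parameter k_NPS must be >= 0, got {self.k_NPS}")
        if not (0.0 <= self.f <= 1.0):
            raise ValidationError(f"parameter f must lie in [0, 1], got {self.f}")
        if not (0.2 <= self.k_udp <= 0.5):
            raise ValidationError(
                f"parameter k_udp must lie in [0.2, 0.5], got {self.k_udp}"
            )
        if not (math.isfinite(self.k_STAdeg) and self.k_STAdeg >= 0):
            raise ValidationError(f"parameter k_STAdeg must be >= 0, got {self.k_STAdeg}")

    def as_dict(self) -> dict[str, float]:
        return {fl.name: float(getattr(self, fl.name)) for fl in fields(self)}

    @classmethod
    def param_names(cls) -> tuple[str, ...]:
        return tuple(fl.name for fl in cls.__dataclass_fields__)

    def with_updates(self, **updates: float) -> "KineticParameters":
        unknown = set(updates) - set(self.as_dict())
        if unknown:
            raise ValidationError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **updates)

    def scaled(self, lam: float) -> "KineticParameters":
        """Scale all ten rate-scaling constants by ``lam`` (> 0)."""
        if lam <= 0:
            raise ValidationError(f"scaling factor must be > 0, got {lam}")
        return self.with_updates(
            **{name: getattr(self, name) * lam for name in SCALING_CONSTANTS}
        )


PARAMETER_NAMES = tuple(KineticParameters.__dataclass_fields__)


@dataclass(frozen=True)
class FluxVector:
    """All reaction fluxes at one instant, µmol gDW⁻¹ h⁻¹."""

    rNPS: float
    rSPS: float
    rFRCK: float
    rGLCK: float
    rINV: float
    rPGI1: float
    rPGI2: float
    r1: float
    r2: float
    rSTAsyn: float
    rANTHO: float
    rSTAdeg: float

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in FLUX_NAMES}

    def reported_pgi(self, mode: str = "rPGI1") -> float:
        """Net reported PGI measure: one of ``rPGI1``, ``rPGI2``, ``mean``."""
        if mode == "rPGI1":
            return self.rPGI1
        if mode == "rPGI2":
            return self.rPGI2
        if mode == "mean":
            return 0.5 * (self.rPGI1 + self.rPGI2)
        raise ConfigurationError(f"unknown PGI report mode {mode!r}; use one of {PGI_REPORT_MODES}")


def _flux_array(y: np.ndarray, p: KineticParameters) -> np.ndarray:
    """Fluxes in FLUX_NAMES order from a raw 5-vector (hot path)."""
    F6P, G6P, Suc, Frc, Glc = y
    rNPS = p.k_NPS / 6.0
    g = p.k_udp * G6P
    rSPS = (
        p.vmax_SPS * F6P * g
        / (p.Km_a_SPS * F6P + (p.Km_b_SPS + F6P) * g + p.Ki_SPS * p.Km_a_SPS)
    )
    rFRCK = p.vmax_FRCK * Frc / ((p.Km_FRCK + Frc) * (1.0 + F6P / p.Ki_FRCK))
    rGLCK = p.vmax_GLCK * Glc / ((p.Km_GLCK + Glc) * (1.0 + G6P / p.Ki_GLCK))
    rINV = p.vmax_INV * Suc / (
        (p.Km_INV * (1.0 + Frc / p.Ki_INV1) + Suc) * (1.0 + Glc / p.Ki_INV2)
    )
    rPGI1 = p.vmax_PGI * F6P / (p.Km_PGI * (1.0 + G6P / p.Ki_PGI) + F6P) * p.f
    rPGI2 = p.vmax_PGI * G6P / (p.Km_PGI * (1.0 + F6P / p.Ki_PGI) + G6P) * (1.0 - p.f)
    r1 = p.k1_exp * Suc
    r2 = p.k2_exp * F6P
    rSTAsyn = p.k_STA * G6P
    rANTHO = p.k_ANT * F6P
    return np.array(
        [rNPS, rSPS, rFRCK, rGLCK, rINV, rPGI1, rPGI2, r1, r2, rSTAsyn, rANTHO, p.k_STAdeg]
    )


def compute_fluxes(state: MetaboliteState, params: KineticParameters) -> FluxVector:
    """Evaluate every reaction flux at ``state`` under ``params``."""
    v = _flux_array(state.as_array(), params)
    return FluxVector(**dict(zip(FLUX_NAMES, v)))


def _rhs_array(y: np.ndarray, p: KineticParameters, mode: str) -> np.ndarray:
    (rNPS, rSPS, rFRCK, rGLCK, rINV, rPGI1, rPGI2,
     r1, r2, rSTAsyn, rANTHO, rSTAdeg) = _flux_array(y, p)
    suc_drain = r1 if mode == "scheme-consistent" else r2
    return np.array([
        rNPS - rSPS - rPGI1 - rANTHO - r2 + rFRCK,   # dF6P/dt
        rPGI2 - rSPS - rSTAsyn + rGLCK,              # dG6P/dt
        rSPS - suc_drain - rINV,                     # dSuc/dt
        rINV - rFRCK,                                # dFrc/dt
        rINV - rGLCK + rSTAdeg,                      # dGlc/dt
    ])


def ode_rhs(
    state: MetaboliteState,
    params: KineticParameters,
    mode: str = "scheme-consistent",
) -> np.ndarray:
    """Time derivatives of the five pools, in STATE_NAMES order.

    ``mode`` selects the sucrose balance: ``scheme-consistent`` (default)
    drains sucrose via its own export r1, ``as-printed`` via r2.
    """
    if mode not in ODE_MODES:
        raise ConfigurationError(f"unknown ODE mode {mode!r}; use one of {ODE_MODES}")
    return _rhs_array(state.as_array(), params, mode)


def simulate(
    params: KineticParameters,
    initial_state: MetaboliteState,
    t_span: tuple[float, float],
    t_eval=None,
    mode: str = "scheme-consistent",
    rtol: float = 1e-9,
    atol: float = 1e-12,
):
    """Integrate the ODE system over ``t_span`` with a stiff solver."""
    if mode not in ODE_MODES:
        raise ConfigurationError(f"unknown ODE mode {mode!r}; use one of {ODE_MODES}")

    def rhs(t, y):
        return _rhs_array(y, params, mode)

    sol = solve_ivp(
        rhs, t_span, initial_state.as_array(), method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise ConvergenceError(f"integration failed: {sol.message}")
    return sol


def find_steady_state(
    params: KineticParameters,
    initial_guess: MetaboliteState | None = None,
    mode: str = "scheme-consistent",
    tol: float = 1e-9,
    t_long: float = 1e4,
    skip_integration: bool = False,
) -> MetaboliteState:
    """Solve for a non-negative steady state of the model.

    Integrates from ``initial_guess`` (default: 1 µmol gDW⁻¹ in every
    pool) out to ``t_long`` hours to relax onto the attractor, then
    refines with a damped Newton step (hybrid Powell). Every component
    of the right-hand side at the returned state is below ``tol``.
    ``skip_integration`` starts Newton directly from the guess — useful
    inside calibration loops where the guess is already near the root.

    Raises :class:`ConvergenceError` (carrying the final residual) if no
    state below tolerance is found.
    """
    if initial_guess is None:
        initial_guess = MetaboliteState(1.0, 1.0, 1.0, 1.0, 1.0)
    y = initial_guess.as_array()
    if not skip_integration:
        sol = simulate(params, initial_guess, (0.0, t_long), mode=mode,
                       rtol=1e-10, atol=1e-12)
        y = sol.y[:, -1]

    def fun(z):
        return _rhs_array(np.abs(z), params, mode)

    best = np.abs(y)
    best_res = float(np.max(np.abs(fun(best))))
    if best_res > tol:
        res = root(fun, best, method="hybr", tol=1e-13)
        cand = np.abs(res.x)
        cand_res = float(np.max(np.abs(fun(cand))))
        if cand_res < best_res:
            best, best_res = cand, cand_res
    if best_res > tol:
        raise ConvergenceError(
            f"no steady state found: max |dX/dt| = {best_res:.3e} > tol {tol:.1e}",
            residual=best_res,
        )
    return MetaboliteState.from_array(best)


GENOTYPES = ("Col-0", "chs", "f3h", "bam3", "pgm1")
DAYS = (0, 1, 3, 7, 14)


@dataclass(frozen=True)
class ConditionRealization:
    """One genotype × day parameterization satisfying the steady-state assumption.

    Genotype is metadata only: mutant effects live entirely in the
    fitted parameter values. ``k_STAdeg`` must be 0 (midday steady state;
    net starch turnover is absorbed into k_STA).
    """

    genotype: str
    day: int
    params: KineticParameters
    steady_state: MetaboliteState
    mode: str = "scheme-consistent"
    steady_state_tol: float = 1e-6

    def __post_init__(self):
        if self.params.k_STAdeg != 0.0:
            raise ValidationError(
                f"condition realizations require k_STAdeg = 0, got {self.params.k_STAdeg}"
            )
        resid = float(np.max(np.abs(
            ode_rhs(self.steady_state, self.params, self.mode)
        )))
        if resid > self.steady_state_tol:
            raise ValidationError(
                f"steady_state violates the steady-state assumption: "
                f"max |dX/dt| = {resid:.3e} > {self.steady_state_tol:.1e}"
            )

    @property
    def label(self) -> str:
        return f"{self.genotype}_day{self.day}"

    def steady_fluxes(self) -> FluxVector:
        return compute_fluxes(self.steady_state, self.params)
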