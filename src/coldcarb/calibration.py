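"""Per-condition parameter estimation under the steady-state assumption.

Each genotype × day condition is fitted individually: a bounded
multi-start least-squares search minimizes weighted squared
log-residuals between the model's steady state (concentrations, plus
any observed flux targets such as the photosynthetic influx or the net
starch balance) and the observations of that condition. All Km and Ki
values share common bounds across conditions and must respect
literature-derived order relations (e.g. Km_FRCK > Km_GLCK); the
requirement that each Km/Ki symbol stays within one order of magnitude
across conditions is checked post hoc, since conditions are fitted
independently.

Residuals are taken on the log scale because the observations span
orders of magnitude; weights default to 1/dispersion² in log units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .kinetic_model import (
    PARAMETER_NAMES,
    STATE_NAMES,
    ConvergenceError,
    KineticParameters,
    MetaboliteState,
    ValidationError,
    _flux_array,
    find_steady_state,
)

#: Parameters estimated per condition (k_STAdeg is fixed at 0).
FITTED_PARAMETERS = tuple(p for p in PARAMETER_NAMES if p != "k_STAdeg")

_KM_KI = tuple(p for p in FITTED_PARAMETERS if p.startswith(("Km", "Ki")))

_FLUX_INDEX = {
    name: i for i, name in enumerate(
        ("rNPS", "rSPS", "rFRCK", "rGLCK", "rINV", "rPGI1", "rPGI2",
         "r1", "r2", "rSTAsyn", "rANTHO", "rSTAdeg")
    )
}

#: Named presets resolving the ambiguous third literature relation on
#: Km_PGI (the two plausible placements of Km_PGI in the Km ordering).
PGI_ORDER_PRESETS = {
    "frck-pgi-glck": (("Km_FRCK", ">", "Km_PGI"), ("Km_PGI", ">", "Km_GLCK")),
    "inv-pgi-frck": (("Km_INV", ">", "Km_PGI"), ("Km_PGI", ">", "Km_FRCK")),
}

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_NPS": (1.0, 300.0),
    "vmax_SPS": (0.5, 200.0),
    "vmax_FRCK": (0.5, 200.0),
    "vmax_GLCK": (0.5, 200.0),
    "vmax_INV": (0.5, 200.0),
    "vmax_PGI": (0.5, 200.0),
    "k1_exp": (0.01, 5.0),
    "k2_exp": (0.01, 5.0),
    "k_STA": (0.001, 5.0),
    "k_ANT": (0.001, 5.0),
    "f": (0.05, 0.95),
    "k_udp": (0.2, 0.5),
    # common Km/Ki bounds shared by all conditions
    **{name: (0.5, 50.0) for name in _KM_KI},
}


@dataclass(frozen=True)
class ConstraintSet:
    """Bounds, order relations and the cross-condition cohesion rule.

    ``order_relations`` are strict ``(A, '>', B)`` triples over
    parameter symbols, enforced within every condition;
    ``km_inv_band`` constrains Km_INV/Km_FRCK to a ratio band
    (operationalizing 'Km_INV close to Km_FRCK'); ``cohesion_factor``
    is the maximal allowed max/min spread of any one Km/Ki symbol
    across conditions.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    order_relations: tuple[tuple[str, str, str], ...] = (
        ("Km_FRCK", ">", "Km_GLCK"),
    )
    km_inv_band: tuple[float, float] = (1.0 / 3.0, 3.0)
    cohesion_factor: float = 10.0

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if name not in PARAMETER_NAMES:
                raise ValidationError(f"bounds given for unknown parameter {name!r}")
            if not (0 < lo < hi) and name != "f":
                raise ValidationError(f"invalid bounds for {name}: ({lo}, {hi})")
        # order relations: known symbols, strict '>', acyclic
        graph: dict[str, list[str]] = {}
        for rel in self.order_relations:
            a, op, b = rel
            if op != ">":
                raise ValidationError(f"only '>' relations are supported, got {rel}")
            for s in (a, b):
                if s not in PARAMETER_NAMES:
                    raise ValidationError(f"order relation uses unknown parameter {s!r}")
            graph.setdefault(a, []).append(b)
        state: dict[str, int] = {}

        def visit(node):
            state[node] = 1
            for nxt in graph.get(node, []):
                if state.get(nxt) == 1:
                    raise ValidationError(
                        f"order relations are cyclic through {node!r} and {nxt!r}"
                    )
                if state.get(nxt) is None:
                    visit(nxt)
            state[node] = 2

        for node in list(graph):
            if state.get(node) is None:
                visit(node)
        # feasibility: for A > B the boxes must overlap the half-plane
        for a, _, b in self.order_relations:
            if self.bounds[a][1] <= self.bounds[b][0]:
                raise ValidationError(
                    f"relation {a} > {b} infeasible under bounds "
                    f"{self.bounds[a]} vs {self.bounds[b]}"
                )
        if not (0 < self.km_inv_band[0] <= 1 <= self.km_inv_band[1]):
            raise ValidationError(f"km_inv_band must bracket 1, got {self.km_inv_band}")
        if self.cohesion_factor < 1:
            raise ValidationError("cohesion_factor must be >= 1")

    def with_pgi_preset(self, preset: str) -> "ConstraintSet":
        if preset not in PGI_ORDER_PRESETS:
            raise ValidationError(
                f"unknown PGI order preset {preset!r}; available: {sorted(PGI_ORDER_PRESETS)}"
            )
        return ConstraintSet(
            bounds=dict(self.bounds),
            order_relations=self.order_relations + PGI_ORDER_PRESETS[preset],
            km_inv_band=self.km_inv_band,
            cohesion_factor=self.cohesion_factor,
        )

    def satisfied_by(self, params: KineticParameters) -> list[str]:
        """Names of violated within-condition rules (empty = all pass)."""
        violations = []
        d = params.as_dict()
        for name, (lo, hi) in self.bounds.items():
            if not (lo <= d[name] <= hi):
                violations.append(f"bound {name} in [{lo}, {hi}]: value {d[name]:.4g}")
        for a, _, b in self.order_relations:
            if not d[a] > d[b]:
                violations.append(
                    f"order {a} > {b}: {d[a]:.4g} vs {d[b]:.4g}"
                )
        ratio = d["Km_INV"] / d["Km_FRCK"]
        if not (self.km_inv_band[0] <= ratio <= self.km_inv_band[1]):
            violations.append(
                f"Km_INV/Km_FRCK = {ratio:.4g} outside band {self.km_inv_band}"
            )
        return violations


@dataclass(frozen=True)
class ConditionObservations:
    """Steady-state observations for one condition.

    ``concentrations`` maps each of the five pools to (value, dispersion)
    in µmol gDW⁻¹; ``flux_targets`` optionally maps flux names (e.g.
    rNPS from gas exchange, rSTAsyn from the net starch balance) to
    (value, dispersion) in µmol gDW⁻¹ h⁻¹. Dispersions are relative
    (coefficients of variation).
    """

    condition: str
    concentrations: dict[str, tuple[float, float]]
    flux_targets: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        missing = set(STATE_NAMES) - set(self.concentrations)
        if missing:
            raise ValidationError(
                f"observations for {self.condition} missing metabolites: {sorted(missing)}"
            )
        for name, (v, s) in {**self.concentrations, **self.flux_targets}.items():
            if not (v > 0 and s > 0):
                raise ValidationError(
                    f"observation {name} of {self.condition} must have positive "
                    f"value and dispersion, got ({v}, {s})"
                )
        for name in self.flux_targets:
            if name not in _FLUX_INDEX:
                raise ValidationError(f"unknown flux target {name!r}")


@dataclass
class FitResult:
    params: KineticParameters
    score: float
    steady_state: MetaboliteState
    n_starts: int
    start_scores: list[float]
    violations: list[str]
    seed: int

    @property
    def success(self) -> bool:
        return math.isfinite(self.score) and not self.violations


_PENALTY_SCALE = 1e3


def _residuals(log_theta, obs: ConditionObservations, constraints: ConstraintSet,
               mode: str, guess: np.ndarray):
    theta = np.exp(log_theta)
    kw = dict(zip(FITTED_PARAMETERS, theta))
    # soft-clip the box-constrained fractions (optimizer bounds keep them in range)
    try:
        params = KineticParameters(k_STAdeg=0.0, **kw)
    except ValidationError:
        return np.full(_n_residuals(obs, constraints), 1e3)
    try:
        ss = find_steady_state(
            params, MetaboliteState.from_array(guess), mode=mode,
            tol=1e-8, skip_integration=True,
        )
    except ConvergenceError:
        try:
            ss = find_steady_state(params, mode=mode, tol=1e-8, t_long=2e3)
        except ConvergenceError:
            return np.full(_n_residuals(obs, constraints), 1e3)
    y = ss.as_array()
    flux = _flux_array(y, params)
    res = []
    for i, name in enumerate(STATE_NAMES):
        v, s = obs.concentrations[name]
        w = 1.0 / s
        res.append(w * math.log(max(y[i], 1e-12) / v))
    for name, (v, s) in obs.flux_targets.items():
        w = 1.0 / s
        res.append(w * math.log(max(flux[_FLUX_INDEX[name]], 1e-12) / v))
    # hinge penalties keep the hard order relations feasible
    d = params.as_dict()
    for a, _, b in constraints.order_relations:
        res.append(_PENALTY_SCALE * max(0.0, math.log(d[b] / d[a])))
    lo, hi = constraints.km_inv_band
    ratio = d["Km_INV"] / d["Km_FRCK"]
    res.append(_PENALTY_SCALE * max(0.0, math.log(lo / ratio)))
    res.append(_PENALTY_SCALE * max(0.0, math.log(ratio / hi)))
    return np.array(res)


def _n_residuals(obs, constraints):
    return 5 + len(obs.flux_targets) + len(constraints.order_relations) + 2


def _informed_start(obs: ConditionObservations, constraints: ConstraintSet,
                    rng: np.random.Generator) -> np.ndarray:
    """Start point that pins the analytically identifiable first-order
    constants to their flux/concentration ratios where targets exist."""
    log_lo = np.log([constraints.bounds[p][0] for p in FITTED_PARAMETERS])
    log_hi = np.log([constraints.bounds[p][1] for p in FITTED_PARAMETERS])
    x = 0.5 * (log_lo + log_hi)
    conc = {k: v for k, (v, _) in obs.concentrations.items()}
    ft = {k: v for k, (v, _) in obs.flux_targets.items()}
    direct = {}
    if "rNPS" in ft:
        direct["k_NPS"] = 6.0 * ft["rNPS"]
    if "r1" in ft:
        direct["k1_exp"] = ft["r1"] / conc["Suc"]
    if "r2" in ft:
        direct["k2_exp"] = ft["r2"] / conc["F6P"]
    if "rSTAsyn" in ft:
        direct["k_STA"] = ft["rSTAsyn"] / conc["G6P"]
    if "rANTHO" in ft:
        direct["k_ANT"] = ft["rANTHO"] / conc["F6P"]
    for name, val in direct.items():
        i = FITTED_PARAMETERS.index(name)
        x[i] = np.clip(math.log(val), log_lo[i], log_hi[i])
    return x


def fit_condition(
    observations: ConditionObservations,
    constraints: ConstraintSet | None = None,
    seed: int = 0,
    n_starts: int = 50,
    mode: str = "scheme-consistent",
    max_nfev: int = 120,
) -> FitResult:
    """Fit one condition's parameters by bounded multi-start least squares.

    Starts are Latin-hypercube draws in log-bound space (plus one
    informed start pinning analytically identifiable rate constants);
    each start runs a trust-region reflective solve of the weighted
    log-residuals. The best feasible solution (bounds and order
    relations satisfied) is returned; the multi-start best score is
    monotonically non-increasing in the number of starts. Deterministic
    given ``seed``.
    """
    if constraints is None:
        constraints = ConstraintSet()
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    log_lo = np.log([constraints.bounds[p][0] for p in FITTED_PARAMETERS])
    log_hi = np.log([constraints.bounds[p][1] for p in FITTED_PARAMETERS])
    guess = np.array([observations.concentrations[n][0] for n in STATE_NAMES])

    starts = [_informed_start(observations, constraints, rng)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(FITTED_PARAMETERS),
                                     seed=int(rng.integers(2**31 - 1)))
        unit = sampler.random(n_starts - 1)
        starts.extend(log_lo + unit * (log_hi - log_lo))

    best = None
    start_scores = []
    for x0 in starts:
        try:
            sol = least_squares(
                _residuals, np.clip(x0, log_lo, log_hi),
                bounds=(log_lo, log_hi),
                args=(observations, constraints, mode, guess),
                method="trf", max_nfev=max_nfev, xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            score = float(np.sum(sol.fun**2))
        except Exception as err:  # pragma: no cover - defensive
            start_scores.append(float("inf"))
            warnings.warn(f"start failed: {err}", stacklevel=2)
            continue
        start_scores.append(score)
        theta = np.exp(sol.x)
        params = KineticParameters(k_STAdeg=0.0, **dict(zip(FITTED_PARAMETERS, theta)))
        if constraints.satisfied_by(params):
            continue  # infeasible start result; try others
        if best is None or score < best[0]:
            best = (score, params)

    if best is None:
        raise ConvergenceError(
            "no feasible fit found in any start; per-start scores: "
            + ", ".join(f"{s:.3g}" for s in start_scores)
        )
    score, params = best
    try:
        ss = find_steady_state(params, MetaboliteState.from_array(guess),
                               mode=mode, tol=1e-8, skip_integration=True)
    except ConvergenceError:
        ss = find_steady_state(params, mode=mode, tol=1e-8)
    return FitResult(
        params=params, score=score, steady_state=ss,
        n_starts=len(starts), start_scores=start_scores,
        violations=constraints.satisfied_by(params), seed=seed,
    )


@dataclass
class ConstraintReport:
    per_condition: dict[str, list[str]]
    cohesion_failures: list[str]

    @property
    def passed(self) -> bool:
        return not self.cohesion_failures and not any(self.per_condition.values())


def check_constraints(
    params_by_condition: dict[str, KineticParameters],
    constraints: ConstraintSet | None = None,
) -> ConstraintReport:
    """Verify order relations per condition and the ≤ cohesion-factor
    max/min spread of every Km/Ki symbol across conditions."""
    if constraints is None:
        constraints = ConstraintSet()
    if not params_by_condition:
        raise ValidationError("at least one condition is required")
    per_condition = {
        cond: constraints.satisfied_by(p) for cond, p in params_by_condition.items()
    }
    cohesion = []
    for sym in _KM_KI:
        vals = np.array([getattr(p, sym) for p in params_by_condition.values()])
        spread = float(vals.max() / vals.min())
        if spread > constraints.cohesion_factor:
            cohesion.append(
                f"{sym}: max/min spread {spread:.3g} exceeds "
                f"{constraints.cohesion_factor:g} "
                f"(min {vals.min():.4g}, max {vals.max():.4g})"
            )
    return ConstraintReport(per_condition=per_condition, cohesion_failures=cohesion)
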