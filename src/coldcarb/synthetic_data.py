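"""Synthetic condition grids emulating the cold-acclimation study design.

The generator produces a genotype × day grid of ground-truth parameter
sets (default 5 genotypes × 5 sampling days = 25 conditional
realizations), each satisfying the calibration constraint set by
construction: Km/Ki values are drawn with a per-condition log-uniform
jitter capped so that each symbol's cross-condition spread stays within
the cohesion factor (one order of magnitude by default), mutant
genotypes get multiplicative defects on their affected rate constants,
and a log-linear drift of the influx and enzyme capacities across days
mimics acclimation (a cold-shock drop on day 1 followed by partial
recovery). Every condition is solved to steady state and noisy
observations are generated with multiplicative lognormal noise.

The generator supplies statistical structure for testing the pipeline;
it makes no attempt to reproduce the published fitted parameter values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ConditionObservations, ConstraintSet
from .kinetic_model import (
    DAYS,
    GENOTYPES,
    ConditionRealization,
    ConvergenceError,
    KineticParameters,
    ValidationError,
    compute_fluxes,
    find_steady_state,
)
from .sensitivity import MEASURES, SensitivityMatrix

#: Base (day-0, wild-type-like) parameter set the per-condition draws
#: jitter around. Concentrations it implies sit in the observed few to
#: tens of µmol gDW⁻¹ range; first-order export/synthesis constants are
#: fractions per hour; the influx k_NPS/6 = 5 µmol gDW⁻¹ h⁻¹.
BASE_PARAMETERS = KineticParameters(
    k_NPS=30.0,
    vmax_SPS=30.0, Km_a_SPS=5.0, Km_b_SPS=5.0, Ki_SPS=10.0, k_udp=0.35,
    vmax_FRCK=40.0, Km_FRCK=6.0, Ki_FRCK=12.0,
    vmax_GLCK=40.0, Km_GLCK=2.0, Ki_GLCK=12.0,
    vmax_INV=15.0, Km_INV=5.0, Ki_INV1=10.0, Ki_INV2=10.0,
    vmax_PGI=25.0, Km_PGI=3.0, Ki_PGI=10.0, f=0.5,
    k1_exp=0.4, k2_exp=0.5, k_STA=0.4, k_ANT=0.1,
    k_STAdeg=0.0,
)

#: Multiplicative genotype defects on the affected rate constants:
#: flavonoid-pathway mutants lose anthocyanin synthesis capacity (and
#: divert less carbon through the secondary export), starch mutants
#: carry a reduced net starch-synthesis constant — a strong defect for
#: the synthesis-deficient archetype, a milder one for the
#: degradation-deficient archetype whose k_STA only absorbs the net
#: balance. The 0.25 floor keeps the G6P pool of the starch-deficient
#: archetype within the experimentally observed order of magnitude.
#: A fixture convention, not fitted.
GENOTYPE_EFFECTS: dict[str, dict[str, float]] = {
    "Col-0": {},
    "chs": {"k_ANT": 0.1, "k2_exp": 0.5},
    "f3h": {"k_ANT": 0.1, "k2_exp": 0.5},
    "bam3": {"k_STA": 0.5},
    "pgm1": {"k_STA": 0.25},
}

#: Day multipliers on the influx and vmax capacities: cold shock on
#: day 1 halves photosynthetic capacity, acclimation partially recovers
#: it over two weeks (log-linear in day).
def _day_capacity_multiplier(day: float) -> float:
    if day <= 0:
        return 1.0
    return 0.5 * (1.0 + 0.25 * math.log1p(day) / math.log1p(14))


_JITTERED = [
    "vmax_SPS", "vmax_FRCK", "vmax_GLCK", "vmax_INV", "vmax_PGI",
    "k1_exp", "k2_exp", "k_STA", "k_ANT", "k_NPS",
]
_CAPACITY = ["k_NPS", "vmax_SPS", "vmax_FRCK", "vmax_GLCK", "vmax_INV", "vmax_PGI"]


@dataclass
class SyntheticStudy:
    """Ground-truth condition grid with noisy observations."""

    realizations: list[ConditionRealization]
    observations: dict[str, ConditionObservations]
    constraints: ConstraintSet
    config: dict = field(default_factory=dict)

    @property
    def genotypes(self) -> list[str]:
        return sorted({r.genotype for r in self.realizations})

    @property
    def days(self) -> list[int]:
        return sorted({r.day for r in self.realizations})

    def params_by_condition(self) -> dict[str, KineticParameters]:
        return {r.label: r.params for r in self.realizations}

    def parameter_table(self) -> pd.DataFrame:
        rows = []
        for r in self.realizations:
            rows.append({"genotype": r.genotype, "day": r.day, **r.params.as_dict()})
        return pd.DataFrame(rows)

    def observation_table(self) -> pd.DataFrame:
        rows = []
        for cond, obs in self.observations.items():
            for name, (v, s) in obs.concentrations.items():
                rows.append({"condition": cond, "measure": name, "value": v,
                             "dispersion": s, "unit": "umol_gDW-1"})
            for name, (v, s) in obs.flux_targets.items():
                rows.append({"condition": cond, "measure": name, "value": v,
                             "dispersion": s, "unit": "umol_gDW-1_h-1"})
        return pd.DataFrame(rows)


def _draw_km_ki(base: dict[str, float], constraints: ConstraintSet,
                rng: np.random.Generator) -> dict[str, float]:
    """Per-condition jitter of Km/Ki values.

    One shared log-uniform condition factor plus a small per-symbol
    factor; the split is chosen so that (i) any symbol's cross-condition
    spread stays below the cohesion factor and (ii) the base set's
    order-relation and ratio-band margins survive the per-symbol part
    — so every draw satisfies the constraint set by construction.
    """
    c = constraints.cohesion_factor
    per_symbol = min(1.3, math.sqrt(math.sqrt(c)))      # small independent part
    shared_half = math.sqrt(c) / per_symbol             # shared part: remainder
    g = math.exp(rng.uniform(-math.log(shared_half), math.log(shared_half)))
    out = {}
    for name in base:
        if not name.startswith(("Km", "Ki")):
            continue
        lo, hi = constraints.bounds[name]
        e = math.exp(rng.uniform(-math.log(per_symbol), math.log(per_symbol)))
        out[name] = float(np.clip(base[name] * g * e, lo, hi))
    return out


def generate_study(
    n_genotypes: int = 5,
    n_days: int = 5,
    constraints: ConstraintSet | None = None,
    noise_cv: float = 0.1,
    seed: int = 0,
    flux_targets: tuple[str, ...] = ("rNPS", "r1", "r2", "rSTAsyn", "rANTHO"),
    redraw_budget: int = 10,
) -> SyntheticStudy:
    """Generate a genotype × day grid of ground-truth realizations.

    Observations carry multiplicative lognormal noise with coefficient
    of variation ``noise_cv`` (0 gives noise-free observations equal to
    the true steady states). Fully reproducible from ``seed``.
    """
    if n_genotypes < 1 or n_days < 1:
        raise ValidationError("need at least one genotype and one day")
    if not (0 <= noise_cv < 1):
        raise ValidationError(f"noise_cv must lie in [0, 1), got {noise_cv}")
    if constraints is None:
        constraints = ConstraintSet()
    genotypes = list(GENOTYPES[:n_genotypes]) + [
        f"geno{i}" for i in range(len(GENOTYPES), n_genotypes)
    ]
    days = list(DAYS[:n_days]) + [
        14 + 7 * (i - len(DAYS) + 1) for i in range(len(DAYS), n_days)
    ]
    rng = np.random.default_rng(seed)
    base = BASE_PARAMETERS.as_dict()
    sigma = math.sqrt(math.log(1 + noise_cv**2)) if noise_cv > 0 else 0.0

    realizations: list[ConditionRealization] = []
    observations: dict[str, ConditionObservations] = {}
    for genotype in genotypes:
        for day in days:
            last_err: Exception | None = None
            for _ in range(redraw_budget):
                d = dict(base)
                d.update(_draw_km_ki(base, constraints, rng))
                cap = _day_capacity_multiplier(day)
                for name in _CAPACITY:
                    d[name] *= cap
                for name in _JITTERED:
                    d[name] *= math.exp(rng.uniform(-0.2, 0.2))
                for name, mult in GENOTYPE_EFFECTS.get(genotype, {}).items():
                    d[name] *= mult
                d["f"] = float(np.clip(0.5 + rng.uniform(-0.15, 0.15), *constraints.bounds["f"]))
                d["k_udp"] = float(rng.uniform(0.25, 0.45))
                for name in _JITTERED:
                    d[name] = float(np.clip(d[name], *constraints.bounds[name]))
                d["k_STAdeg"] = 0.0
                try:
                    params = KineticParameters(**d)
                    ss = find_steady_state(params, tol=1e-9)
                    realization = ConditionRealization(
                        genotype=genotype, day=day, params=params, steady_state=ss,
                    )
                except (ConvergenceError, ValidationError) as err:
                    last_err = err
                    continue
                break
            else:
                raise ConvergenceError(
                    f"no steady-state realization found for {genotype} day {day} "
                    f"within {redraw_budget} redraws; last error: {last_err}"
                )
            realizations.append(realization)
            fluxes = compute_fluxes(realization.steady_state, realization.params).as_dict()
            conc = {}
            for name, true in realization.steady_state.as_dict().items():
                noisy = true * math.exp(rng.normal(0.0, sigma)) if sigma else true
                conc[name] = (noisy, max(noise_cv, 0.05))
            ft = {}
            for name in flux_targets:
                true = fluxes[name]
                if true <= 0:
                    continue
                noisy = true * math.exp(rng.normal(0.0, sigma)) if sigma else true
                ft[name] = (noisy, max(noise_cv, 0.05))
            observations[realization.label] = ConditionObservations(
                condition=realization.label, concentrations=conc, flux_targets=ft,
            )

    return SyntheticStudy(
        realizations=realizations,
        observations=observations,
        constraints=constraints,
        config={
            "seed": seed, "n_genotypes": n_genotypes, "n_days": n_days,
            "noise_cv": noise_cv, "flux_targets": list(flux_targets),
            "noise_model": "lognormal-multiplicative",
        },
    )


def planted_sensitivity_matrix(
    n_conditions: int = 25,
    n_measures: int = 14,
    planted_structure: dict | None = None,
    seed: int = 0,
) -> SensitivityMatrix:
    """Sensitivity matrix with declared low-rank + noise structure.

    ``planted_structure`` keys:
      ``rank1_scale`` — sd of the scores along a planted dominant
        direction;
      ``noise_scale`` — isotropic noise sd (0 for exact low rank);
      ``day0_shift`` — shift (in sd units of the planted scores) of the
        day-0 conditions along the dominant direction;
      ``baseline`` — offset keeping entries positive;
      ``direction`` — optional explicit unit direction (length
        n_measures); drawn Gaussian and normalized when absent;
      ``scale`` — ``"linear"`` plants baseline + structure additively,
        ``"log"`` plants the structure on log values (entries are
        baseline · exp(structure), the natural scale for positive
        scores subjected to multiplicative noise).
    Conditions are labelled with a synthetic genotype × day grid.
    """
    if n_measures > len(MEASURES):
        raise ValidationError(
            f"n_measures must be <= {len(MEASURES)} (the reported measure set)"
        )
    if n_conditions < 2:
        raise ValidationError("need at least 2 conditions")
    ps = {"rank1_scale": 1.0, "noise_scale": 0.05, "day0_shift": 0.0,
          "baseline": 2.0, "direction": None, "scale": "linear"}
    ps.update(planted_structure or {})
    if ps["scale"] not in ("linear", "log"):
        raise ValidationError(f"unknown planted scale {ps['scale']!r}")
    rng = np.random.default_rng(seed)
    n_days = 5
    days = [DAYS[i % n_days] for i in range(n_conditions)]
    genotypes = [f"g{i // n_days}" for i in range(n_conditions)]
    labels = [f"{g}_day{d}" for g, d in zip(genotypes, days)]

    if ps["direction"] is None:
        direction = rng.normal(size=n_measures)
    else:
        direction = np.asarray(ps["direction"], dtype=float)
        if direction.shape != (n_measures,):
            raise ValidationError(
                f"direction must have length {n_measures}, got {direction.shape}"
            )
    direction = direction / np.linalg.norm(direction)
    scores = rng.normal(size=n_conditions) * ps["rank1_scale"]
    shift = ps["day0_shift"] * max(ps["rank1_scale"], 1e-12)
    scores = scores + shift * (np.array(days) == 0)
    structure = (
        np.outer(scores, direction)
        + rng.normal(size=(n_conditions, n_measures)) * ps["noise_scale"]
    )
    if structure.shape != (n_conditions, n_measures):
        raise ValidationError("inconsistent planted dimensions")
    if ps["scale"] == "log":
        data = ps["baseline"] * np.exp(structure)
    else:
        data = np.abs(ps["baseline"] + structure)
    values = pd.DataFrame(data, index=labels, columns=list(MEASURES[:n_measures]))
    if n_measures < len(MEASURES):
        for m in MEASURES[n_measures:]:
            values[m] = ps["baseline"]
    values = values[list(MEASURES)]
    meta = pd.DataFrame({"genotype": genotypes, "day": days}, index=labels)
    return SensitivityMatrix(values=values, meta=meta, protocol=None)
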