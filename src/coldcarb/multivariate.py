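"""Standardized PCA of sensitivity profiles and its noise-robustness test.

Each condition's 14 sensitivity scores form one row; columns are
standardized to zero mean and unit variance before a full singular
value decomposition. Components are reported with explained-variance
fractions over all components and with a fixed sign convention (the
sucrose loading is made non-positive wherever it is nonzero) so that
loadings are comparable across runs.

The day-0 separation statistic quantifies how far the pre-acclimation
(day 0) conditions sit from all cold days along PC1; the robustness
test re-runs the PCA under repeated multiplicative lognormal noise on
the sensitivity scores and reports how often that separation survives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .kinetic_model import ValidationError
from .sensitivity import SensitivityMatrix


@dataclass
class PCAResult:
    """Loadings, explained-variance fractions and per-condition scores."""

    loadings: pd.DataFrame          # components × measures, unit-norm rows
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame            # conditions × components
    sign_flips: dict[str, int]      # component -> ±1 applied
    dropped_columns: list[str]
    meta: pd.DataFrame | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def pca_on_gamma(matrix: SensitivityMatrix) -> PCAResult:
    """Column-standardized PCA of a sensitivity matrix.

    Conditions with undefined (NaN) scores are excluded with a warning;
    zero-variance measures cannot be standardized and are dropped with
    a warning. All components are kept, so the explained-variance
    fractions sum to 1.
    """
    matrix = matrix.dropna()
    values = matrix.values
    if values.shape[0] < 2:
        raise ValidationError("PCA requires at least 2 conditions")
    sd = values.std(axis=0, ddof=0)
    dropped = list(values.columns[sd == 0.0])
    if dropped:
        warnings.warn(f"dropping zero-variance measure(s): {dropped}", stacklevel=2)
        values = values.drop(columns=dropped)
    X = StandardScaler().fit_transform(values.to_numpy(dtype=float))
    pca = PCA(n_components=None, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_

    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[0])]
    suc_idx = list(values.columns).index("Suc") if "Suc" in values.columns else None
    flips: dict[str, int] = {}
    for i, name in enumerate(comp_names):
        if suc_idx is not None and loadings[i, suc_idx] != 0.0:
            flip = -1 if loadings[i, suc_idx] > 0 else 1
        else:
            j = int(np.argmax(np.abs(loadings[i])))
            flip = -1 if loadings[i, j] > 0 else 1
        flips[name] = flip
        loadings[i] *= flip
        scores[:, i] *= flip

    return PCAResult(
        loadings=pd.DataFrame(loadings, index=comp_names, columns=values.columns),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        scores=pd.DataFrame(scores, index=values.index, columns=comp_names),
        sign_flips=flips,
        dropped_columns=dropped,
        meta=matrix.meta,
    )


@dataclass
class SeparationResult:
    statistic: float
    silhouette: float
    low_confidence: bool

    def __float__(self) -> float:
        return self.statistic


def day0_separation(result: PCAResult, labels=None) -> SeparationResult:
    """Standardized distance of day-0 conditions from all others on PC1.

    Returns |mean(PC1 | day 0) − mean(PC1 | other days)| divided by the
    pooled within-group standard deviation of the PC1 scores, plus a
    silhouette score of the two groups along PC1. Invariant to the PC1
    sign convention and to condition ordering. A group with fewer than
    two members flags the result as low-confidence.
    """
    if labels is None:
        if result.meta is None or "day" not in result.meta:
            raise ValidationError("day labels required (none stored in the result)")
        labels = result.meta["day"]
    labels = np.asarray(labels)
    pc1 = result.scores["PC1"].to_numpy()
    if labels.shape[0] != pc1.shape[0]:
        raise ValidationError(
            f"{labels.shape[0]} labels for {pc1.shape[0]} conditions"
        )
    is0 = labels == 0
    a, b = pc1[is0], pc1[~is0]
    if a.size == 0 or b.size == 0:
        raise ValidationError("both a day-0 group and a non-day-0 group are required")
    low_conf = a.size < 2 or b.size < 2
    na, nb = a.size, b.size
    var_a = a.var(ddof=1) if na > 1 else 0.0
    var_b = b.var(ddof=1) if nb > 1 else 0.0
    dof = max(na + nb - 2, 1)
    pooled = math.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / dof)
    if pooled == 0.0:
        stat = math.inf if a.mean() != b.mean() else 0.0
    else:
        stat = abs(a.mean() - b.mean()) / pooled
    try:
        sil = float(silhouette_score(pc1.reshape(-1, 1), is0.astype(int)))
    except ValueError:
        sil = float("nan")
    return SeparationResult(statistic=float(stat), silhouette=sil,
                            low_confidence=low_conf)


@dataclass
class RobustnessResult:
    preservation_fraction: float
    baseline_statistic: float
    statistics: np.ndarray
    noise_level: float
    repetitions: int
    threshold_fraction: float


def robustness_test(
    matrix: SensitivityMatrix,
    labels=None,
    noise_level: float = 0.5,
    repetitions: int = 100,
    seed: int = 0,
    threshold_fraction: float = 0.5,
) -> RobustnessResult:
    """Fraction of noisy PCA repetitions preserving the day-0 separation.

    Each repetition multiplies every sensitivity score by an independent
    lognormal factor whose log-sd is set so the central 95 % of factors
    spans 1/(1+noise_level) … (1+noise_level), then redoes the PCA and
    the separation statistic. A repetition preserves the separation if
    its statistic stays above ``threshold_fraction`` times the
    noise-free value. Deterministic given ``seed``.
    """
    if repetitions < 1:
        raise ValidationError("repetitions must be >= 1")
    if noise_level < 0:
        raise ValidationError("noise_level must be >= 0")
    if labels is None:
        labels = matrix.meta["day"]
    base = day0_separation(pca_on_gamma(matrix), labels)
    sigma = math.log1p(noise_level) / 1.959963984540054
    rng = np.random.default_rng(seed)
    stats = np.empty(repetitions)
    for k in range(repetitions):
        factors = np.exp(rng.normal(0.0, sigma, size=matrix.values.shape))
        noisy = SensitivityMatrix(
            values=matrix.values * factors, meta=matrix.meta, protocol=matrix.protocol,
        )
        stats[k] = day0_separation(pca_on_gamma(noisy), labels).statistic
    preserved = float(np.mean(stats >= threshold_fraction * base.statistic))
    return RobustnessResult(
        preservation_fraction=preserved,
        baseline_statistic=base.statistic,
        statistics=stats,
        noise_level=noise_level,
        repetitions=repetitions,
        threshold_fraction=threshold_fraction,
    )
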