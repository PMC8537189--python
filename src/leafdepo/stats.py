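"""Species-comparison statistics and capacity clustering.

Replication unit is the leaf batch (three per species), so species effects
are tested by one-way fixed-effects ANOVA over batch-level values with
Tukey's HSD for pairwise contrasts.  Relationships between retention and
surface properties (contact angle, surface free energy) use Pearson
correlation and ordinary least-squares slopes.  Capacity grouping follows
the field convention: K-means into three clusters on the standardized
per-species density profile, relabelled so cluster 1 has the smallest and
cluster 3 the largest mean total PM.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .errors import ValidationError

#: Default clustering seed: the start date of the reference field campaign
#: (18 Dec 2018), recorded so runs are reproducible by construction.
DEFAULT_SEED = 20181218
DEFAULT_RESTARTS = 50


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int


def _check_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 species")
    out = {}
    for k, v in groups.items():
        arr = np.asarray(v, dtype=float)
        if arr.size < 2:
            raise ValidationError(f"species {k}: at least 2 replicates required")
        out[k] = arr
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across species groups."""
    g = _check_groups(groups)
    arrays = list(g.values())
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return AnovaResult(f=float(f), p=float(p), df_between=k - 1, df_within=n - k)


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise studentized-range comparisons at a fixed alpha."""

    alpha: float
    pvalues: dict[tuple[str, str], float]

    def significant(self, a: str, b: str) -> bool:
        key = (a, b) if (a, b) in self.pvalues else (b, a)
        return self.pvalues[key] < self.alpha

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        return sorted(k for k, p in self.pvalues.items() if p < self.alpha)


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey honestly-significant-difference test over all species pairs."""
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    g = _check_groups(groups)
    names = list(g)
    res = sps.tukey_hsd(*g.values())
    pvals = {
        (names[i], names[j]): float(res.pvalue[i, j])
        for i, j in combinations(range(len(names)), 2)
    }
    return TukeyResult(alpha=alpha, pvalues=pvals)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Correlation between two per-species variables, with the OLS slope.

    Pearson (default) or Spearman coefficient with a two-sided p-value;
    the regression slope/intercept always come from ordinary least squares
    of y on x.
    """
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.size != ya.size or xa.size < 3:
        raise ValidationError("paired samples of size >= 3 required")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("zero variance in x or y: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = sps.spearmanr(xa, ya)
    else:
        raise ValidationError(f"unknown method {method!r}")
    lr = sps.linregress(xa, ya)
    return CorrelationResult(
        r=float(r), p=float(p), slope=float(lr.slope),
        intercept=float(lr.intercept), n=int(xa.size),
    )


@dataclass(frozen=True)
class ClusterResult:
    """Species -> cluster label (1..k), ordered by mean total PM.

    Cluster 1 has the smallest mean total PM, cluster k the largest.
    Centers are in standardized feature space, reordered consistently.
    """

    labels: dict[str, int]
    centers: np.ndarray
    inertia: float


def kmeans_capacity_clusters(
    features: pd.DataFrame,
    totals: Sequence[float] | None = None,
    k: int = 3,
    seed: int = DEFAULT_SEED,
    n_restarts: int = DEFAULT_RESTARTS,
    standardize: bool = True,
) -> ClusterResult:
    """Group species into ``k`` capacity tiers by K-means.

    Parameters
    ----------
    features
        Species x variables table (per-species mg/m^2 densities of the
        8 inventory cells plus total PM, by convention).  Standardized to
        zero mean / unit variance per column unless ``standardize=False``
        (raw scales would let the coarse >10 um fraction dominate).
    totals
        Per-species total PM used to order the cluster labels; defaults to
        the row sums of ``features``.
    """
    if len(features) < k:
        raise ValidationError(f"need at least k={k} species, got {len(features)}")
    X = features.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(X)

    tot = np.asarray(totals, float) if totals is not None else features.sum(axis=1).to_numpy()
    order = np.argsort(
        [tot[raw == c].mean() if (raw == c).any() else np.inf for c in range(k)]
    )
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = {sp: relabel[int(c)] for sp, c in zip(features.index, raw)}
    centers = km.cluster_centers_[order]
    return ClusterResult(labels=labels, centers=centers, inertia=float(km.inertia_))
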