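"""Habitat typing, selection ratios, diversity of use and contrasts.

Habitats are typed two ways: a priori from physiognomy (wadi vs plain
labels carried by the transects) and a posteriori by Ward hierarchical
clustering of transect covariates — the habitat map as the animals'
covariate space partitions it.  Selection is quantified by Manly
standardized selection ratios B_i (the probability a species would pick
habitat i were all equally available); habitats with B_i >= 0.5 are key
resource areas.  Diversity of habitat use is the Shannon–Wiener index over
the B_i.  Wadi/plain covariate contrasts use the Wilcoxon rank-sum test
with midranks, exact by enumeration at small n.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = ["ward_cluster", "choose_k_silhouette", "selection_ratio",
           "key_resource_flags", "shannon_diversity", "partition_index",
           "wilcoxon_rank_sum", "HabitatPartition"]


def ward_cluster(covariates: pd.DataFrame, k: int, standardize: bool = True):
    """Assign transects to ``k`` habitats by Ward minimum-variance clustering.

    Covariates are optionally z-scored (constant columns are dropped with a
    warning, since they carry no distance information after scaling).
    Returns ``(labels, linkage_matrix)``; labels are 0-based and
    deterministic, and the linkage's merge heights are nondecreasing.
    """
    X = covariates.select_dtypes(include=[np.number]).to_numpy(float)
    n = X.shape[0]
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    if standardize:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            dropped = covariates.select_dtypes(include=[np.number]).columns[~keep]
            logger.warning("dropping constant covariate(s) under standardization: %s",
                           list(dropped))
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    return labels, Z


def choose_k_silhouette(covariates: pd.DataFrame, k_range=range(2, 9),
                        standardize: bool = True) -> int:
    """Pick the habitat count by maximum mean silhouette over ``k_range``."""
    X = covariates.select_dtypes(include=[np.number]).to_numpy(float)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= len(X):
            continue
        labels, _ = ward_cluster(covariates, k, standardize=standardize)
        s = silhouette_score(X, labels)
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def selection_ratio(use, availability=None) -> np.ndarray:
    """Manly standardized selection ratios B_i.

    ``use`` is density or count per habitat; ``availability`` the habitat
    availability proportions (defaults to equal).  w_i = use_i / a_i and
    B_i = w_i / sum_j w_j, so the B_i sum to one and B_i is the selection
    probability under equal availability.
    """
    u = np.asarray(use, float)
    if np.any(u < 0):
        raise ValueError("use values must be >= 0")
    if u.sum() == 0:
        raise ValueError("all-zero use: selection ratios undefined")
    if availability is None:
        a = np.full(len(u), 1.0 / len(u))
    else:
        a = np.asarray(availability, float)
        if np.any(a <= 0):
            raise ValueError("availability must be > 0")
        a = a / a.sum()
    w = u / a
    return w / w.sum()


def key_resource_flags(B, threshold: float = 0.5) -> np.ndarray:
    """Key-resource-area flags: standardized ratio at or above ``threshold``."""
    return np.asarray(B, float) >= threshold


def shannon_diversity(B, base: float | None = None) -> float:
    """Shannon–Wiener H' = -sum B_i log(B_i) over habitat-use proportions.

    ``base`` defaults to the natural log; zero proportions contribute zero.
    Raises if the proportions do not sum to one.
    """
    p = np.asarray(B, float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum():.6f}")
    p = p[p > 0]
    h = -np.sum(p * np.log(p))
    if base is not None:
        h /= np.log(base)
    return float(h)


def partition_index(d_oryx, d_gazelle, eps: float = 1e-12):
    """Per-habitat dominance: (density ratio, signed density difference).

    The ratio is max/min of the two species densities (guarded by ``eps``
    and flagged NaN when both are zero); the difference is oryx minus
    gazelle, so its sign says which species dominates the habitat.
    """
    d1 = np.atleast_1d(np.asarray(d_oryx, float))
    d2 = np.atleast_1d(np.asarray(d_gazelle, float))
    if np.any(d1 < 0) or np.any(d2 < 0):
        raise ValueError("densities must be >= 0")
    hi = np.maximum(d1, d2)
    lo = np.minimum(d1, d2)
    ratio = np.where((hi == 0) & (lo == 0), np.nan, hi / np.maximum(lo, eps))
    diff = d1 - d2
    if ratio.size == 1:
        return float(ratio[0]), float(diff[0])
    return ratio, diff


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def wilcoxon_rank_sum(x, y, exact_max_n: int = 12):
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test with midrank ties.

    Returns ``(W, p)`` where W is the Mann–Whitney statistic for ``x``
    (rank sum of x minus n_x(n_x+1)/2), which is half-integer under ties.
    For combined sample size at most ``exact_max_n`` the p-value is exact
    by enumerating every assignment of the pooled midranks to the two
    groups; otherwise a normal approximation with tie correction and
    continuity correction is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    rx = ranks[:nx].sum()
    W = rx - nx * (nx + 1) / 2.0

    if nx + ny <= exact_max_n:
        # enumerate all C(n, nx) splits of the midranks
        idx = np.arange(nx + ny)
        stats_all = np.array([
            ranks[list(comb)].sum() for comb in itertools.combinations(idx, nx)
        ])
        mean_r = stats_all.mean()
        obs_dev = abs(rx - mean_r)
        p = float(np.mean(np.abs(stats_all - mean_r) >= obs_dev - 1e-12))
        return float(W), min(p, 1.0)

    n = nx + ny
    mean_W = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var_W = nx * ny / 12.0 * (n + 1 - tie_term)
    if var_W == 0:
        return float(W), 1.0
    z = (abs(W - mean_W) - 0.5) / np.sqrt(var_W)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return float(W), min(p, 1.0)


@dataclass
class HabitatPartition:
    """A transect→habitat assignment with selection and diversity summaries."""

    assignment: pd.Series                  # transect_id -> habitat label
    availability: pd.Series                # habitat -> proportion (sums to 1)
    densities: pd.DataFrame                # habitat x species mean density
    selection: pd.DataFrame                # habitat x species B_i
    key_resource: pd.DataFrame             # habitat x species flags
    diversity: pd.Series                   # species -> H'

    @classmethod
    def from_assignment(cls, assignment: pd.Series,
                        density_by_transect: pd.DataFrame,
                        availability: pd.Series | None = None,
                        shannon_base: float | None = None,
                        key_threshold: float = 0.5):
        """Build the partition summary from per-transect species densities.

        ``density_by_transect`` is indexed by transect_id with one column
        per species.  Availability defaults to the proportion of transects
        per habitat (equal-effort design); pass mapped habitat areas to
        override.
        """
        habitats = sorted(pd.unique(assignment))
        dens = density_by_transect.groupby(assignment).mean().reindex(habitats)
        if availability is None:
            counts = assignment.value_counts()
            availability = (counts / counts.sum()).reindex(habitats)
        else:
            availability = availability.reindex(habitats)
            availability = availability / availability.sum()
        sel = pd.DataFrame(index=habitats, columns=dens.columns, dtype=float)
        for sp in dens.columns:
            sel[sp] = selection_ratio(dens[sp].to_numpy(),
                                      availability.to_numpy())
        key = sel.apply(lambda c: key_resource_flags(c.to_numpy(), key_threshold))
        div = pd.Series({sp: shannon_diversity(sel[sp].to_numpy(), shannon_base)
                         for sp in sel.columns})
        return cls(assignment=assignment, availability=availability,
                   densities=dens, selection=sel, key_resource=key,
                   diversity=div)
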