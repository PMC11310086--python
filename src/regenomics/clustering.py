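"""Time-course normalisation and soft clustering.

TMM between-sample normalisation, log/standardise transforms, fuzzy
c-means soft clustering of standardised profiles, cluster-number
selection by the minimum-centroid-distance curve, and temporal ordering
plus the major-cluster rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SoftClustering",
    "tmm_factors",
    "normalize_tmm",
    "transform_standardize",
    "fuzzy_cmeans",
    "select_cluster_number",
    "order_and_filter_major",
]


class ZeroLibraryError(ValueError):
    """A sample has zero total counts and cannot be normalised."""


@dataclass
class SoftClustering:
    """Result of fuzzy c-means clustering of gene expression profiles.

    Attributes
    ----------
    membership : DataFrame
        Genes x clusters membership weights; each row sums to 1.
    centroids : DataFrame
        Clusters x samples centroid profiles (standardised units).
    m : float
        Fuzzifier; m -> 1 approaches hard k-means, larger m softens.
    hard : Series
        Hard assignment per gene (argmax membership; ties -> lowest
        cluster index).
    converged : bool
        Whether the alternating updates reached the shift tolerance.
    order : list | None
        Temporal cluster order (earliest onset first), set by
        :func:`order_and_filter_major`.
    major : Series | None
        Boolean per cluster, True if the cluster passes the
        major-cluster rule.
    onset : Series | None
        Per cluster, index of the first sample where the centroid
        exceeds the onset threshold.
    peak : Series | None
        Per cluster, index of the sample where the centroid peaks.
    """

    membership: pd.DataFrame
    centroids: pd.DataFrame
    m: float
    hard: pd.Series
    converged: bool = True
    order: list | None = None
    major: pd.Series | None = None
    onset: pd.Series | None = None
    peak: pd.Series | None = None

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    def cluster_genes(self, cluster) -> list:
        """Genes hard-assigned to ``cluster``."""
        return list(self.hard.index[self.hard == cluster])


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def _quantile_by_lib(counts: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.array(
        [np.quantile(counts[:, j] / lib[j], p) for j in range(counts.shape[1])]
    )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one library against the reference library.

    Doubly trimmed (30% of M-values, 5% of A-values) weighted mean of
    log2 ratios of gene proportions, weights the inverse of the binomial
    delta-method variance of M. Genes with a zero in either library are
    excluded pairwise.
    """
    keep = (obs > 0) & (ref > 0)
    po = obs[keep] / n_obs
    pr = ref[keep] / n_ref
    if po.size == 0:
        return 1.0
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic variance of M under binomial sampling
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (
        n_ref * ref[keep]
    )
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = int(np.floor(n * logratio_trim)) + 1
    hi_l = n + 1 - lo_l
    lo_s = int(np.floor(n * sum_trim)) + 1
    hi_s = n + 1 - lo_s
    rank_m = pd.Series(m).rank(method="average").to_numpy()
    rank_a = pd.Series(a).rank(method="average").to_numpy()
    keep2 = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not np.any(keep2):
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors, one per sample.

    The reference sample is the one whose 75th-percentile count
    proportion is closest to the mean across samples. Factors are
    geometric-mean centred so their product is 1.

    Parameters
    ----------
    counts : DataFrame
        Genes x samples nonnegative counts (or TPM; any library-scale
        abundance works since proportions are used).

    Raises
    ------
    ZeroLibraryError
        If any sample has zero total counts.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = list(counts.columns[lib <= 0])
        raise ZeroLibraryError(f"samples with zero total counts: {bad}")
    f75 = _quantile_by_lib(x, lib)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    raw = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(x.shape[1])
        ]
    )
    centred = raw / np.exp(np.mean(np.log(raw)))
    return pd.Series(centred, index=counts.columns, name="tmm_factor")


def normalize_tmm(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Rescale columns to TPM-like units using effective library sizes.

    value / (library_size * factor) * 1e6.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    eff = lib * factors.reindex(counts.columns).to_numpy()
    return pd.DataFrame(
        x / eff * 1e6, index=counts.index, columns=counts.columns
    )


def transform_standardize(
    matrix: pd.DataFrame, factors: pd.Series | None = None
) -> tuple[pd.DataFrame, list]:
    """log2(x+1) transform then per-gene standardisation to mean 0, sd 1.

    If ``factors`` is given the matrix is TMM-normalised first.
    Zero-variance genes cannot be standardised; they are dropped and
    returned in the second element.

    Returns
    -------
    (standardised, dropped) : (DataFrame, list)
    """
    if factors is not None:
        matrix = normalize_tmm(matrix, factors)
    logged = np.log2(matrix.astype(float) + 1.0)
    sd = logged.std(axis=1, ddof=0)
    dropped = list(logged.index[sd <= 0])
    kept = logged.loc[sd > 0]
    if kept.empty:
        raise ValueError("all genes have zero variance")
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return z, dropped


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------

def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update: u_ij proportional to d_ij^(-2/(m-1))."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
    # genes coincident with a centroid: full membership there
    zero_rows, zero_cols = np.nonzero(d2 == 0)
    if zero_rows.size:
        u[zero_rows] = 0.0
        u[zero_rows, zero_cols] = 1.0
        u[zero_rows] /= u[zero_rows].sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    matrix: pd.DataFrame,
    n_clusters: int,
    m: float = 1.25,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SoftClustering:
    """Fuzzy c-means soft clustering of standardised expression profiles.

    Minimises sum_i sum_j u_ij^m ||x_i - c_j||^2 by alternating
    membership and centroid updates until the largest centroid shift
    falls below ``tol`` or ``max_iter`` iterations; deterministic given
    ``seed`` (centroids initialised from ``n_clusters`` distinct
    profiles).

    Non-convergence returns the best solution with ``converged=False``.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = matrix.to_numpy(dtype=float)
    n = x.shape[0]
    if n_clusters >= n:
        raise ValueError(f"n_clusters={n_clusters} must be < number of genes ({n})")
    # k-means++ seeding: spread initial centroids, far fewer bad local optima
    # than uniform random picks
    from sklearn.cluster import kmeans_plusplus

    centroids, _ = kmeans_plusplus(x, n_clusters, random_state=int(seed) % (2**32))
    centroids = centroids.astype(float)
    converged = False
    u = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        u = _fcm_memberships(d2, m)
        um = u**m
        new = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.max(np.abs(new - centroids))
        centroids = new
        if shift < tol:
            converged = True
            break
    labels = list(range(n_clusters))
    membership = pd.DataFrame(u, index=matrix.index, columns=labels)
    hard = pd.Series(
        np.argmax(u, axis=1), index=matrix.index, name="cluster"
    )
    return SoftClustering(
        membership=membership,
        centroids=pd.DataFrame(centroids, index=labels, columns=matrix.columns),
        m=m,
        hard=hard,
        converged=converged,
    )


def min_centroid_distance(clustering: SoftClustering) -> float:
    """Smallest pairwise Euclidean distance among cluster centroids."""
    c = clustering.centroids.to_numpy()
    d = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
    iu = np.triu_indices(c.shape[0], k=1)
    return float(d[iu].min())


def select_cluster_number(
    matrix: pd.DataFrame,
    c_range,
    m: float = 1.25,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster number from the minimum-centroid-distance curve.

    Fits fuzzy c-means for each C in ``c_range`` and records
    D_min(C), the smallest pairwise centroid distance. Past the true
    cluster number centroids start splitting real clusters and D_min
    collapses, so the selected C is the knee of the curve: the C
    immediately preceding the largest drop D_min(C) - D_min(C+1)
    (ties broken toward larger C). A range of length 1 is returned
    as-is.

    Returns
    -------
    (best_c, curve) : (int, DataFrame)
        ``curve`` has columns ``n_clusters`` and ``d_min`` for
        inspection or manual override.
    """
    cs = sorted(set(int(c) for c in c_range))
    if min(cs) < 2:
        raise ValueError("cluster numbers must be >= 2")
    dmin = [
        min_centroid_distance(fuzzy_cmeans(matrix, c, m=m, seed=seed)) for c in cs
    ]
    curve = pd.DataFrame({"n_clusters": cs, "d_min": dmin})
    if len(cs) == 1:
        return cs[0], curve
    drops = np.array([dmin[i] - dmin[i + 1] for i in range(len(cs) - 1)])
    # argmax of the drop, preferring the larger C on (near-)ties
    best = len(drops) - 1 - int(np.argmax(drops[::-1]))
    return cs[best], curve


# ---------------------------------------------------------------------------
# Temporal ordering and the major-cluster rule
# ---------------------------------------------------------------------------

def order_and_filter_major(
    clustering: SoftClustering,
    regenerating: pd.Series,
    enrichment: pd.DataFrame,
    onset_threshold: float = 0.0,
    alpha: float = 0.05,
) -> SoftClustering:
    """Order clusters temporally and flag major clusters.

    Onset of a cluster is the first sample (in biological time order)
    where its centroid exceeds ``onset_threshold`` (standardised units).
    Clusters are ordered by onset, ties by peak sample, then by cluster
    index. A cluster is *major* iff it has more than one enriched term
    (``enrichment`` rows with ``padj < alpha``) AND its centroid exceeds
    the threshold in more than one regenerating sample.

    Parameters
    ----------
    regenerating : Series
        Boolean per sample, aligned with the centroid columns; False
        marks non-regenerating controls.
    enrichment : DataFrame
        Per-cluster enrichment results with columns ``cluster`` and
        ``padj``.
    """
    if enrichment is None or not {"cluster", "padj"}.issubset(enrichment.columns):
        raise ValueError("enrichment table with columns cluster, padj is required")
    cent = clustering.centroids
    regen = regenerating.reindex(cent.columns).fillna(False).astype(bool)
    above = cent.to_numpy() > onset_threshold
    onset = pd.Series(
        [int(np.argmax(row)) if row.any() else len(row) for row in above],
        index=cent.index,
        name="onset",
    )
    peak = pd.Series(
        np.argmax(cent.to_numpy(), axis=1), index=cent.index, name="peak"
    )
    n_regen_expressed = pd.Series(
        (cent.loc[:, regen.to_numpy()].to_numpy() > onset_threshold).sum(axis=1),
        index=cent.index,
    )
    sig = enrichment[enrichment["padj"] < alpha]
    n_terms = sig.groupby("cluster").size().reindex(cent.index, fill_value=0)
    major = (n_terms > 1) & (n_regen_expressed > 1)
    order = sorted(cent.index, key=lambda c: (onset[c], peak[c], c))
    return SoftClustering(
        membership=clustering.membership,
        centroids=clustering.centroids,
        m=clustering.m,
        hard=clustering.hard,
        converged=clustering.converged,
        order=order,
        major=major.rename("major"),
        onset=onset,
        peak=peak,
    )
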