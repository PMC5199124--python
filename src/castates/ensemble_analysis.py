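"""Posterior-ensemble distances, clustering and cluster characterization.

The between-cell distance is information-theoretic: pool two cells'
particle ensembles, measure the empirical distribution of "my nearest
neighbor belongs to my own cell" over all pooled particles, and take the
Kullback-Leibler divergence of that two-category distribution from the
analytic permutation null (no difference between the two cells).
Well-separated ensembles have same-cell probability near one and a
large divergence; ensembles drawn from one distribution sit at the null
and score near zero.

Cells are then clustered by average-linkage hierarchy on the distance
matrix; the cluster count is chosen by a Calinski-Harabasz style
variance-ratio criterion computed with cluster medoids as centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

__all__ = [
    "EnsembleDistanceMatrix",
    "ClusterAssignment",
    "kl_distance",
    "pairwise_distances",
    "cluster",
    "variance_ratio",
    "characterize_clusters",
]


@dataclass(frozen=True)
class EnsembleDistanceMatrix:
    """Symmetric pairwise KL-based distances between cells (nats)."""

    d: np.ndarray
    cell_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.cell_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match cell_ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and nonnegative")

    def __len__(self) -> int:
        return len(self.cell_ids)


@dataclass
class ClusterAssignment:
    """Hierarchical clustering outcome with the selected cluster count."""

    labels: np.ndarray
    k: int
    linkage: np.ndarray
    ch_curve: dict[int, float]
    medoids: np.ndarray
    degenerate: bool = False
    weak: bool = False


def _extract(ens) -> np.ndarray:
    return np.asarray(getattr(ens, "particles", ens), dtype=float)


def _same_cell_counts(x1: np.ndarray, x2: np.ndarray) -> tuple[int, int]:
    """Nearest-neighbor same-cell / other-cell counts on the pooled pair."""
    pooled = np.vstack([x1, x2])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (pooled - mu) / sd
    labels = np.concatenate([np.zeros(len(x1), dtype=int),
                             np.ones(len(x2), dtype=int)])
    tree = cKDTree(z)
    dist, idx = tree.query(z, k=2)
    m = len(z)
    rows = np.arange(m)
    nn = np.where(idx[:, 0] == rows, idx[:, 1], idx[:, 0])
    same = int(np.sum(labels[nn] == labels))
    return same, m - same


def kl_distance(ens_i, ens_j, pseudo_count: float = 0.5) -> float:
    """KL divergence of the observed NN same-cell distribution from null.

    Both ensembles are pooled in per-pair standardized log10 space; the
    observed two-category distribution (same-cell vs other-cell nearest
    neighbor, aggregated over all particles of both cells) is compared
    with the analytic permutation expectation.  Zero counts receive
    ``pseudo_count`` regularization so fully separated ensembles get a
    large finite distance rather than infinity.
    """
    x1, x2 = _extract(ens_i), _extract(ens_j)
    if len(x1) == 0 or len(x2) == 0:
        raise ValueError("ensembles must be nonempty")
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("ensembles must share parameter dimensionality")
    same, diff = _same_cell_counts(x1, x2)
    m = same + diff
    n1, n2 = len(x1), len(x2)
    # analytic null: random permutation of cell identities over pooled
    # particles; the probability a particle's NN shares its identity
    p_null = (n1 * (n1 - 1) + n2 * (n2 - 1)) / ((n1 + n2) * (n1 + n2 - 1))
    if same == 0 or diff == 0:
        p_obs = (same + pseudo_count) / (m + 2 * pseudo_count)
    else:
        p_obs = same / m
    q = np.array([p_null, 1.0 - p_null])
    p = np.array([p_obs, 1.0 - p_obs])
    return float(np.sum(p * np.log(p / q)))


def pairwise_distances(ensembles, cell_ids=None,
                       pseudo_count: float = 0.5) -> EnsembleDistanceMatrix:
    """All-pairs :func:`kl_distance` matrix."""
    ensembles = list(ensembles)
    n = len(ensembles)
    if cell_ids is None:
        cell_ids = tuple(
            getattr(e, "cell_id", "") or f"cell{i}"
            for i, e in enumerate(ensembles))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kl_distance(ensembles[i], ensembles[j],
                                            pseudo_count=pseudo_count)
    return EnsembleDistanceMatrix(d=d, cell_ids=tuple(cell_ids))


def _medoid(indices: np.ndarray, d: np.ndarray) -> int:
    sub = d[np.ix_(indices, indices)]
    return int(indices[np.argmin(sub.sum(axis=1))])


def _ch_score(labels: np.ndarray, d: np.ndarray) -> float:
    """Calinski-Harabasz variance ratio with medoids as centers.

    Within dispersion: summed squared distances of members to their
    cluster medoid.  Between dispersion: size-weighted squared distances
    of cluster medoids to the global medoid.  Ratio normalized by the
    usual (n-k)/(k-1) degrees of freedom.
    """
    n = len(labels)
    ks = np.unique(labels)
    k = len(ks)
    if k < 2:
        return math.nan
    global_medoid = _medoid(np.arange(n), d)
    within = 0.0
    between = 0.0
    for lab in ks:
        members = np.nonzero(labels == lab)[0]
        med = _medoid(members, d)
        within += float(np.sum(d[members, med] ** 2))
        between += len(members) * float(d[med, global_medoid] ** 2)
    if within == 0:
        return math.inf if between > 0 else math.nan
    return (between / (k - 1)) / (within / (n - k))


def cluster(dmat: EnsembleDistanceMatrix,
            k_range=range(2, 11)) -> ClusterAssignment:
    """Average-linkage clustering with CH-medoid selection of k.

    The candidate producing the highest medoid-based Calinski-Harabasz
    score wins.  A zero distance matrix yields a degenerate single
    cluster; a CH curve whose maximum sits at a boundary of the scanned
    range with no interior peak is flagged weak.
    """
    d = dmat.d
    n = len(dmat)
    k_range = [k for k in k_range if 2 <= k <= n]
    if not k_range:
        raise ValueError("k_range contains no feasible candidate")
    if np.all(d == 0):
        return ClusterAssignment(
            labels=np.zeros(n, dtype=int), k=1,
            linkage=average(squareform(d, checks=False)),
            ch_curve={}, medoids=np.array([0]), degenerate=True)
    link = average(squareform(d, checks=False))
    ch_curve: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    eligible: set[int] = set()
    for k in k_range:
        labels = fcluster(link, t=k, criterion="maxclust") - 1
        uniq, sizes = np.unique(labels, return_counts=True)
        if len(uniq) < 2:
            continue
        labelings[k] = labels
        ch_curve[k] = _ch_score(labels, d)
        # singleton clusters contribute zero within-dispersion and blow
        # the ratio up spuriously at small n; bar them from selection
        if sizes.min() >= 2:
            eligible.add(k)
    if not ch_curve:
        return ClusterAssignment(
            labels=np.zeros(n, dtype=int), k=1, linkage=link,
            ch_curve={}, medoids=np.array([_medoid(np.arange(n), d)]),
            degenerate=True)
    pool = eligible if eligible else set(ch_curve)
    best_k = max(pool, key=lambda k: (ch_curve[k], -k))
    labels = labelings[best_k]
    medoids = np.array([
        _medoid(np.nonzero(labels == lab)[0], d)
        for lab in np.unique(labels)])
    finite = {k: v for k, v in ch_curve.items() if np.isfinite(v)}
    interior = [k for k in finite
                if min(k_range) < k < max(k_range)]
    weak = bool(finite) and (best_k in (min(k_range), max(k_range))) \
        and bool(interior)
    return ClusterAssignment(labels=labels, k=int(best_k), linkage=link,
                             ch_curve=ch_curve, medoids=medoids, weak=weak)


def variance_ratio(vectors: np.ndarray, labels: np.ndarray) -> float:
    """Between-group over within-group dispersion of per-cell vectors.

    Dispersion is the trace of the scatter matrices: between = size-
    weighted squared distances of group means from the grand mean,
    within = summed squared deviations of members from their group mean.
    """
    x = np.asarray(vectors, dtype=float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    if len(ks) < 2:
        raise ValueError("need at least two clusters")
    grand = x.mean(axis=0)
    between = 0.0
    within = 0.0
    singletons = True
    for lab in ks:
        members = x[labels == lab]
        if len(members) > 1:
            singletons = False
        mu = members.mean(axis=0)
        between += len(members) * float(np.sum((mu - grand) ** 2))
        within += float(np.sum((members - mu) ** 2))
    if within == 0:
        if singletons:
            raise ValueError("all clusters are singletons; ratio undefined")
        return math.inf if between > 0 else math.nan
    return between / within


def characterize_clusters(ensembles, labels,
                          parameter_names=None) -> "pd.DataFrame":
    """Per-cluster parameter summaries and per-parameter separation.

    For every parameter: per-cluster median and interquartile range of
    the per-cell ensemble medians, plus a separation score defined as
    the spread (SD) of cluster medians divided by the pooled
    within-cluster spread of cell medians.  Sorting by the score ranks
    the parameters that drive the clustering.
    """
    import pandas as pd

    from castates.model import PARAMETER_NAMES

    names = list(parameter_names) if parameter_names is not None \
        else list(PARAMETER_NAMES)
    cell_medians = np.array([np.median(_extract(e), axis=0)
                             for e in ensembles])
    labels = np.asarray(labels)
    ks = np.unique(labels)
    rows = []
    for p, name in enumerate(names):
        col = cell_medians[:, p]
        cluster_medians = []
        within_devs = []
        entry: dict[str, float | str] = {"parameter": name}
        for lab in ks:
            vals = col[labels == lab]
            med = float(np.median(vals))
            q75, q25 = np.percentile(vals, [75, 25])
            cluster_medians.append(med)
            within_devs.append(vals - med)
            entry[f"median_c{lab}"] = med
            entry[f"iqr_c{lab}"] = float(q75 - q25)
        pooled_sd = float(np.std(np.concatenate(within_devs)))
        spread = float(np.std(cluster_medians))
        entry["separation"] = spread / pooled_sd if pooled_sd > 0 \
            else math.inf if spread > 0 else 0.0
        rows.append(entry)
    df = pd.DataFrame(rows).set_index("parameter")
    return df.sort_values("separation", ascending=False)
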