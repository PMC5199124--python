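"""Dual-run convergence test via nearest-neighbor run identity.

Two independent SMC runs on the same cell should sample the same
posterior.  If they do, the nearest neighbor of any pooled particle is
equally likely to come from either run; a chi-square goodness-of-fit
test on the same-run/different-run counts decides convergence at
significance level alpha (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi2

__all__ = ["ConvergenceReport", "test_convergence", "nn_same_run_counts"]


@dataclass(frozen=True)
class ConvergenceReport:
    """Outcome of the nearest-neighbor run-identity test."""

    p_same_run: float
    chi2: float
    p_value: float
    converged: bool
    n1: int
    n2: int
    null_p: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_same_run <= 1.0:
            raise ValueError("p_same_run outside [0, 1]")


def _standardize(pooled: np.ndarray) -> np.ndarray:
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (pooled - mu) / sd


def nearest_neighbor_graph(z: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Index of each point's nearest neighbor, self excluded.

    Exact distance ties — which arise when SMC resampling duplicates
    particles — are broken uniformly at random.  For co-located
    duplicates (minimal distance exactly zero) the tie group includes
    the point itself; drawing self (``nn[i] == i``) marks the neighbor
    identity as uninformative, which keeps exact duplicates from
    biasing the run-identity test either way.
    """
    m = len(z)
    tree = cKDTree(z)
    k = min(m, 8)
    dist, idx = tree.query(z, k=k)
    nn = np.full(m, -1, dtype=int)

    # fast path: self is first, runner-up is a unique nearest neighbor
    simple = (idx[:, 0] == np.arange(m)) & (dist[:, 1] > 0)
    if k > 2:
        simple &= dist[:, 2] > dist[:, 1]
    nn[simple] = idx[simple, 1]

    for i in np.nonzero(~simple)[0]:
        d_row, i_row = dist[i], idx[i]
        own = i_row != i
        d_min = d_row[own][0]
        if d_row[-1] <= d_min:  # ties saturated the k-window: brute force
            d_all = np.linalg.norm(z - z[i], axis=1)
            d_all[i] = np.inf
            d_min = d_all.min()
            tied = list(np.nonzero(d_all == d_min)[0])
        else:
            tied = list(i_row[own][d_row[own] == d_min])
        if d_min == 0.0:
            tied.append(i)
        nn[i] = tied[rng.integers(len(tied))] if len(tied) > 1 else tied[0]
    return nn


def nn_same_run_counts(x1: np.ndarray, x2: np.ndarray,
                       rng: np.random.Generator | None = None
                       ) -> tuple[int, int]:
    """Count pooled particles whose nearest neighbor shares their run.

    Particles are z-scored on the pooled population before the Euclidean
    nearest-neighbor search.  A self neighbor (duplicate tie rule, see
    :func:`nearest_neighbor_graph`) counts as same-run.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pooled = np.vstack([x1, x2])
    labels = np.concatenate([np.zeros(len(x1), dtype=int),
                             np.ones(len(x2), dtype=int)])
    nn = nearest_neighbor_graph(_standardize(pooled), rng)
    same = int(np.sum(labels[nn] == labels))
    return same, len(nn) - same


def _ff(x: int, k: int) -> float:
    out = 1.0
    for i in range(k):
        out *= x - i
    return out


def _permutation_moments(nn: np.ndarray, n1: int, n2: int
                         ) -> tuple[float, float]:
    """Exact mean and variance of the same-run count under relabeling.

    Conditions on the realized nearest-neighbor graph and randomizes the
    run labels (n1 of one run, n2 of the other, without replacement).
    Covariances between the per-particle same-run indicators depend only
    on how the index pairs {i, nn(i)} and {j, nn(j)} overlap: mutual
    neighbors, one shared element, or disjoint.
    """
    m = len(nn)
    p0 = (_ff(n1, 2) + _ff(n2, 2)) / _ff(m, 2)
    p3 = (_ff(n1, 3) + _ff(n2, 3)) / _ff(m, 3)
    p4 = (_ff(n1, 4) + 2 * _ff(n1, 2) * _ff(n2, 2) + _ff(n2, 4)) / _ff(m, 4)
    mutual = int(np.sum(nn[nn] == np.arange(m)))
    counts = np.bincount(nn, minlength=m)
    shared_nn = int(np.sum(counts * (counts - 1)))
    share_one = 2 * (m - mutual) + shared_nn
    disjoint = m * (m - 1) - mutual - share_one
    mean = m * p0
    var = (m * p0 * (1 - p0)
           + mutual * (p0 - p0 ** 2)
           + share_one * (p3 - p0 ** 2)
           + disjoint * (p4 - p0 ** 2))
    return mean, var


def test_convergence(run1, run2, alpha: float = 0.05,
                     exact_null: bool = True,
                     variance: str = "permutation",
                     seed: int | np.random.Generator = 0
                     ) -> ConvergenceReport:
    """Decide whether two SMC runs sampled the same posterior.

    Parameters
    ----------
    run1, run2 : ParameterEnsemble or array of shape (n, d)
        The two runs' particles.
    alpha : float
        Significance level; convergence = failure to reject.
    exact_null : bool
        Use the finite-sample null same-run probability
        ``(n1*(n1-1) + n2*(n2-1)) / ((n1+n2)*(n1+n2-1))`` instead of the
        asymptotic 0.5.  With equal run sizes n this is (n-1)/(2n-1).
    variance : {"permutation", "multinomial"}
        Null variance of the same-run count.  ``"permutation"``
        conditions on the realized NN graph and is exactly calibrated;
        ``"multinomial"`` is the naive binomial chi-square, which is
        slightly anticonservative because NN indicators are correlated.

    Notes
    -----
    The statistic is (observed - expected)^2 / variance with 1 degree
    of freedom, no continuity correction; with ``"multinomial"`` this
    reduces to the standard two-category chi-square.
    """
    x1 = np.asarray(getattr(run1, "particles", run1), dtype=float)
    x2 = np.asarray(getattr(run2, "particles", run2), dtype=float)
    if x1.ndim != 2 or x2.ndim != 2 or x1.shape[1] != x2.shape[1]:
        raise ValueError("runs must be 2-D with equal dimensionality")
    if variance not in ("permutation", "multinomial"):
        raise ValueError(f"unknown variance mode {variance!r}")
    n1, n2 = len(x1), len(x2)
    if min(n1, n2) < 20:
        raise ValueError("each run needs at least 20 particles")
    if max(n1, n2) > 4 * min(n1, n2):
        import warnings
        warnings.warn("run sizes differ by more than 4:1; "
                      "the null probability is distorted", stacklevel=2)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    pooled = np.vstack([x1, x2])
    labels = np.concatenate([np.zeros(n1, dtype=int), np.ones(n2, dtype=int)])
    nn = nearest_neighbor_graph(_standardize(pooled), rng)
    same = int(np.sum(labels[nn] == labels))
    n = len(nn)
    p0 = ((n1 * (n1 - 1) + n2 * (n2 - 1)) / ((n1 + n2) * (n1 + n2 - 1))
          if exact_null else 0.5)

    has_self = bool(np.any(nn == np.arange(n)))
    if variance == "permutation" and not has_self:
        mean, var = _permutation_moments(nn, n1, n2)
        if exact_null is False:
            mean = n * 0.5
        stat = (same - mean) ** 2 / var if var > 0 else 0.0
    else:
        # self neighbors (duplicate degeneracy) fall back to the naive
        # two-category chi-square
        expected = np.array([n * p0, n * (1.0 - p0)])
        observed = np.array([same, n - same], dtype=float)
        stat = float(np.sum((observed - expected) ** 2 / expected))
    p_value = float(chi2.sf(stat, df=1))
    return ConvergenceReport(
        p_same_run=same / n, chi2=float(stat), p_value=p_value,
        converged=bool(p_value >= alpha), n1=n1, n2=n2,
        null_p=float(p0), alpha=float(alpha))
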