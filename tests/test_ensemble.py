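import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from castates.ensemble_analysis import (
    EnsembleDistanceMatrix,
    characterize_clusters,
    cluster,
    kl_distance,
    pairwise_distances,
    variance_ratio,
)
from castates.model import PARAMETER_NAMES


def brute_force_kl(x1, x2, pseudo=0.5):
    """Independent re-implementation: exhaustive NN loops, analytic null."""
    pooled = np.vstack([x1, x2])
    z = (pooled - pooled.mean(axis=0)) / np.where(
        pooled.std(axis=0) > 0, pooled.std(axis=0), 1.0)
    labels = [0] * len(x1) + [1] * len(x2)
    same = 0
    for i in range(len(z)):
        best, best_d = None, np.inf
        for j in range(len(z)):
            if j == i:
                continue
            d = np.sqrt(np.sum((z[i] - z[j]) ** 2))
            if d < best_d:
                best, best_d = j, d
        same += labels[best] == labels[i]
    m = len(z)
    n1, n2 = len(x1), len(x2)
    p_null = (n1 * (n1 - 1) + n2 * (n2 - 1)) / (m * (m - 1))
    diff = m - same
    if same == 0 or diff == 0:
        p_obs = (same + pseudo) / (m + 2 * pseudo)
    else:
        p_obs = same / m
    return (p_obs * math.log(p_obs / p_null)
            + (1 - p_obs) * math.log((1 - p_obs) / (1 - p_null)))


def gaussian_ensembles(rng, means, n_cells_per=5, n_particles=60,
                       center_sd=0.1, particle_sd=0.25):
    """Clouds of particle ensembles around the given 17-D means.

    ``center_sd`` spreads cells within a group; ``particle_sd`` spreads
    particles within a cell's ensemble.  Both large enough that
    within-group ensemble distances stay in the measure's responsive
    range rather than collapsing to zero.
    """
    ensembles, labels = [], []
    for g, mean in enumerate(means):
        for _ in range(n_cells_per):
            center = mean + rng.normal(scale=center_sd, size=17)
            ensembles.append(center + rng.normal(
                scale=particle_sd, size=(n_particles, 17)))
            labels.append(g)
    return ensembles, np.array(labels)


class TestKlDistance:
    def test_identical_distribution_concentrates_near_zero(self):
        # distance between two draws from one distribution stays below
        # the 95th percentile of its own null distribution
        rng = np.random.default_rng(0)
        null = [kl_distance(rng.normal(size=(80, 17)),
                            rng.normal(size=(80, 17))) for _ in range(100)]
        cutoff = np.percentile(null, 95)
        below = sum(kl_distance(rng.normal(size=(80, 17)),
                                rng.normal(size=(80, 17))) <= cutoff
                    for _ in range(40))
        assert below >= 32  # ~95% expected, allow sampling slack
        assert np.median(null) < 0.01

    def test_fully_separated_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=(50, 17))
        x2 = rng.normal(size=(50, 17)) + 10.0  # ~10 pooled SDs everywhere
        got = kl_distance(x1, x2)
        m, n1, n2 = 100, 50, 50
        p_null = (n1 * (n1 - 1) + n2 * (n2 - 1)) / (m * (m - 1))
        p_obs = (m + 0.5) / (m + 1.0)  # all same-cell, pseudo-regularized
        expected = (p_obs * math.log(p_obs / p_null)
                    + (1 - p_obs) * math.log((1 - p_obs) / (1 - p_null)))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for shift in (0.0, 1.0, 3.0):
            x1 = rng.normal(size=(20, 17))
            x2 = rng.normal(size=(20, 17))
            x2[:, 3] += shift
            assert kl_distance(x1, x2) == pytest.approx(
                brute_force_kl(x1, x2), rel=1e-9)

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(3)
        dists = []
        for offset in (0.0, 1.0, 2.0, 5.0):
            vals = []
            for _ in range(10):
                x1 = rng.normal(size=(80, 17))
                x2 = rng.normal(size=(80, 17))
                x2[:, 0] += offset
                vals.append(kl_distance(x1, x2))
            dists.append(np.mean(vals))
        assert dists[0] < dists[1] < dists[2] < dists[3]

    def test_nonnegative_and_finite(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            d = kl_distance(rng.normal(size=(30, 17)),
                            rng.normal(size=(30, 17)) + rng.normal())
            assert np.isfinite(d) and d >= 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kl_distance(np.empty((0, 17)), np.ones((5, 17)))


class TestPairwiseAndMatrix:
    def test_matrix_properties(self):
        rng = np.random.default_rng(5)
        ens = [rng.normal(size=(40, 17)) + i for i in range(4)]
        dmat = pairwise_distances(ens)
        assert np.allclose(dmat.d, dmat.d.T)
        assert np.all(np.diag(dmat.d) == 0)
        assert np.all(dmat.d >= 0)

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            EnsembleDistanceMatrix(
                d=np.array([[0.0, 1.0], [2.0, 0.0]]), cell_ids=("a", "b"))


class TestCluster:
    def test_three_groups_recovered(self):
        rng = np.random.default_rng(6)
        means = [np.zeros(17), np.zeros(17), np.zeros(17)]
        means[1][0] = 3.0
        means[2][1] = 3.0
        ens, truth = gaussian_ensembles(rng, means)
        assign = cluster(pairwise_distances(ens))
        assert assign.k == 3
        assert adjusted_rand_score(truth, assign.labels) >= 0.95

    def test_two_groups_recovered(self):
        rng = np.random.default_rng(7)
        means = [np.zeros(17), np.zeros(17)]
        means[1][2] = 3.0
        ens, truth = gaussian_ensembles(rng, means, n_cells_per=6)
        assign = cluster(pairwise_distances(ens))
        assert assign.k == 2
        assert adjusted_rand_score(truth, assign.labels) >= 0.95

    def test_single_cloud_flagged_weak_or_small(self):
        rng = np.random.default_rng(8)
        ens, _ = gaussian_ensembles(rng, [np.zeros(17)], n_cells_per=12)
        assign = cluster(pairwise_distances(ens))
        # no strong interior CH maximum for an unstructured cloud
        assert assign.weak

    def test_zero_matrix_degenerate(self):
        dmat = EnsembleDistanceMatrix(d=np.zeros((5, 5)),
                                      cell_ids=tuple("abcde"))
        assign = cluster(dmat)
        assert assign.degenerate and assign.k == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        means = [np.zeros(17), np.zeros(17)]
        means[1][0] = 3.0
        ens, truth = gaussian_ensembles(rng, means, n_cells_per=5)
        a = cluster(pairwise_distances(ens))
        perm = rng.permutation(len(ens))
        b = cluster(pairwise_distances([ens[i] for i in perm]))
        assert a.k == b.k
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0


class TestVarianceRatio:
    def test_closed_form_two_point_clusters(self):
        # two 1-D clusters at +/- delta/2 with within-SD sigma:
        # between = n*(delta/2)^2, within = sum sq deviations
        delta, sigma, n = 4.0, 0.5, 200
        rng = np.random.default_rng(10)
        a = rng.normal(-delta / 2, sigma, size=(n, 1))
        b = rng.normal(+delta / 2, sigma, size=(n, 1))
        x = np.vstack([a, b])
        labels = np.array([0] * n + [1] * n)
        got = variance_ratio(x, labels)
        expected = (2 * n * (delta / 2) ** 2) / (2 * n * sigma ** 2)
        assert got == pytest.approx(expected, rel=0.2)

    def test_zero_within_diverges(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        assert variance_ratio(x, np.array([0, 0, 1, 1])) == math.inf

    def test_permuted_labels_destroy_ratio(self):
        rng = np.random.default_rng(11)
        x = np.vstack([rng.normal(0, 0.2, size=(30, 5)),
                       rng.normal(3, 0.2, size=(30, 5))])
        labels = np.array([0] * 30 + [1] * 30)
        structured = variance_ratio(x, labels)
        perms = [variance_ratio(x, rng.permutation(labels))
                 for _ in range(50)]
        assert structured > 20 * np.max(perms)

    def test_singletons_undefined(self):
        with pytest.raises(ValueError):
            variance_ratio(np.array([[0.0], [1.0]]), np.array([0, 1]))


class TestCharacterize:
    def _regime_ensembles(self, rng, offset_names, magnitude=0.6,
                          n_per=5, spread=0.05):
        idx = {n: i for i, n in enumerate(PARAMETER_NAMES)}
        means = []
        for signs in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            mean = np.zeros(17)
            for s, name in zip(signs, offset_names):
                mean[idx[name]] = s * magnitude
            means.append(mean)
        return gaussian_ensembles(rng, means, n_cells_per=n_per,
                                  center_sd=spread, particle_sd=0.25)

    def test_feedback_constants_rank_top(self):
        rng = np.random.default_rng(12)
        ens, labels = self._regime_ensembles(rng, ("d1", "d5", "dinh"))
        table = characterize_clusters(ens, labels)
        top3 = set(table.index[:3])
        assert top3 == {"d1", "d5", "dinh"}

    def test_no_difference_flat_scores(self):
        rng = np.random.default_rng(13)
        ens, labels = gaussian_ensembles(
            rng, [np.zeros(17)] * 3, n_cells_per=5)
        table = characterize_clusters(ens, labels)
        assert table["separation"].max() < 2.0

    def test_medians_recover_offsets(self):
        rng = np.random.default_rng(14)
        ens, labels = self._regime_ensembles(rng, ("d1", "d5", "dinh"))
        table = characterize_clusters(ens, labels)
        i_d1 = list(PARAMETER_NAMES).index("d1")
        lab_with_d1 = labels[np.argmax(
            [np.median(np.asarray(e)[:, i_d1]) for e in ens])]
        assert table.loc["d1", f"median_c{lab_with_d1}"] == pytest.approx(
            0.6, abs=0.1)
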