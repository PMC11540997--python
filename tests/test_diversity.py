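"""Shannon, zero-adjusted Bray-Curtis, ANOSIM, PCO, NMDS, diversity correlation.

ANOSIM and PCO have independent oracles: a naive double-loop/enumeration
implementation written here, plus scikit-bio's versions on shared cases.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from oralgut import (
    FeatureTable, ResemblanceMatrix, anosim, bray_curtis, diversity_correlation,
    nmds, pco, shannon, shannon_table, sqrt_transform, to_relative_abundance,
)


# ---------------------------------------------------------------------------
# Shannon
# ---------------------------------------------------------------------------

class TestShannon:
    @pytest.mark.parametrize("k", [2, 3, 4, 8, 16, 64])
    def test_uniform_community_equals_log_richness(self, k):
        assert shannon([1.0] * k) == pytest.approx(math.log(k), abs=1e-12)

    def test_single_taxon_zero(self):
        assert shannon([5.0, 0.0, 0.0]) == 0.0

    def test_direct_summation_oracle(self):
        # -(0.5 ln 0.5 + 0.25 ln 0.25 + 0.25 ln 0.25)
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.0397, abs=5e-5)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    def test_log2_base_option(self):
        assert shannon([1, 1, 1, 1], base=2) == pytest.approx(2.0)

    def test_table_skips_empty_samples(self, caplog):
        t = FeatureTable(["a", "b"], ["s1", "s2"],
                         np.array([[50.0, 0.0], [50.0, 0.0]]), state="percent")
        with caplog.at_level("WARNING"):
            h = shannon_table(t)
        assert list(h.index) == ["s1"]
        assert h["s1"] == pytest.approx(math.log(2))


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def _table(cols, state="sqrt_percent"):
    arr = np.asarray(cols, dtype=float).T
    return FeatureTable([f"f{i}" for i in range(arr.shape[0])],
                        [f"s{j}" for j in range(arr.shape[1])], arr, state=state)


class TestBrayCurtis:
    def test_identical_samples_fully_similar(self):
        r = bray_curtis(_table([[3, 1, 2], [3, 1, 2]]), dummy_value=0.0)
        assert r.values[0, 1] == pytest.approx(100.0)

    def test_disjoint_samples_zero_similarity_without_dummy(self):
        r = bray_curtis(_table([[5, 0], [0, 5]]), dummy_value=0.0)
        assert r.values[0, 1] == pytest.approx(0.0)

    def test_all_zero_pair_fully_similar_with_dummy(self):
        # hand evaluation: both samples become (0,..,0,1); |diff| = 0 -> s = 100
        r = bray_curtis(_table([[0.0, 0.0], [0.0, 0.0]]), dummy_value=1.0)
        assert r.values[0, 1] == pytest.approx(100.0)

    def test_dummy_hand_formula_on_asymmetric_pair(self):
        # samples (4,) and (0,) with dummy 1: sum|diff| = 4, sum = 6 -> s = 100/3
        r = bray_curtis(_table([[4.0], [0.0]]), dummy_value=1.0)
        assert r.values[0, 1] == pytest.approx(100 * (1 - 4 / 6))

    def test_all_zero_sample_without_dummy_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(_table([[0.0, 0.0], [1.0, 2.0]]), dummy_value=0.0)

    def test_bounds_symmetry_and_order_invariance(self):
        rng = np.random.default_rng(5)
        cols = rng.gamma(1.0, 2.0, size=(6, 10))
        r = bray_curtis(_table(cols))
        assert np.all((r.values >= -1e-9) & (r.values <= 100 + 1e-9))
        np.testing.assert_allclose(r.values, r.values.T, atol=1e-9)
        perm = rng.permutation(6)
        r2 = bray_curtis(_table(cols[perm]))
        np.testing.assert_allclose(r2.values, r.values[np.ix_(perm, perm)], atol=1e-9)

    def test_counts_state_rejected(self):
        with pytest.raises(Exception, match="state|percent"):
            bray_curtis(_table([[1, 2], [3, 4]], state="counts"))


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def naive_anosim_r(dmat: np.ndarray, labels: np.ndarray) -> float:
    """Independent double-loop ANOSIM R (test oracle)."""
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = rankdata([dmat[i, j] for i, j in pairs])
    within = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
    between = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2)


def _resemblance_from_points(points: np.ndarray) -> ResemblanceMatrix:
    d = squareform(pdist(points))
    d = d / (d.max() or 1.0)
    return ResemblanceMatrix([f"s{i}" for i in range(len(points))], 100.0 * (1 - d))


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        pts = np.vstack([np.random.default_rng(0).normal(0, 0.01, (4, 2)),
                         np.random.default_rng(1).normal(10, 0.01, (4, 2))])
        res = anosim(_resemblance_from_points(pts), ["a"] * 4 + ["b"] * 4,
                     n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_exhaustive_enumeration_on_six_sample_toy(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(6, 3))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        resem = _resemblance_from_points(pts)
        res = anosim(resem, labels, n_permutations=4999, seed=0)
        assert res.exact
        # oracle: enumerate all 6! orderings, count distinct multiset orderings
        dmat = resem.to_dissimilarity()
        r_obs = naive_anosim_r(dmat, labels)
        perms = sorted(set(itertools.permutations(labels)))
        assert len(perms) == res.n_permutations == 20
        rs = [naive_anosim_r(dmat, np.array(p)) for p in perms]
        p_exact = sum(1 for r in rs if r >= r_obs - 1e-12) / len(rs)
        assert res.R == pytest.approx(r_obs, abs=1e-12)
        assert res.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_sampling_p_converges_to_exhaustive(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(1.5, 1, (5, 2))])
        labels = np.array(["a"] * 5 + ["b"] * 5)
        resem = _resemblance_from_points(pts)
        exact = anosim(resem, labels, n_permutations=100_000, seed=0)
        assert exact.exact  # 252 distinct orderings
        approx = anosim(resem, labels, n_permutations=199, seed=7)
        assert not approx.exact
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.08)
        assert approx.p_value >= 1 / 200

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(9)
        rs = []
        for _ in range(200):
            pts = rng.normal(size=(10, 3))
            labels = np.array(["a"] * 5 + ["b"] * 5)
            rng.shuffle(labels)
            rs.append(anosim(_resemblance_from_points(pts), labels,
                             n_permutations=0, seed=0).R)
        assert abs(np.mean(rs)) < 0.05

    def test_matches_scikit_bio_r(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim, DistanceMatrix
        rng = np.random.default_rng(21)
        pts = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(2, 1, (6, 2))])
        resem = _resemblance_from_points(pts)
        labels = ["a"] * 6 + ["b"] * 6
        ours = anosim(resem, labels, n_permutations=99, seed=0)
        theirs = sk_anosim(DistanceMatrix(resem.to_dissimilarity(),
                                          ids=resem.sample_ids),
                           grouping=list(labels), permutations=0)
        assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_single_sample_group_rejected(self):
        resem = _resemblance_from_points(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="fewer than 2"):
            anosim(resem, ["a", "a", "a", "a", "b"], seed=0)


# ---------------------------------------------------------------------------
# PCO
# ---------------------------------------------------------------------------

class TestPco:
    def test_zero_dissimilarity_all_eigenvalues_zero(self):
        resem = ResemblanceMatrix(["a", "b", "c"], np.full((3, 3), 100.0))
        res = pco(resem)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_collinear_points_recovered_in_one_dimension(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])[:, None]
        resem = _resemblance_from_points(x)
        res = pco(resem)
        big = res.eigenvalues[np.abs(res.eigenvalues) > 1e-9]
        assert len(big) == 1
        coords = res.coordinates[:, 0]
        got = squareform(pdist(coords[:, None]))
        np.testing.assert_allclose(got, resem.to_dissimilarity(), atol=1e-9)

    def test_euclidean_case_equals_pca_scores(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 5))
        resem = _resemblance_from_points(X)
        scale = squareform(pdist(X)).max()
        res = pco(resem)
        assert res.n_negative_eigenvalues == 0
        Xc = X - X.mean(axis=0)
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        scores = (Xc @ vt.T) / scale
        k = min(res.coordinates.shape[1], 5)
        np.testing.assert_allclose(np.abs(res.coordinates[:, :k]),
                                   np.abs(scores[:, :k]), atol=1e-8)

    def test_matches_scikit_bio_pcoa(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 4))
        resem = _resemblance_from_points(X)
        ours = pco(resem)
        theirs = pcoa(resem.to_dissimilarity(), number_of_dimensions=3)
        np.testing.assert_allclose(np.abs(ours.coordinates[:, :3]),
                                   np.abs(theirs.samples.to_numpy()[:, :3]), atol=1e-8)

    def test_asymmetric_input_rejected(self):
        vals = np.array([[100.0, 50.0], [60.0, 100.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ResemblanceMatrix(["a", "b"], vals)

    def test_lingoes_correction_removes_negative_eigenvalues(self):
        # a non-Euclidean dissimilarity (violates the triangle-embedding)
        d = np.array([[0, .9, .1, .1], [.9, 0, .1, .1],
                      [.1, .1, 0, .1], [.1, .1, .1, 0]])
        resem = ResemblanceMatrix(list("abcd"), 100 * (1 - d))
        assert pco(resem).n_negative_eigenvalues > 0
        assert pco(resem, correction="lingoes").n_negative_eigenvalues == 0


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

class TestNmds:
    def test_recovers_planar_configuration_with_low_stress(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(15, 2))
        res = nmds(_resemblance_from_points(pts), n_axes=2, n_restarts=4, seed=0)
        assert res.stress is not None and res.stress < 0.01

    def test_same_seed_identical_output(self):
        rng = np.random.default_rng(6)
        resem = _resemblance_from_points(rng.normal(size=(10, 4)))
        a = nmds(resem, n_restarts=3, seed=5)
        b = nmds(resem, n_restarts=3, seed=5)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        assert a.stress == b.stress

    def test_too_few_samples_rejected(self):
        resem = _resemblance_from_points(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="at least"):
            nmds(resem, n_axes=2)


# ---------------------------------------------------------------------------
# Diversity correlation
# ---------------------------------------------------------------------------

class TestDiversityCorrelation:
    def test_identical_pairs_give_r2_one(self):
        pairs = [(4.1, 4.1), (4.5, 4.5), (4.9, 4.9), (5.2, 5.2)]
        assert diversity_correlation(pairs) == pytest.approx(1.0)

    def test_orthogonalized_pairs_near_zero(self):
        gut = np.array([1.0, -1.0, 1.0, -1.0])
        oral = np.array([1.0, 1.0, -1.0, -1.0])  # exactly uncorrelated
        assert diversity_correlation(list(zip(gut, oral))) == pytest.approx(0.0, abs=1e-12)

    def test_four_pair_fixture_matches_closed_form(self):
        pairs = np.array([(4.0, 4.2), (4.5, 4.1), (5.0, 4.8), (5.5, 4.6)])
        x, y = pairs[:, 0], pairs[:, 1]
        r = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert diversity_correlation(pairs) == pytest.approx(r * r, abs=1e-12)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            diversity_correlation([(4.0, 1.0), (4.0, 2.0), (4.0, 3.0)])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            diversity_correlation([(1.0, 2.0), (2.0, 3.0)])
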