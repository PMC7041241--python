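import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from famprof import (
    OtuTable,
    OtuTableError,
    bray_curtis,
    observed_richness,
    pcoa,
    permanova,
    rarefaction_curve,
    shannon,
)

from conftest import random_table


class TestAlphaDiversity:
    def test_observed_richness_counts_nonzero(self):
        assert observed_richness([3, 0, 1]) == 2
        assert observed_richness([0, 0]) == 0

    def test_richness_matches_naive_loop_on_random_columns(self, rng):
        for _ in range(50):
            col = rng.integers(0, 5, size=12)
            assert observed_richness(col) == sum(1 for c in col if c > 0)

    @pytest.mark.parametrize("counts, expected", [
        ([10], 0.0),
        ([1, 1, 1, 1], np.log(4)),
        ([2, 1, 1], -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))),
    ])
    def test_shannon_closed_forms(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-12)

    def test_shannon_base_conversion_and_zero_total_error(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0)
        with pytest.raises(OtuTableError):
            shannon([0, 0])


class TestRarefaction:
    def test_full_depth_returns_observed_richness(self):
        counts = [5, 3, 2, 0]
        curve = rarefaction_curve(counts, [10])
        assert curve.expected_richness[0] == pytest.approx(3.0, abs=1e-12)

    def test_depth_one_returns_one(self):
        curve = rarefaction_curve([4, 2], [1])
        assert curve.expected_richness[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_enumeration_small_sample(self):
        # N = 6 reads over 3 OTUs: average richness over all C(6,3) subsets
        counts = [3, 2, 1]
        reads = [otu for otu, c in enumerate(counts) for _ in range(c)]
        for depth in (2, 3, 4):
            exact = np.mean([
                len(set(combo)) for combo in itertools.combinations(reads, depth)
            ])
            curve = rarefaction_curve(counts, [depth])
            assert curve.expected_richness[0] == pytest.approx(exact, abs=1e-10)

    def test_monotone_in_depth_and_depth_validation(self, rng):
        counts = rng.integers(0, 20, size=10)
        counts[0] += 1
        total = int(counts.sum())
        curve = rarefaction_curve(counts, range(1, total + 1))
        assert np.all(np.diff(curve.expected_richness) >= -1e-12)
        with pytest.raises(OtuTableError):
            rarefaction_curve(counts, [total + 1])

    def test_matches_monte_carlo_subsampling(self, rng):
        counts = np.array([6, 3, 2, 1])
        depth, n_draws = 5, 10000
        reads = np.repeat(np.arange(4), counts)
        richness = np.empty(n_draws)
        for b in range(n_draws):
            sub = rng.choice(reads, size=depth, replace=False)
            richness[b] = len(np.unique(sub))
        expected = rarefaction_curve(counts, [depth]).expected_richness[0]
        se = richness.std(ddof=1) / np.sqrt(n_draws)
        assert abs(richness.mean() - expected) < 3 * se + 1e-9


class TestBrayCurtis:
    def test_identical_and_disjoint_columns(self):
        t = OtuTable(["a", "b"], ["s1", "s2", "s3"],
                     np.array([[5, 5, 0], [0, 0, 7]]))
        dm = bray_curtis(t, transform="none")
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)
        assert dm["s1", "s3"] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_untransformed_value(self):
        t = OtuTable(["a", "b"], ["s1", "s2"], np.array([[1, 3], [3, 1]]))
        dm = bray_curtis(t, transform="none")
        assert dm["s1", "s2"] == pytest.approx(0.5, abs=1e-12)

    def test_sqrt_transform_matches_manual_computation(self, rng):
        t = random_table(rng, n_otus=6, n_samples=4,
                         ensure_positive_samples=True)
        dm = bray_curtis(t, transform="sqrt")
        props = t.counts / t.counts.sum(axis=0)
        x = np.sqrt(props)
        manual = np.abs(x[:, 0] - x[:, 1]).sum() / (x[:, 0] + x[:, 1]).sum()
        assert dm[t.sample_ids[0], t.sample_ids[1]] == pytest.approx(manual)

    def test_zero_total_sample_rejected(self):
        t = OtuTable(["a"], ["s1", "s2"], np.array([[3, 0]]))
        with pytest.raises(OtuTableError):
            bray_curtis(t)


class TestPcoa:
    def test_reconstructs_euclidean_distances(self, rng):
        pts = rng.normal(size=(10, 3))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(10)]))
        d2 = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(d - d2).max() < 1e-9

    def test_three_equidistant_points_have_two_equal_eigenvalues(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        positive = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(positive) == 2
        assert positive[0] == pytest.approx(positive[1])

    def test_duplicated_sample_coincides(self, rng):
        pts = rng.normal(size=(5, 2))
        pts = np.vstack([pts, pts[0]])
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(6)]))
        coords = res.coordinates.to_numpy()
        assert np.allclose(coords[0], coords[5], atol=1e-9)

    def test_positive_eigenvalue_sum_equals_centred_trace(self, rng):
        t = random_table(rng, n_otus=8, n_samples=6,
                         ensure_positive_samples=True)
        dm = bray_curtis(t)
        res = pcoa(dm)
        d = dm.data
        a = -0.5 * d * d
        g = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
        positive = res.eigenvalues[res.eigenvalues > 1e-12]
        # BC is generally non-Euclidean: trace = sum of ALL eigenvalues
        assert res.eigenvalues.sum() == pytest.approx(np.trace(g), abs=1e-9)
        assert res.proportion_explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert len(res.proportion_explained) == len(positive)

    def test_agrees_with_skbio_on_euclidean_input(self, rng):
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(7)])
        ours = pcoa(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=2)
        assert ours.proportion_explained[:2] == pytest.approx(
            ref.proportion_explained.to_numpy()[:2], abs=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(Exception):
            pcoa(DistanceMatrix(np.array([[0, 1], [2, 0]]), ids=list("ab")))


def _random_dm(rng, n):
    pts = rng.normal(size=(n, 3))
    return DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(n)])


class TestPermanova:
    def test_duplicated_groups_give_r_squared_one(self):
        pts = np.array([[0.0, 0], [0, 0], [0, 0], [5, 5], [5, 5], [5, 5]])
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(6)])
        res = permanova(dm, {f"s{i}": "a" if i < 3 else "b" for i in range(6)},
                        n_permutations=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)

    def test_sum_of_squares_decomposition(self, rng):
        for _ in range(10):
            dm = _random_dm(rng, 9)
            res = permanova(dm, {f"s{i}": "abc"[i % 3] for i in range(9)},
                            n_permutations=49, seed=1)
            assert res.ss_among + res.ss_within == pytest.approx(
                res.ss_total, abs=1e-9)
            assert 0 <= res.r_squared <= 1

    def test_r_squared_invariant_to_seed_and_permutation_count(self, rng):
        dm = _random_dm(rng, 8)
        factor = {f"s{i}": "a" if i < 4 else "b" for i in range(8)}
        r1 = permanova(dm, factor, n_permutations=49, seed=1)
        r2 = permanova(dm, factor, n_permutations=999, seed=99)
        assert r1.r_squared == r2.r_squared
        assert r1.pseudo_f == r2.pseudo_f

    def test_pseudo_f_matches_skbio(self, rng):
        dm = _random_dm(rng, 10)
        labels = ["a", "a", "a", "b", "b", "b", "c", "c", "c", "c"]
        ours = permanova(dm, dict(zip(dm.ids, labels)),
                         n_permutations=99, seed=0)
        ref = skbio_permanova(dm, labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(float(ref["test statistic"]),
                                              abs=1e-9)

    def test_monte_carlo_p_matches_exhaustive_enumeration(self, rng):
        # 3 + 3 samples: all C(6,3) = 20 relabellings enumerable
        dm = _random_dm(rng, 6)
        factor = {f"s{i}": "a" if i < 3 else "b" for i in range(6)}
        obs = permanova(dm, factor, n_permutations=9999, seed=5)
        fs = []
        d2 = dm.data ** 2
        ss_total = d2.sum() / 12
        for combo in itertools.combinations(range(6), 3):
            in_a = np.zeros(6, dtype=bool)
            in_a[list(combo)] = True
            ss_w = d2[np.ix_(in_a, in_a)].sum() / 6 + \
                d2[np.ix_(~in_a, ~in_a)].sum() / 6
            fs.append(((ss_total - ss_w) / 1) / (ss_w / 4))
        exact_p = np.mean([f >= obs.pseudo_f - 1e-12 for f in fs])
        se = np.sqrt(exact_p * (1 - exact_p) / obs.n_permutations)
        assert abs(obs.p_value - exact_p) <= 2 * se + 2 / obs.n_permutations

    def test_single_level_and_no_residual_df_errors(self, rng):
        dm = _random_dm(rng, 4)
        with pytest.raises(OtuTableError, match="one level"):
            permanova(dm, {s: "a" for s in dm.ids})
        with pytest.raises(OtuTableError, match="residual"):
            permanova(dm, dict(zip(dm.ids, "abcd")))

    def test_unlabelled_sample_rejected(self, rng):
        dm = _random_dm(rng, 4)
        with pytest.raises(OtuTableError, match="unlabelled"):
            permanova(dm, {"s0": "a", "s1": "b"})
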