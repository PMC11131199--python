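import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa

from cazyome.stats import (
    anosim,
    bh_adjust,
    jaccard_matrix,
    kw_enrichment,
    lda_effect_size,
    pcoa,
    permanova,
    profile_matrix,
)
from cazyome.consensus import ToolHits, call_genome

from oracles import brute_force_bh


def presence_df(rows):
    return pd.DataFrame(rows).T if isinstance(rows, dict) else rows


class TestProfileMatrix:
    def test_presence_counts_and_granularity(self):
        calls = {
            "G1": call_genome([ToolHits("a", hmmer=("GH5_2", "GH5_46")),
                               ToolHits("b", hmmer=("PL1",))]),
            "G2": call_genome([ToolHits("c", diamond=("GH13",))]),  # unclassified: no profile
        }
        fam = profile_matrix(calls, granularity="family", counts=True)
        assert fam.loc["G1", "GH5"] == 2 and fam.loc["G2"].sum() == 0
        sub = profile_matrix(calls, granularity="subfamily")
        assert set(sub.columns) == {"GH5_2", "GH5_46", "PL1"}
        gh_only = profile_matrix(calls, cazy_classes=("GH",))
        assert "PL1" not in gh_only.columns


class TestJaccard:
    def test_set_arithmetic(self):
        presence = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0], [0, 0, 1], [0, 1, 1]],
            index=["a", "b", "c", "d"], columns=["GH5", "GH13", "PL1"],
        )
        dm = jaccard_matrix(presence)
        assert dm["a", "b"] == 0.0  # identical sets
        assert dm["a", "c"] == 1.0  # disjoint
        assert dm["a", "d"] == pytest.approx(2 / 3)  # {GH5,GH13} vs {GH13,PL1}

    def test_two_empty_sets_distance_zero_with_warning(self):
        presence = pd.DataFrame([[0, 0], [0, 0], [1, 0]], index=list("abc"), columns=["f", "g"])
        with pytest.warns(UserWarning, match="empty"):
            dm = jaccard_matrix(presence)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_triangle_inequality_on_random_profiles(self):
        rng = np.random.default_rng(0)
        presence = pd.DataFrame(rng.random((30, 15)) < 0.4).astype(int)
        presence.index = [f"G{i}" for i in range(30)]
        d = jaccard_matrix(presence).data
        for _ in range(500):
            i, j, k = rng.choice(30, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPcoa:
    def test_all_zero_distances(self):
        res = pcoa(np.zeros((4, 4)))
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)

    def test_equilateral_triangle_roundtrip(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(d)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)

    def test_euclidean_input_full_roundtrip_and_spectrum(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 5))
        d = squareform(pdist(x))
        res = pcoa(d)
        assert np.all(res.eigenvalues >= -1e-10)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, d, atol=1e-8)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)  # sorted descending

    def test_matches_skbio_coordinates(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 4))
        dm = DistanceMatrix(squareform(pdist(x)))
        ours = pcoa(dm).coordinates.to_numpy()
        theirs = skbio_pcoa(dm, method="eigh", warn_neg_eigval=False).samples.to_numpy()
        k = min(4, ours.shape[1])
        for axis in range(k):  # sign-free comparison
            assert np.allclose(np.abs(ours[:, axis]), np.abs(theirs[:, axis]), atol=1e-8)

    def test_asymmetric_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)


def two_cloud_dm(n_per=6, sep=100.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per, 3))
    b = rng.normal(0, 1, size=(n_per, 3)) + sep
    d = squareform(pdist(np.vstack([a, b])))
    groups = ["a"] * n_per + ["b"] * n_per
    return DistanceMatrix(d), groups


class TestGroupTests:
    def test_separated_clouds_maximal_significance(self):
        dm, groups = two_cloud_dm()
        res_a = anosim(dm, groups, n_permutations=199, seed=1)
        res_p = permanova(dm, groups, n_permutations=199, seed=1)
        assert res_a.statistic == pytest.approx(1.0)
        assert res_a.p_value == pytest.approx(1 / 200)
        assert res_p.p_value == pytest.approx(1 / 200)

    def test_anosim_r_matches_hand_ranks_on_toy_matrix(self):
        # 6 pairwise distances ranked 1..6; within-group: d01=3, d23=5
        d = np.array(
            [[0, 3, 1, 2],
             [3, 0, 4, 6],
             [1, 4, 0, 5],
             [2, 6, 5, 0]], dtype=float,
        )
        res = anosim(DistanceMatrix(d), ["a", "a", "b", "b"], n_permutations=99, seed=0)
        # mean between rank 3.25, mean within rank 4, M/2 = 3
        assert res.statistic == pytest.approx((3.25 - 4.0) / 3.0)

    def test_all_equal_distances_give_r_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        res = anosim(DistanceMatrix(d), ["a"] * 3 + ["b"] * 3, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(0.0)

    def test_reordering_genomes_preserves_statistics(self):
        dm, groups = two_cloud_dm(sep=2.0, seed=3)
        perm = np.random.default_rng(4).permutation(12)
        d2 = DistanceMatrix(dm.data[np.ix_(perm, perm)])
        g2 = [groups[i] for i in perm]
        assert anosim(d2, g2, 99, seed=0).statistic == pytest.approx(
            anosim(dm, groups, 99, seed=0).statistic)
        assert permanova(d2, g2, 99, seed=0).statistic == pytest.approx(
            permanova(dm, groups, 99, seed=0).statistic)

    def test_seed_reproducibility(self):
        dm, groups = two_cloud_dm(sep=1.0, seed=5)
        p1 = permanova(dm, groups, 199, seed=42).p_value
        p2 = permanova(dm, groups, 199, seed=42).p_value
        assert p1 == p2

    def test_singleton_group_rejected(self):
        dm, _ = two_cloud_dm()
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(dm, ["a"] + ["b"] * 11, 99, seed=0)


class TestBhAdjust:
    def test_step_up_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.array_equal(bh_adjust(p), brute_force_bh(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(10)
        p = rng.random(50)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_adjusted_never_below_raw_and_nan_passthrough(self):
        p = np.array([0.2, np.nan, 0.01])
        adj = bh_adjust(p)
        assert np.isnan(adj[1])
        ok = ~np.isnan(p)
        assert np.all(adj[ok] >= p[ok] - 1e-15)


class TestEnrichment:
    def _profile(self, n_per=20, seed=0):
        rng = np.random.default_rng(seed)
        cols = {
            "planted": np.r_[np.ones(n_per), np.zeros(n_per)],
            "flat1": (rng.random(2 * n_per) < 0.5).astype(float),
            "flat2": (rng.random(2 * n_per) < 0.5).astype(float),
            "constant": np.ones(2 * n_per),
        }
        df = pd.DataFrame(cols, index=[f"G{i}" for i in range(2 * n_per)])
        groups = {f"G{i}": ("A" if i < n_per else "B") for i in range(2 * n_per)}
        return df, groups

    def test_maximal_signal_flagged(self):
        df, groups = self._profile()
        res = kw_enrichment(df, groups)
        row = res[res.family_label == "planted"].iloc[0]
        assert row.p_adjusted < 0.05 and row.significant and row.enriched_group == "A"

    def test_constant_family_skipped(self):
        df, groups = self._profile()
        row = kw_enrichment(df, groups)[lambda r: r.family_label == "constant"].iloc[0]
        assert row.skipped and np.isnan(row.p_value)

    def test_lda_score_scale(self):
        # planted family carries ~all of group A's abundance: per-million
        # class-mean difference near 1e6 -> log10 score near 6
        n = 20
        df = pd.DataFrame(
            {"planted": np.r_[np.full(n, 1000.0), np.zeros(n)],
             "background": np.ones(2 * n)},
            index=[f"G{i}" for i in range(2 * n)],
        )
        groups = {f"G{i}": ("A" if i < n else "B") for i in range(2 * n)}
        res = lda_effect_size(df, groups, seed=0)
        row = res[res.family_label == "planted"].iloc[0]
        assert row.lda_score >= 4.0
        assert row.enriched_group == "A"

    def test_identical_distributions_never_reach_lda(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"f": np.repeat([1.0, 2.0], 10)},
                          index=[f"G{i}" for i in range(20)])
        df["f"] = rng.permutation(df["f"].to_numpy())
        groups = {f"G{i}": ("A" if i < 10 else "B") for i in range(20)}
        res = lda_effect_size(df, groups, kw_alpha=1e-6, seed=0)
        assert res.empty
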