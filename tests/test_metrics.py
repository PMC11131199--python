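import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cazyome.consensus import ToolHits, call_genome
from cazyome.io import GenomeMetadata
from cazyome.metrics import (
    OTHER_CLASS,
    family_diversity,
    gh_cbm_correlation,
    group_small_classes,
    multimodularity,
    quality_filter,
    rare_families,
    summarise_genome,
)

from oracles import spearman_rho_from_ranks


def calls_with(labels_by_gene):
    return call_genome([ToolHits(g, hmmer=tuple(ls)) for g, ls in labels_by_gene.items()])


def meta(gid, completeness=90.0, contamination=1.0, tax_class="K", n_proteins=1000):
    return GenomeMetadata(gid, tax_class, "O", "F", "soil", completeness, contamination,
                          3_000_000, n_proteins)


class TestFamilyDiversity:
    def test_family_level_collapses_subfamilies(self):
        calls = calls_with({"g1": ["GH5_2"], "g2": ["GH5_46"], "g3": ["GH13"]})
        assert family_diversity(calls.values(), "GH", "family") == 2
        assert family_diversity(calls.values(), "GH", "subfamily") == 3

    def test_absent_class_is_zero(self):
        calls = calls_with({"g1": ["GH5"]})
        assert family_diversity(calls.values(), "PL") == 0

    def test_unclassified_calls_do_not_count(self):
        calls = call_genome([ToolHits("g1", diamond=("GH5",))])
        assert family_diversity(calls.values(), "GH") == 0


class TestQualityFilter:
    def _calls(self, n):
        return calls_with({f"g{i}": ["GH5"] for i in range(n)})

    @pytest.mark.parametrize(
        "completeness,contamination,n_caz,kept",
        [
            (74.9, 1.0, 10, False),
            (75.0, 1.0, 10, False),  # strictly above required
            (75.1, 1.0, 10, True),
            (90.0, 9.9, 10, True),
            (90.0, 10.0, 10, False),  # strictly below required
            (90.0, 1.0, 9, False),
            (90.0, 1.0, 10, True),
        ],
    )
    def test_boundaries(self, completeness, contamination, n_caz, kept):
        m = [meta("G1", completeness, contamination)]
        retained, log = quality_filter(m, {"G1": self._calls(n_caz)})
        assert (retained == ["G1"]) is kept
        if not kept:
            assert log.iloc[0]["genome_id"] == "G1"

    def test_idempotent(self):
        ms = [meta("G1"), meta("G2", completeness=60.0)]
        calls = {"G1": self._calls(12), "G2": self._calls(12)}
        retained, _ = quality_filter(ms, calls)
        again, log2 = quality_filter([m for m in ms if m.genome_id in retained],
                                     {g: calls[g] for g in retained})
        assert again == retained and log2.empty

    def test_calls_without_metadata_is_hard_error(self):
        with pytest.raises(KeyError, match="G2"):
            quality_filter([meta("G1")], {"G1": {}, "G2": {}})


class TestGroupSmallClasses:
    def test_threshold_and_conservation(self):
        ms = [meta(f"A{i}", tax_class="big") for i in range(10)]
        ms += [meta(f"B{i}", tax_class="small") for i in range(9)]
        relabelled = group_small_classes(ms, min_n=10)
        assert len(relabelled) == len(ms)  # counts conserved
        assert all(relabelled[f"A{i}"] == "big" for i in range(10))
        assert all(relabelled[f"B{i}"] == OTHER_CLASS for i in range(9))


class TestRareFamilies:
    def test_strict_threshold(self):
        presence = pd.DataFrame(
            {"rare": [1] * 4 + [0] * 96, "edge": [1] * 5 + [0] * 95, "common": [1] * 100}
        )
        assert rare_families(presence, 0.05) == ["rare"]
        assert rare_families(presence, 0.0) == []

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            rare_families(pd.DataFrame())


class TestMultimodularity:
    def test_combination_is_order_insensitive_multiset(self):
        calls = calls_with({"g1": ["GH5", "CBM6"], "g2": ["CBM6", "GH5"]})
        mm = multimodularity(calls.values())
        assert mm["n_multimodular"] == 2
        assert mm["unique_combinations"] == 1

    def test_repeated_modules_distinguish_combinations(self):
        calls = calls_with({"g1": ["GH10", "CBM2", "CBM2"], "g2": ["GH10", "CBM2"]})
        mm = multimodularity(calls.values())
        assert mm["unique_combinations"] == 2
        assert mm["module_count_distribution"] == {2: 1, 3: 1}

    def test_all_unimodular(self):
        calls = calls_with({"g1": ["GH5"], "g2": ["GH13"]})
        assert multimodularity(calls.values())["n_multimodular"] == 0


class TestGhCbmCorrelation:
    def test_monotone_identity_and_reversal(self):
        gh = [3, 7, 12, 20, 25, 30, 33, 41, 44, 50]
        rho, p = gh_cbm_correlation(gh, gh)
        assert rho == pytest.approx(1.0)
        rho_r, _ = gh_cbm_correlation(gh, gh[::-1])
        assert rho_r == pytest.approx(-1.0)

    def test_matches_rank_formula_on_fixture(self):
        rng = np.random.default_rng(3)
        gh = rng.integers(0, 50, 10).astype(float)
        cbm = rng.integers(0, 20, 10).astype(float)
        rho, _ = gh_cbm_correlation(gh, cbm)
        assert rho == pytest.approx(spearman_rho_from_ranks(gh, cbm), abs=1e-12)

    def test_small_n_exact_p_matches_enumeration(self):
        gh, cbm = [1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 3.0, 2.0, 5.0, 4.0]
        rho, p = gh_cbm_correlation(gh, cbm)
        # scipy's exact mode for n<=? compare against scipy permutation route
        ref = sps.permutation_test(
            (np.array(gh), np.array(cbm)),
            lambda x, y: sps.spearmanr(x, y).statistic,
            permutation_type="pairings", n_resamples=np.inf, alternative="two-sided",
        )
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_zero_variance_is_missing(self):
        assert gh_cbm_correlation([5, 5, 5, 5], [1, 2, 3, 4]) == (None, None)

    def test_too_few_genomes_rejected(self):
        with pytest.raises(ValueError):
            gh_cbm_correlation([1, 2], [1, 2])


class TestGenomeSummary:
    def test_trend_boundary_goes_to_t2(self):
        # exactly 2% GH+CBM coding frequency -> T2 (split is strictly >2%)
        calls = calls_with({f"g{i}": ["GH5"] for i in range(20)})
        s = summarise_genome("G1", calls, n_proteins=1000)
        assert s.gh_cbm_frequency == pytest.approx(2.0)
        assert s.trend == "T2"
        s21 = summarise_genome("G1", calls_with({f"g{i}": ["GH5"] for i in range(21)}), 1000)
        assert s21.trend == "T1"

    def test_coding_frequency_counts_classified_genes(self):
        calls = call_genome(
            [ToolHits("g1", hmmer=("GH5", "CBM6")), ToolHits("g2", diamond=("GH9",))]
        )
        s = summarise_genome("G1", calls, n_proteins=100)
        assert s.n_cazyme_genes == 1  # unclassified g2 not counted
        assert s.coding_frequency == pytest.approx(1.0)
        assert s.unclassified_ratio == pytest.approx(0.5)
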