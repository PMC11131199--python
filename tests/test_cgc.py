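import numpy as np
import pytest

from cazyome.cgc import (
    ROLE_AUXILIARY,
    ROLE_CAZYME,
    ROLE_OTHER,
    assign_auxiliary,
    cgc_fractions,
    detect_cgcs,
)
from cazyome.consensus import ToolHits, call_genome
from cazyome.io import GeneRecord

from oracles import brute_force_cgcs, make_contig


def spans(cgcs):
    return sorted((c.first_rank, c.last_rank) for c in cgcs)


class TestDetectCgcs:
    def test_cazyme_plus_auxiliary_within_gap(self):
        cgcs = detect_cgcs(make_contig(["CAZ", "OTH", "OTH", "AUX"]), max_gap=2)
        (c,) = cgcs
        assert (c.n_cazymes, c.n_auxiliary, c.n_other) == (1, 1, 2)
        assert (c.first_rank, c.last_rank) == (0, 3)

    def test_gap_of_three_breaks_the_chain(self):
        cgcs = detect_cgcs(make_contig(["CAZ", "OTH", "OTH", "OTH", "CAZ"]), max_gap=2)
        assert cgcs == []

    def test_distant_cazyme_excluded_from_cluster(self):
        roles = ["CAZ", "CAZ", "OTH", "AUX", "OTH", "OTH", "OTH", "CAZ"]
        cgcs = detect_cgcs(make_contig(roles), max_gap=2)
        assert spans(cgcs) == [(0, 3)]
        assert cgcs[0].n_cazymes == 2 and cgcs[0].n_auxiliary == 1

    def test_two_auxiliaries_never_cluster_alone(self):
        assert detect_cgcs(make_contig(["AUX", "AUX"]), max_gap=2) == []

    def test_singleton_cazyme_fails_composition(self):
        assert detect_cgcs(make_contig(["OTH", "CAZ", "OTH"]), max_gap=2) == []

    def test_cluster_trimmed_to_signature_genes(self):
        cgcs = detect_cgcs(make_contig(["OTH", "CAZ", "CAZ", "OTH", "OTH"]), max_gap=2)
        assert spans(cgcs) == [(1, 2)]

    def test_unsorted_input_rejected(self):
        genes = make_contig(["CAZ", "CAZ"])
        with pytest.raises(ValueError, match="sorted"):
            detect_cgcs(list(reversed(genes)))

    def test_negative_max_gap_rejected(self):
        with pytest.raises(ValueError, match="max_gap"):
            detect_cgcs(make_contig(["CAZ"]), max_gap=-1)

    def test_matches_brute_force_on_random_contigs(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 51))
            roles = [["CAZ", "AUX", "OTH"][i] for i in rng.choice(3, n, p=[0.25, 0.15, 0.6])]
            max_gap = int(rng.integers(0, 4))
            got = spans(detect_cgcs(make_contig(roles), max_gap=max_gap))
            assert got == brute_force_cgcs(roles, max_gap), (roles, max_gap)

    def test_more_gap_never_loses_clustered_cazymes(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            roles = [["CAZ", "AUX", "OTH"][i] for i in rng.choice(3, n, p=[0.3, 0.1, 0.6])]
            counts = []
            for gap in (0, 1, 2, 3):
                cgcs = detect_cgcs(make_contig(roles), max_gap=gap)
                counts.append(sum(c.n_cazymes for c in cgcs))
            assert counts == sorted(counts)


def _gene(gid, rank, product, genome="G", contig="c"):
    start = 1 + rank * 1000
    return GeneRecord(genome, contig, gid, start, start + 899, "+", rank, product, 299)


class TestAssignAuxiliary:
    def test_transporter_keyword(self):
        genes = [_gene("g0", 0, "ABC transporter permease")]
        (role,) = assign_auxiliary(genes, {})
        assert role.role == ROLE_AUXILIARY

    def test_hypothetical_is_other_and_flagged(self):
        genes = [_gene("g0", 0, "hypothetical protein")]
        (role,) = assign_auxiliary(genes, {})
        assert role.role == ROLE_OTHER and role.is_hypothetical

    def test_cazyme_status_overrides_regulator_product(self):
        genes = [_gene("g0", 0, "LacI family transcriptional regulator")]
        calls = call_genome([ToolHits("g0", hmmer=("GH13",))])
        (role,) = assign_auxiliary(genes, calls)
        assert role.role == ROLE_CAZYME

    def test_unclassified_cazyme_is_other_but_flagged(self):
        genes = [_gene("g0", 0, "putative protein")]
        calls = call_genome([ToolHits("g0", diamond=("GH13",))])
        (role,) = assign_auxiliary(genes, calls)
        assert role.role == ROLE_OTHER and role.is_unclassified_cazyme

    def test_empty_signature_config_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assign_auxiliary([_gene("g0", 0, "ABC transporter")], {}, auxiliary_patterns=())
        assert "auxiliary" in caplog.text


class TestCgcFractions:
    def _fixture(self):
        # ranks: 0 CAZ(GH) 1 AUX 2 OTH(hyp) 3 CAZ(GH) | isolated: 7 CAZ(GH) 11 CAZ(GH,CE)
        products = {
            0: "glycoside hydrolase", 1: "MFS transporter", 2: "hypothetical protein",
            3: "glycoside hydrolase", 7: "glycoside hydrolase", 11: "esterase",
        }
        genes = [
            _gene(f"g{r}", r, products.get(r, "hypothetical protein")) for r in range(14)
        ]
        hits = [
            ToolHits("g0", hmmer=("GH5",)),
            ToolHits("g3", hmmer=("GH13",)),
            ToolHits("g7", hmmer=("GH9",)),
            ToolHits("g11", hmmer=("GH3", "CE1")),
        ]
        calls = call_genome(hits)
        roles = assign_auxiliary(genes, calls)
        cgcs = detect_cgcs(roles, max_gap=2)
        assert spans(cgcs) == [(0, 3)]
        return roles, cgcs, calls

    def test_half_of_gh_genes_in_clusters(self):
        roles, cgcs, calls = self._fixture()
        fr = cgc_fractions(roles, cgcs, calls)
        assert fr["frac_cazymes_in_cgc"] == pytest.approx(0.5)  # 2 of 4
        assert fr["frac_gh_in_cgc"] == pytest.approx(0.5)  # 2 of 4 GH genes
        # span ranks 0-3: one OTHER gene (rank 2, hypothetical)
        assert fr["frac_unassigned_in_cgc"] == pytest.approx(0.25)
        assert fr["frac_hypothetical_in_cgc"] == pytest.approx(0.25)

    def test_all_in_and_none_in(self):
        roles = make_contig(["CAZ", "CAZ"])
        calls = call_genome(
            [ToolHits("G_0000", hmmer=("GH5",)), ToolHits("G_0001", hmmer=("GH13",))]
        )
        cgcs = detect_cgcs(roles, max_gap=2)
        assert cgc_fractions(roles, cgcs, calls)["frac_cazymes_in_cgc"] == 1.0

        lonely = make_contig(["CAZ", "OTH", "OTH", "OTH", "OTH"])
        calls2 = call_genome([ToolHits("G_0000", hmmer=("GH5",))])
        assert cgc_fractions(lonely, [], calls2)["frac_cazymes_in_cgc"] == 0.0

    def test_zero_cazymes_gives_missing(self):
        roles = make_contig(["OTH", "OTH"])
        fr = cgc_fractions(roles, [], {})
        assert fr["frac_cazymes_in_cgc"] is None
        assert fr["frac_unassigned_in_cgc"] is None
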