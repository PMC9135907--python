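"""TSS-relative annotation, feature precedence and hypergeometric enrichment."""

import numpy as np
import pandas as pd
import pytest

from panclock.annotation import (
    GeneModel,
    annotate_probes,
    feature_distribution,
    read_bed12,
    read_gff3,
)
from panclock.datamodel import ProbeManifest, ValidationError
from panclock.enrichment import hypergeom_enrich, hypergeom_upper_tail, read_gmt, write_gmt

from oracles import hypergeom_upper_tail_enumeration, hypergeom_upper_tail_exact


def _manifest(probes: dict[str, tuple[str, int]]) -> ProbeManifest:
    return ProbeManifest(pd.DataFrame({
        "probe_id": list(probes),
        "chrom": [v[0] for v in probes.values()],
        "pos": [v[1] for v in probes.values()],
    }))


PLUS_GENE = GeneModel("geneA", "chr1", "+", 1000, 5000,
                      exons=[(1000, 1500), (4000, 5000)],
                      five_prime_utrs=[(1000, 1100)])
MINUS_GENE = GeneModel("geneB", "chr2", "-", 1000, 5000,
                       exons=[(1000, 1800), (4500, 5000)])


class TestAnnotate:
    def test_probe_inside_promoter_window_downstream_of_plus_tss(self):
        man = annotate_probes(_manifest({"p1": ("chr1", 1100)}), [PLUS_GENE])
        row = man.df.iloc[0]
        assert row["feature"] == "promoter"
        assert row["dist_to_tss"] == 100
        assert row["nearest_gene"] == "geneA"

    def test_minus_strand_probe_past_span_end_is_upstream(self):
        # minus-strand gene spans [1000, 5000]: its TSS is at 5000, so a
        # probe at 5100 is 100 bp upstream in gene orientation
        man = annotate_probes(_manifest({"p1": ("chr2", 5100)}), [MINUS_GENE])
        row = man.df.iloc[0]
        assert row["dist_to_tss"] == -100
        assert row["feature"] == "promoter"  # -100 falls inside -2000..+500

    def test_far_probe_is_intergenic(self):
        man = annotate_probes(_manifest({"p1": ("chr1", 60000)}), [PLUS_GENE])
        assert man.df.iloc[0]["feature"] == "intergenic"

    def test_feature_precedence_promoter_utr_exon_intron_downstream(self):
        probes = {
            "in_utr_and_promoter": ("chr1", 1050),  # promoter wins
            "in_exon_past_window": ("chr1", 4200),
            "in_intron": ("chr1", 3000),
            "just_downstream": ("chr1", 5500),
            "beyond_downstream": ("chr1", 9000),
        }
        man = annotate_probes(_manifest(probes), [PLUS_GENE])
        got = man.df.set_index("probe_id")["feature"].to_dict()
        assert got == {
            "in_utr_and_promoter": "promoter",
            "in_exon_past_window": "exon",
            "in_intron": "intron",
            "just_downstream": "downstream",
            "beyond_downstream": "intergenic",
        }

    def test_every_probe_gets_exactly_one_feature(self, tiny):
        genes = [PLUS_GENE, MINUS_GENE]
        man = annotate_probes(tiny.manifest, genes)
        assert man.df["feature"].notna().all()
        assert set(man.df["feature"]) <= {
            "promoter", "five_prime_utr", "exon", "intron", "downstream", "intergenic"}

    def test_off_chromosome_probe_flagged_intergenic(self):
        man = annotate_probes(_manifest({"p1": ("chrUn", 500)}), [PLUS_GENE])
        row = man.df.iloc[0]
        assert row["feature"] == "intergenic" and row["off_chromosome"]

    def test_equidistant_tie_broken_by_gene_id(self):
        g1 = GeneModel("zzz", "chr1", "+", 1000, 2000)
        g2 = GeneModel("aaa", "chr1", "+", 3000, 4000)
        man = annotate_probes(_manifest({"p1": ("chr1", 2000)}), [g1, g2])
        assert man.df.iloc[0]["nearest_gene"] == "aaa"  # |d|=1000 both ways


class TestReaders:
    def test_bed12_blocks_become_exons_and_utr(self, tmp_path):
        # one + strand transcript: chr1:1000-5000 (0-based), thick 1200-4800
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t1000\t5000\tgeneX\t0\t+\t1200\t4800\t0\t2\t500,1000\t0,3000\n")
        genes = read_bed12(bed)
        g = genes[0]
        assert (g.start, g.end) == (1001, 5000)  # converted to 1-based closed
        assert g.exons == [(1001, 1500), (4001, 5000)]
        assert g.five_prime_utrs == [(1001, 1200)]
        assert g.tss == 1001

    def test_gff3_reader(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t5000\t.\t+\t.\tID=gene1;Name=geneY\n"
            "chr1\tsrc\tmRNA\t1001\t5000\t.\t+\t.\tID=tx1;Parent=gene1\n"
            "chr1\tsrc\texon\t1001\t1500\t.\t+\t.\tID=ex1;Parent=tx1\n"
            "chr1\tsrc\tfive_prime_UTR\t1001\t1100\t.\t+\t.\tID=u1;Parent=tx1\n"
        )
        genes = read_gff3(gff)
        g = genes[0]
        assert g.gene_id == "geneY" and g.exons == [(1001, 1500)]
        assert g.five_prime_utrs == [(1001, 1100)]


class TestHypergeometric:
    def test_spec_worked_example(self):
        # N=10 background, K=5 in category, n=4 drawn, all 4 in category
        assert hypergeom_upper_tail(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)

    def test_exact_for_all_small_instances(self):
        # complete sweep N <= 12 against rational-arithmetic enumeration
        worst = 0.0
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        got = hypergeom_upper_tail(N, K, n, k)
                        want = hypergeom_upper_tail_exact(N, K, n, k)
                        worst = max(worst, abs(got - want))
        assert worst < 1e-12

    def test_exact_oracle_agrees_with_enumeration(self):
        for (N, K, n, k) in [(10, 5, 4, 4), (8, 3, 5, 2), (12, 6, 6, 3)]:
            assert hypergeom_upper_tail_exact(N, K, n, k) == pytest.approx(
                hypergeom_upper_tail_enumeration(N, K, n, k), abs=1e-14)

    def test_p_monotone_decreasing_in_overlap(self):
        ps = [hypergeom_upper_tail(100, 30, 20, k) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_zero_category_gives_p_one(self):
        assert hypergeom_upper_tail(10, 0, 4, 0) == 1.0


class TestEnrichment:
    def test_query_equal_background_saturates(self):
        bg = [f"cg{i}" for i in range(20)]
        table = hypergeom_enrich(bg, bg, {"setA": bg[:7]})
        row = table.iloc[0]
        assert row["overlap"] == 7 and row["p"] == pytest.approx(1.0)

    def test_planted_enrichment_detected(self):
        bg = [f"cg{i}" for i in range(100)]
        query = bg[:10]
        table = hypergeom_enrich(query, bg, {"hit": bg[:12], "miss": bg[50:90]})
        by_name = table.set_index("set_name")
        assert by_name.loc["hit", "p"] < 1e-6
        assert by_name.loc["hit", "fold_enrichment"] > 5
        assert by_name.loc["miss", "p"] > 0.5

    def test_query_outside_background_dropped(self, caplog):
        bg = ["a", "b", "c", "d"]
        table = hypergeom_enrich(["a", "zzz"], bg, {"s": ["a", "b"]})
        assert table.iloc[0]["query_size"] == 1

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrich(["a"], [], {"s": ["a"]})

    def test_gmt_roundtrip(self, tmp_path):
        cats = {"setA": {"cg1", "cg2"}, "setB": {"cg3"}}
        path = tmp_path / "sets.gmt"
        write_gmt(cats, path)
        assert read_gmt(path) == cats


class TestFeatureDistribution:
    def test_fractions(self):
        man = ProbeManifest(pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(5)],
            "chrom": "chr1", "pos": range(1, 6),
            "feature": ["promoter"] * 4 + ["intron"],
        }))
        dist = feature_distribution([f"p{i}" for i in range(5)], man)
        by_feat = dist.set_index("feature")
        assert by_feat.loc["promoter", "selected_fraction"] == pytest.approx(0.8)
        assert by_feat.loc["intron", "selected_fraction"] == pytest.approx(0.2)

    def test_empty_selection_no_division_error(self, tiny):
        dist = feature_distribution([], tiny.manifest)
        assert (dist["selected_count"] == 0).all()

    def test_gain_selection_promoter_enriched_on_fixture(self, three_tissue):
        from panclock.ewas import ewas_all_tissues, select_top, stouffer_meta

        per_tissue = ewas_all_tissues(three_tissue.beta, three_tissue.sheet)
        zmat = pd.DataFrame({t: r["z"] for t, r in per_tissue.items()})
        gain, _ = select_top(stouffer_meta(zmat), "meta")
        dist = feature_distribution(gain.probes, three_tissue.manifest)
        by_feat = dist.set_index("feature")
        sel = by_feat.loc[["promoter", "five_prime_utr"], "selected_fraction"].sum()
        bg = by_feat.loc[["promoter", "five_prime_utr"], "background_fraction"].sum()
        assert sel > bg
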