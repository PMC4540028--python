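"""Pileup variant calling, effect annotation and density arithmetic."""

import numpy as np
import pytest

from neemomics.simulate import (
    PanelConfig,
    generate_panel,
    simulate_genotype_reads,
    write_sam,
)
from neemomics.variants import (
    GeneModel,
    VariantCall,
    annotate_variant,
    marker_density,
    normalize_indel,
    phred_quality,
    pileup_call,
    summarize_effects,
)
from neemomics.variants.pileup import EffectAnnotation

from oracles import whole_protein_effect


def _sam_text(tmp_path, reference, records):
    path = tmp_path / "reads.sam"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, seq in reference.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for i, (contig, pos1, cigar, seq) in enumerate(records):
            fh.write(f"r{i}\t0\t{contig}\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t{'I'*len(seq)}\n")
    return path


REF = {"c": "ACGTACGGTTCAGGCATTACGATCAGGCATTACCGGAT"}


class TestPileup:
    def test_reads_matching_reference_yield_no_calls(self, tmp_path):
        recs = [("c", p, "20M", REF["c"][p - 1 : p + 19]) for p in range(1, 19)]
        sam = _sam_text(tmp_path, REF, recs * 2)
        assert pileup_call(sam, REF) == []

    def test_unknown_contig_is_an_input_error(self, tmp_path):
        sam = _sam_text(tmp_path, {"other": "ACGT" * 10}, [("other", 1, "8M", "ACGTACGT")])
        with pytest.raises(ValueError, match="unknown contig"):
            pileup_call(sam, REF)

    def test_depth_boundary_at_ten_reads(self, tmp_path):
        # SNP at position 10 (T->A), read depth exactly 9 vs exactly 10
        alt = REF["c"][:9] + "A" + REF["c"][10:]
        for depth, expected in [(9, "low_depth"), (10, "pass")]:
            recs = [("c", 1, "20M", alt[:20])] * depth
            sam = _sam_text(tmp_path, REF, recs)
            calls = pileup_call(sam, REF)
            snp = [c for c in calls if c.position == 10]
            assert len(snp) == 1 and snp[0].filter == expected
            assert snp[0].alt_allele == "A" and snp[0].type == "SNP"

    def test_low_mapping_quality_reads_excluded(self, tmp_path):
        alt = REF["c"][:9] + "A" + REF["c"][10:]
        path = tmp_path / "mapq.sam"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:c\tLN:%d\n" % len(REF["c"]))
            for i in range(12):
                fh.write(f"r{i}\t0\tc\t1\t5\t20M\t*\t0\t0\t{alt[:20]}\t{'I'*20}\n")
        assert pileup_call(path, REF) == []

    def test_insertion_called_from_cigar(self, tmp_path):
        # 2bp insertion after position 12
        ins_seq = REF["c"][:12] + "GG" + REF["c"][12:28]
        sam = _sam_text(tmp_path, REF, [("c", 1, "12M2I16M", ins_seq[:30])] * 12)
        (ins,) = pileup_call(sam, REF)
        assert ins.type == "insertion"
        assert (ins.position, ins.ref_allele, ins.alt_allele) == (12, "A", "AGG")

    def test_deletion_called_from_cigar(self, tmp_path):
        # 3bp deletion of positions 20-22
        del_seq = REF["c"][:19] + REF["c"][22:34]
        sam = _sam_text(tmp_path, REF, [("c", 1, "19M3D12M", del_seq[:31])] * 12)
        (dele,) = pileup_call(sam, REF)
        assert dele.type == "deletion"
        # raw record (19, ACGA, A) left-aligns one base (deleting CGA at
        # 20-22 equals deleting ACG at 19-21)
        assert (dele.position, dele.ref_allele, dele.alt_allele) == (18, "TACG", "T")

    def test_alt_fraction_threshold(self, tmp_path):
        alt = REF["c"][:9] + "A" + REF["c"][10:]
        recs = [("c", 1, "20M", alt[:20])] * 7 + [("c", 1, "20M", REF["c"][:20])] * 3
        sam = _sam_text(tmp_path, REF, recs)
        assert pileup_call(sam, REF) == []  # 0.7 < 0.8
        recs = [("c", 1, "20M", alt[:20])] * 9 + [("c", 1, "20M", REF["c"][:20])] * 1
        assert len(pileup_call(_sam_text(tmp_path, REF, recs), REF)) == 1

    def test_quality_is_binomial_tail_score(self):
        from scipy.stats import binom

        expected = -10 * binom.logsf(9, 30, 0.01) / np.log(10)
        assert phred_quality(10, 30) == pytest.approx(expected)
        assert phred_quality(0, 30) == 0.0

    def test_raising_thresholds_never_increases_pass_calls(self, tmp_path, small_panel):
        reads = simulate_genotype_reads(small_panel, "G2")
        sam = tmp_path / "g2.sam"
        write_sam(reads, small_panel.reference, sam)
        baseline = pileup_call(sam, small_panel.reference, min_depth=10, min_qual=30)
        stricter_d = pileup_call(sam, small_panel.reference, min_depth=20, min_qual=30)
        stricter_q = pileup_call(sam, small_panel.reference, min_depth=10, min_qual=60)
        n = lambda calls: sum(c.filter == "pass" for c in calls)
        assert n(stricter_d) <= n(baseline)
        assert n(stricter_q) <= n(baseline)


class TestNormalize:
    def test_left_alignment_in_repeat_run(self):
        seq = "GGCATATATATGGC"  # (AT)x4 at 4-11
        # deletion of the last 'AT' (pos 10-11), anchored at 9
        pos, ref, alt = normalize_indel(seq, 9, "TAT", "T")
        assert (pos, ref, alt) == (3, "CAT", "C")
        # insertion of one extra AT at the run end
        pos, ref, alt = normalize_indel(seq, 11, "T", "TAT")
        assert (pos, ref, alt) == (3, "C", "CAT")

    def test_snp_passthrough(self):
        assert normalize_indel("ACGT", 2, "C", "G") == (2, "C", "G")


def _snp_call(contig, pos, ref, alt):
    return VariantCall(contig, pos, ref, alt, "SNP", 30, 30, 300.0, "pass")


@pytest.fixture(scope="module")
def gene_setup():
    # forward gene: ATG GCT TGG TAA at 101..112 on a 300 bp contig
    cds = "ATGGCTTGGTAA"
    seq = ("ACGGTTCCAGCATGCCATGCAAGGTCCAT" * 10)[:100] + cds + \
          ("TTGCACCGGATGCCTTAGCATCAAGGCTA" * 10)[:188]
    gene = GeneModel("g1", "c", "+", exons=[(101, 112)], cds=[(101, 112, 0)])
    return {"c": seq}, [gene]


class TestAnnotation:

    def test_synonymous_change(self, gene_setup):
        ref, models = gene_setup
        # GCT -> GCC (Ala->Ala), third codon base at 106
        eff = annotate_variant(_snp_call("c", 106, "T", "C"), models, ref)
        assert (eff.region_class, eff.coding_effect) == ("exonic", "synonymous")

    def test_stop_gained(self, gene_setup):
        ref, models = gene_setup
        # TGG -> TGA at codon 3, base at 109 G->A
        eff = annotate_variant(_snp_call("c", 109, "G", "A"), models, ref)
        assert eff.coding_effect == "stop_gained"

    def test_start_and_stop_lost(self, gene_setup):
        ref, models = gene_setup
        assert annotate_variant(_snp_call("c", 102, "T", "C"), models, ref).coding_effect == "start_lost"
        # TAA stop -> CAA at 110
        assert annotate_variant(_snp_call("c", 110, "T", "C"), models, ref).coding_effect == "stop_lost"

    def test_upstream_downstream_and_intergenic(self, gene_setup):
        ref, models = gene_setup
        assert annotate_variant(_snp_call("c", 50, "A", "C"), models, ref).region_class == "upstream"
        assert annotate_variant(_snp_call("c", 200, "A", "C"), models, ref).region_class == "downstream"
        far = annotate_variant(_snp_call("c", 200, "A", "C"), models, ref, flank_window=10)
        assert far.region_class == "intergenic"

    def test_agrees_with_whole_protein_oracle_on_planted_panel(self, small_panel):
        """Codon-level classification must equal full-protein translation
        diffing for every planted exonic SNP, both strands, with introns."""
        models = {m.gene_id: m for m in small_panel.gene_models}
        by_contig = {}
        for m in small_panel.gene_models:
            by_contig.setdefault(m.contig, []).append(m)
        truth = small_panel.truth.variant_truth
        snps = truth[truth.type == "SNP"]
        checked = 0
        for row in snps.itertuples():
            ref = small_panel.reference
            call = _snp_call(row.contig, int(row.position), row.ref, row.alt)
            eff = annotate_variant(call, by_contig.get(row.contig, []), ref)
            if eff.region_class != "exonic" or eff.coding_effect == "none":
                continue
            gene = models[eff.gene_id]
            oracle = whole_protein_effect(gene, ref[row.contig], int(row.position), row.alt)
            assert eff.coding_effect == oracle, (row, eff.coding_effect, oracle)
            checked += 1
        assert checked >= 20  # the panel plants plenty of exonic SNPs


class TestDensityAndSummary:
    def test_reproduces_published_snp_density(self):
        d = marker_density([698_173, 860_215], 267_000_000)
        assert d["mean_rounded"] == 2.9

    def test_reproduces_published_indel_density(self):
        d = marker_density([53_508, 66_171], 267_000_000)
        assert d["mean_rounded"] == 0.22

    def test_zero_count_zero_density(self):
        assert marker_density([0], 1000)["mean"] == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            marker_density([], 1000)

    def test_effect_fractions_sum_to_one(self):
        calls = [_snp_call("c", i, "A", "C") for i in range(1, 8)]
        for i, c in enumerate(calls):
            c.effect = EffectAnnotation(
                ["exonic", "intronic", "upstream", "downstream", "intergenic",
                 "exonic", "exonic"][i],
                ["synonymous", "none", "none", "none", "none",
                 "nonsynonymous", "stop_gained"][i],
            )
        tables = summarize_effects(calls)
        for name, table in tables.items():
            for axis in ("region_class", "coding_effect"):
                sub = table[table.axis == axis]
                assert sub["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        region = tables["all"][tables["all"].axis == "region_class"].set_index("label")
        assert region.loc["exonic", "count"] == 3

    def test_empty_call_list_summary(self):
        tables = summarize_effects([])
        assert all(t.empty for t in tables.values())
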