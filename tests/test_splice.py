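import numpy as np
import pytest
from Bio.Seq import Seq

from omicnet import splice, synth

# independent codon table for the translation oracle (standard code)
_T4 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _oracle_translate(cdna):
    return "".join(
        _T4[cdna[i : i + 3]] for i in range(0, len(cdna) - len(cdna) % 3, 3)
    )


class TestSkipExons:
    def test_inframe_12nt(self):
        gm = synth.generate_gene_model((30, 12, 30), cds_span=(0, 72), seed=4)
        tv = splice.skip_exons(gm, ["2"])
        assert tv.deletion_length == 12
        assert tv.frame_class == "in-frame"

    def test_brca2_like_skip_5_and_7(self, brca2_like_gm):
        tv = splice.skip_exons(brca2_like_gm, ["5", "7"])
        assert tv.deletion_length == 165
        assert tv.frame_class == "in-frame"

    def test_skip_7_alone_frameshift(self, brca2_like_gm):
        tv = splice.skip_exons(brca2_like_gm, ["7"])
        assert tv.deletion_length == 115
        assert tv.frame_class == "frameshift"

    def test_skip_5_alone_frameshift(self, brca2_like_gm):
        tv = splice.skip_exons(brca2_like_gm, ["5"])
        assert tv.frame_class == "frameshift"

    def test_unknown_exon(self, brca2_like_gm):
        with pytest.raises(splice.SpliceError, match="unknown exon"):
            splice.skip_exons(brca2_like_gm, ["99"])

    def test_terminal_guard(self, brca2_like_gm):
        with pytest.raises(splice.SpliceError, match="terminal"):
            splice.skip_exons(brca2_like_gm, ["2"])
        tv = splice.skip_exons(brca2_like_gm, ["2"], guard_terminal_coding=False)
        assert tv.deletion_length == 106

    def test_frame_arithmetic_property(self):
        # in-frame <=> skipped length divisible by 3, over random exon subsets
        rng = np.random.default_rng(0)
        for trial in range(25):
            lengths = tuple(int(x) for x in rng.integers(10, 80, size=6))
            total = sum(lengths)
            gm = synth.generate_gene_model(
                lengths, cds_span=(0, total - total % 3), seed=trial
            )
            n_skip = int(rng.integers(1, 4))
            ids = [str(i) for i in rng.choice(range(2, 6), size=n_skip, replace=False)]
            tv = splice.skip_exons(gm, ids, guard_terminal_coding=False)
            expected = sum(gm.exon(i).length for i in ids)
            assert tv.deletion_length == expected
            # exons 2-5 lie fully inside the CDS, so the frame rule reduces
            # to the skipped-length sum
            assert (tv.frame_class == "in-frame") == (expected % 3 == 0)


class TestClassifyAndTranslate:
    def test_inframe_deletion_removes_55_aa(self, brca2_like_gm):
        tv = splice.classify_and_translate(
            splice.skip_exons(brca2_like_gm, ["5", "7"]), brca2_like_gm
        )
        assert tv.deleted_aa == 55
        assert tv.ptc_position is None
        assert tv.protein_length == len(brca2_like_gm.reference_protein) - 55

    def test_frameshift_truncates(self, brca2_like_gm):
        tv = splice.classify_and_translate(
            splice.skip_exons(brca2_like_gm, ["7"]), brca2_like_gm
        )
        assert tv.ptc_position is not None
        assert tv.protein_length < len(brca2_like_gm.reference_protein)

    def test_junction_codon_recomputed(self):
        # ATG AAA | GGG | TTT TAA ; dropping the middle exon fuses AAA|TTT
        exons = [
            splice.Exon("1", 1, 6, "ATGAAA"),
            splice.Exon("2", 101, 103, "GGG"),
            splice.Exon("3", 201, 206, "TTTTAA"),
        ]
        gm = splice.GeneModel("TOY", exons, 0, 15)
        assert gm.reference_protein == "MKGF"
        tv = splice.classify_and_translate(
            splice.skip_exons(gm, ["2"]), gm
        )
        assert tv.protein == "MKF"
        # junction codons are flagged novel
        assert any(lo <= 2 < hi or lo <= 1 < hi for lo, hi in tv.novel_protein_intervals)

    def test_shifted_segment_between_balanced_junctions(self, brca2_like_gm):
        # exons 5 (50 nt) and 7 (115 nt) skipped: exon 6 is read shifted,
        # downstream frame restored — its residues must be flagged novel
        tv = splice.classify_and_translate(
            splice.skip_exons(brca2_like_gm, ["5", "7"]), brca2_like_gm
        )
        assert tv.novel_protein_intervals
        spans = sum(hi - lo for lo, hi in tv.novel_protein_intervals)
        # at least the ~14 residues of the shifted exon 6
        assert spans >= 41 // 3

    def test_translation_matches_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(100):
            n_codons = int(rng.integers(4, 40))
            gm = synth.generate_gene_model(
                (3 * n_codons,), cds_span=(0, 3 * n_codons), seed=1000 + trial
            )
            assert splice.translate_cdna(gm.transcript) == _oracle_translate(
                gm.transcript
            )

    def test_cds_start_removed(self):
        gm = synth.generate_gene_model((30, 30), cds_span=(3, 57), seed=6)
        tv = splice.skip_exons(gm, ["1"], guard_terminal_coding=False)
        with pytest.raises(splice.SpliceError, match="CDS start"):
            splice.classify_and_translate(tv, gm)


class TestInsilicoPcr:
    def test_arithmetic(self):
        fwd = "A" * 9 + "CGTACGTACGT"  # 20-mer
        rev = "GGCCGGCCGGCCGGCCGGCC"
        template = fwd + "T" * 10 + str(Seq(rev).reverse_complement())
        (prod,) = splice.insilico_pcr(template, fwd, rev)
        assert prod.length == 50
        assert prod.sequence == template

    def test_no_reverse_match(self):
        products = splice.insilico_pcr("ACGT" * 30, "ACGTACGTACGT", "TTTTTTTTTTTT")
        assert products == []

    def test_variant_product_shorter_by_deletion(self, brca2_like_gm):
        gm = brca2_like_gm
        fwd = gm.exons[0].sequence[5:25]
        rev = str(Seq(gm.exons[-1].sequence[-30:-10]).reverse_complement())
        (wt,) = splice.insilico_pcr(gm.transcript, fwd, rev)
        tv = splice.skip_exons(gm, ["5", "7"])
        (var,) = splice.insilico_pcr(tv.cdna, fwd, rev)
        assert wt.length - var.length == 165

    def test_pcr_consistency_property(self, brca2_like_gm):
        gm = brca2_like_gm
        fwd = gm.exons[0].sequence[0:20]
        rev = str(Seq(gm.exons[-1].sequence[-20:]).reverse_complement())
        (wt,) = splice.insilico_pcr(gm.transcript, fwd, rev)
        for ids in (["4"], ["5"], ["3", "6"], ["4", "5", "6"]):
            tv = splice.skip_exons(gm, ids)
            (var,) = splice.insilico_pcr(tv.cdna, fwd, rev)
            assert wt.length - var.length == tv.deletion_length

    def test_bad_primer(self):
        with pytest.raises(splice.SpliceError):
            splice.insilico_pcr("ACGT", "ACGX", "ACGT")


class TestTrypticDigest:
    def test_basic_rule(self):
        peps = [p.sequence for p in splice.tryptic_digest("GKGGRG")]
        assert peps == ["GK", "GGR", "G"]

    def test_proline_suppression(self):
        peps = [p.sequence for p in splice.tryptic_digest("AKPR")]
        assert peps == ["AKPR"]

    def test_tiling_conservation(self):
        protein = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK"
        frags = splice.tryptic_digest(protein)
        assert "".join(p.sequence for p in frags) == protein
        pos = 0
        for p in frags:
            assert p.start == pos
            pos = p.end

    def test_missed_cleavages(self):
        peps = {p.sequence for p in splice.tryptic_digest("GKGGRG", missed_cleavages=1)}
        assert peps == {"GK", "GGR", "G", "GKGGR", "GGRG"}

    def test_invalid_residue(self):
        with pytest.raises(splice.SpliceError):
            splice.tryptic_digest("ACDEFZ")


class TestVariantSpecificPeptides:
    def test_self_reference_gives_no_unique(self, brca2_like_gm):
        tv = splice.classify_and_translate(
            splice.skip_exons(brca2_like_gm, ["5", "7"]), brca2_like_gm
        )
        peps = splice.variant_specific_peptides(tv, [tv.protein])
        assert not any(p.unique_vs_reference for p in peps)

    def test_junction_peptide_unique_vs_reference(self, brca2_like_gm):
        tv = splice.classify_and_translate(
            splice.skip_exons(brca2_like_gm, ["5", "7"]), brca2_like_gm
        )
        ref = brca2_like_gm.reference_protein
        peps = splice.variant_specific_peptides(tv, [ref])
        junction_unique = [
            p for p in peps if p.spans_novel_junction and p.unique_vs_reference
        ]
        assert junction_unique
        # brute-force check of the uniqueness flag
        for p in junction_unique:
            assert p.sequence not in ref

    def test_sorted_junction_first(self, brca2_like_gm):
        tv = splice.classify_and_translate(
            splice.skip_exons(brca2_like_gm, ["5", "7"]), brca2_like_gm
        )
        peps = splice.variant_specific_peptides(tv, [brca2_like_gm.reference_protein])
        flags = [p.spans_novel_junction for p in peps]
        assert flags == sorted(flags, reverse=True)

    def test_empty_reference_indeterminate(self, brca2_like_gm):
        tv = splice.classify_and_translate(
            splice.skip_exons(brca2_like_gm, ["5", "7"]), brca2_like_gm
        )
        peps = splice.variant_specific_peptides(tv, [])
        assert all(p.unique_vs_reference is None for p in peps)

    def test_requires_translation(self, brca2_like_gm):
        tv = splice.skip_exons(brca2_like_gm, ["5", "7"])
        with pytest.raises(splice.SpliceError):
            splice.variant_specific_peptides(tv, ["AAAA"])
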