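"""Transcript arithmetic, the minimal-dicistron rule, TSS assignment and
circular-junction reconstruction on the reconstructed Synechocystis locus."""

import pytest

from alkatlas import locus
from alkatlas.genome_model import GeneFeature, ProductClass, TssRecord
from alkatlas.txunit import (LengthEvidence, SrnaLocus, TranscriptModel,
                             TxClass, assign_tss, classify_transcript,
                             min_dicistron_length,
                             reconstruct_circular_junction, transcript_length,
                             utr_lengths)
from conftest import mirror_genome, mirror_tss


def _genes():
    return {f.product_class: f for f in locus.locus_features()}


class TestTranscriptLength:
    def test_aar_mrna_is_1159(self):
        assert transcript_length(2511367, 2510209, "-") == 1159

    def test_cotranscript_is_985(self):
        assert transcript_length(2512423, 2511439, "-") == 985

    def test_single_nucleotide(self):
        assert transcript_length(5, 5, "+") == 1

    def test_orientation_contradiction(self):
        with pytest.raises(ValueError):
            transcript_length(100, 200, "-")
        with pytest.raises(ValueError):
            transcript_length(200, 100, "+")


class TestMinDicistron:
    def test_ado_aar_bound_exceeds_orf_sum_and_1700(self):
        g = _genes()
        bound = min_dicistron_length(g[ProductClass.ADO], g[ProductClass.AAR])
        assert bound >= 696 + 1023 == 1719
        assert bound > 1700
        assert bound == 1937  # from the reconstructed coordinates

    def test_zero_gap_two_30nt_orfs(self):
        up = GeneFeature("u", "c", 1, 30, "+")
        down = GeneFeature("d", "c", 31, 60, "+")
        assert min_dicistron_length(up, down) == 60

    def test_bound_at_least_orf_sum_for_any_gap(self):
        for gap in (0, 1, 50, 400):
            up = GeneFeature("u", "c", 100, 795, "+")          # 696 nt
            down = GeneFeature("d", "c", 796 + gap, 1818 + gap, "+")  # 1023 nt
            assert min_dicistron_length(up, down) == 1719 + gap

    def test_wrong_order_rejected(self):
        up = GeneFeature("u", "c", 100, 400, "+")
        with pytest.raises(ValueError, match="downstream"):
            min_dicistron_length(up, GeneFeature("d", "c", 50, 90, "+"))

    def test_strand_and_contig_mismatch(self):
        a = GeneFeature("a", "c", 1, 30, "+")
        with pytest.raises(ValueError):
            min_dicistron_length(a, GeneFeature("b", "c", 40, 60, "-"))
        with pytest.raises(ValueError):
            min_dicistron_length(a, GeneFeature("b", "c2", 40, 60, "+"))


class TestClassifyTranscript:
    def test_northern_interval_too_short_for_dicistron(self):
        """A 900-1000 nt band against the 1937-nt bound -> monocistronic."""
        g = _genes()
        genes = list(g.values())
        model = TranscriptModel(2512423, 2511439, "-")
        cls = classify_transcript(model, genes,
                                  evidence=LengthEvidence(900, 1000))
        assert cls is TxClass.MONOCISTRONIC

    def test_exact_1159_aar_transcript_is_monocistronic(self):
        genes = list(_genes().values())
        model = TranscriptModel(2511367, 2510209, "-")
        assert classify_transcript(model, genes) is TxClass.MONOCISTRONIC

    def test_985_spanning_srna_and_ado_is_cotranscript(self):
        genes = list(_genes().values())
        model = TranscriptModel(2512423, 2511439, "-")
        cls = classify_transcript(model, genes, srna_loci=[locus.syr9_locus()])
        assert cls is TxClass.COTRANSCRIPT

    def test_leader_only_without_srna_list_is_ambiguous(self):
        genes = list(_genes().values())
        model = TranscriptModel(2512423, 2511439, "-")
        assert classify_transcript(model, genes) is TxClass.AMBIGUOUS

    def test_no_orf_covered_is_srna(self):
        genes = list(_genes().values())
        model = TranscriptModel(2512423, 2512264, "-")  # the SyR9 span itself
        assert classify_transcript(model, genes) is TxClass.SRNA

    def test_interval_at_or_above_bound_is_dicistron_compatible(self):
        genes = list(_genes().values())
        model = TranscriptModel(2512423, 2511439, "-")
        cls = classify_transcript(model, genes,
                                  evidence=LengthEvidence(1937, 2100))
        assert cls is TxClass.DICISTRON_COMPATIBLE

    def test_monotone_in_observed_max(self):
        """Raising observed_max can only move away from MONOCISTRONIC."""
        genes = list(_genes().values())
        model = TranscriptModel(2512423, 2511439, "-")
        order = {TxClass.MONOCISTRONIC: 0, TxClass.AMBIGUOUS: 1,
                 TxClass.DICISTRON_COMPATIBLE: 1}
        prev = 0
        for hi in (1000, 1500, 1936, 2000, 3000):
            cls = classify_transcript(model, genes,
                                      evidence=LengthEvidence(900, hi))
            assert order[cls] >= prev
            prev = order[cls]

    def test_no_genes_supplied(self):
        with pytest.raises(ValueError):
            classify_transcript(TranscriptModel(10, 5, "-"), [])


class TestUtrLengths:
    def test_aar_utr_decomposition_72_64(self):
        g = _genes()[ProductClass.AAR]
        model = TranscriptModel(2511367, 2510209, "-")
        assert utr_lengths(model, g) == (72, 64)

    def test_cotranscript_ado_trailer_75(self):
        g = _genes()[ProductClass.ADO]
        model = TranscriptModel(2512423, 2511439, "-")
        u5, trailer = utr_lengths(model, g)
        assert trailer == 75
        assert u5 == 214  # TSS1 leader over the ado start codon

    def test_gene_equal_to_span(self):
        gene = GeneFeature("g", "c", 100, 400, "+")
        assert utr_lengths(TranscriptModel(100, 400, "+"), gene) == (0, 0)

    def test_conservation_identity(self):
        """5'UTR + ORF + trailer equals the transcript length."""
        g = _genes()
        for cls, model in ((ProductClass.AAR, TranscriptModel(2511367, 2510209, "-")),
                           (ProductClass.ADO, TranscriptModel(2512423, 2511439, "-")),
                           (ProductClass.ADO, TranscriptModel(2512315, 2511439, "-"))):
            u5, u3 = utr_lengths(model, g[cls])
            assert u5 + g[cls].length_nt + u3 == model.length_nt

    def test_uncovered_gene_rejected(self):
        gene = GeneFeature("g", "c", 100, 400, "+")
        with pytest.raises(ValueError):
            utr_lengths(TranscriptModel(150, 500, "+"), gene)


class TestAssignTss:
    def test_proximal_and_distal_ado_promoters(self, locus_genes,
                                               locus_tss_records):
        assigned, orphans = assign_tss(locus_tss_records, locus_genes)
        ado = assigned["sll0208_ado"]
        assert [(a.tss.label, a.leader_nt, a.role) for a in ado] == [
            ("TSS2", 106, "proximal"), ("TSS1", 214, "distal")]
        aar = assigned["sll0209_aar"]
        assert [(a.tss.label, a.leader_nt, a.role) for a in aar] == [
            ("TSS3", 72, "proximal")]
        assert orphans == []

    def test_opposite_strand_tss_is_orphan(self, locus_genes):
        tss = [TssRecord(2512300, "+", 5, "X")]
        assigned, orphans = assign_tss(tss, locus_genes)
        assert assigned == {} and len(orphans) == 1

    def test_intervening_gene_blocks_assignment(self):
        genes = [GeneFeature("up", "c", 50, 200, "+"),
                 GeneFeature("down", "c", 300, 500, "+")]
        assigned, orphans = assign_tss([TssRecord(20, "+", 1, "T")], genes,
                                       max_leader_nt=300)
        assert list(assigned) == ["up"]  # blocked from reaching "down"

    def test_leader_cap(self, locus_genes):
        tss = [TssRecord(2512423, "-", 1, "TSS1")]
        assigned, orphans = assign_tss(tss, locus_genes, max_leader_nt=100)
        assert assigned == {} and len(orphans) == 1


class TestCircularJunction:
    def test_cotranscript_junction_gives_985(self):
        model = reconstruct_circular_junction((2511439, 2512423), "-")
        assert model.length_nt == 985
        assert model.five_prime == 2512423 and model.three_prime == 2511439

    def test_aar_junction_gives_1159(self):
        model = reconstruct_circular_junction((2510209, 2511367), "-")
        assert model.length_nt == 1159

    def test_point_junction(self):
        assert reconstruct_circular_junction((7, 7), "+").length_nt == 1

    def test_strand_inconsistency(self):
        with pytest.raises(ValueError):
            reconstruct_circular_junction((2511439, 2512423), "+")


def test_printed_number_chain_consistency():
    """TSS3 - 72 - 1023 + 1 - 64 lands exactly on the mapped aar 3' end."""
    assert locus.TSS3 - 72 - 1023 + 1 - 64 == 2510209
    assert locus.AAR_MRNA_3PRIME == 2510209
    assert locus.ADO_MRNA_3PRIME == 2511439
    assert locus.ADO_START_FIRST_NT == 2512209


def test_strand_symmetry_of_lengths_and_classes(demo_locus):
    """Mirroring the demo genome leaves lengths, classes and UTRs unchanged."""
    g = demo_locus.genome
    L = len(g.contigs["demo"])
    m = mirror_genome(g)
    off = demo_locus.offset
    junc = tuple(x - off for x in locus.COTRANSCRIPT_JUNCTION)
    model = reconstruct_circular_junction(junc, "-")
    mm = reconstruct_circular_junction((L - junc[0] + 1, L - junc[1] + 1), "+")
    assert mm.length_nt == model.length_nt == 985
    srna = demo_locus.srna
    msrna = SrnaLocus(srna.name, srna.contig_id, L - srna.end + 1,
                      L - srna.start + 1, "+")
    assert classify_transcript(model, g.features, srna_loci=[srna]) == \
        classify_transcript(mm, m.features, srna_loci=[msrna])
    ado = next(f for f in g.features if f.product_class is ProductClass.ADO)
    mado = next(f for f in m.features if f.product_class is ProductClass.ADO)
    assert utr_lengths(model, ado) == utr_lengths(mm, mado)


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    gene_start=st.integers(min_value=1000, max_value=5000),
    orf_codons=st.integers(min_value=2, max_value=500),
    utr5=st.integers(min_value=0, max_value=400),
    trailer=st.integers(min_value=0, max_value=400),
    strand=st.sampled_from(["+", "-"]),
)
def test_utr_conservation_property(gene_start, orf_codons, utr5, trailer, strand):
    """For any gene placed inside any covering transcript on either strand,
    5'UTR + ORF + trailer equals the transcript length."""
    orf_nt = 3 * orf_codons
    gene = GeneFeature("g", "c", gene_start, gene_start + orf_nt - 1, strand)
    if strand == "+":
        model = TranscriptModel(gene.start - utr5, gene.end + trailer, "+")
    else:
        model = TranscriptModel(gene.end + utr5, gene.start - trailer, "-")
    got5, got3 = utr_lengths(model, gene)
    assert (got5, got3) == (utr5, trailer)
    assert got5 + gene.length_nt + got3 == model.length_nt
    assert transcript_length(model.five_prime, model.three_prime, strand) == \
        model.length_nt
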