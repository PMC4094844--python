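"""Transcript-unit inference: TSS assignment, transcript/UTR arithmetic and
the minimal-dicistron decision rule.

The central question this module answers is whether two adjacent genes are
transcribed as one dicistronic mRNA or as independent monocistrons. The
decision rule compares an observed transcript size (an exact end pair from
circular RACE, or a northern size interval) with the minimal length a
dicistron covering both ORFs would need: the span from the upstream gene's
start codon to the downstream gene's stop codon. A transcript shorter than
that bound cannot carry both ORFs.

All positions are 1-based genomic coordinates; on the minus strand the 5'
end of a transcript is the numerically larger coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .genome_model import GeneFeature, TssRecord


class TxClass(str, Enum):
    MONOCISTRONIC = "MONOCISTRONIC"
    COTRANSCRIPT = "COTRANSCRIPT"
    SRNA = "SRNA"
    DICISTRON_COMPATIBLE = "DICISTRON_COMPATIBLE"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class LengthEvidence:
    """A transcript size estimate, e.g. a northern-blot band range in nt."""

    observed_min_nt: int
    observed_max_nt: int

    def __post_init__(self) -> None:
        if not 0 < self.observed_min_nt <= self.observed_max_nt:
            raise ValueError("need 0 < observed_min <= observed_max")


@dataclass
class TranscriptModel:
    """One inferred transcript with genomic 5'/3' ends."""

    five_prime: int
    three_prime: int
    strand: str
    covered_gene_ids: tuple[str, ...] = ()
    tx_class: TxClass = TxClass.AMBIGUOUS

    def __post_init__(self) -> None:
        _check_orientation(self.five_prime, self.three_prime, self.strand)

    @property
    def length_nt(self) -> int:
        return abs(self.five_prime - self.three_prime) + 1

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.five_prime, self.three_prime),
                max(self.five_prime, self.three_prime))


def _check_orientation(five_prime: int, three_prime: int, strand: str) -> None:
    if strand == "+" and five_prime > three_prime:
        raise ValueError(
            f"plus-strand transcript with 5' {five_prime} > 3' {three_prime}"
        )
    if strand == "-" and five_prime < three_prime:
        raise ValueError(
            f"minus-strand transcript with 5' {five_prime} < 3' {three_prime}"
        )
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")


def transcript_length(five_prime: int, three_prime: int, strand: str) -> int:
    """Inclusive length |5' - 3'| + 1 of a transcript."""
    _check_orientation(five_prime, three_prime, strand)
    return abs(five_prime - three_prime) + 1


def min_dicistron_length(upstream_gene: GeneFeature,
                         downstream_gene: GeneFeature) -> int:
    """Lower bound on a dicistronic mRNA covering both ORFs.

    Measured from the upstream gene's start-codon first nucleotide to the
    downstream gene's stop-codon last nucleotide, inclusive; any real
    dicistron must additionally carry a 5' UTR and 3' trailer, so observed
    sizes below this bound exclude a dicistron. Always >= the sum of the two
    ORF lengths.
    """
    if upstream_gene.contig_id != downstream_gene.contig_id:
        raise ValueError("genes on different contigs")
    if upstream_gene.strand != downstream_gene.strand:
        raise ValueError("genes on different strands")
    a = upstream_gene.start_codon_first_nt
    b = downstream_gene.stop_codon_last_nt
    strand = upstream_gene.strand
    if (strand == "+" and b <= upstream_gene.stop_codon_last_nt) or (
            strand == "-" and b >= upstream_gene.stop_codon_last_nt):
        raise ValueError(
            f"{downstream_gene.gene_id} does not lie downstream of "
            f"{upstream_gene.gene_id} in transcription order"
        )
    return abs(a - b) + 1


def _covers(model: TranscriptModel, gene: GeneFeature) -> bool:
    lo, hi = model.span
    return gene.strand == model.strand and lo <= gene.start and gene.end <= hi


@dataclass(frozen=True)
class SrnaLocus:
    """A known small-RNA locus (e.g. SyR9 upstream of ado)."""

    name: str
    contig_id: str
    start: int
    end: int
    strand: str


def classify_transcript(
    model: TranscriptModel,
    genes: Sequence[GeneFeature],
    evidence: Optional[LengthEvidence] = None,
    srna_loci: Sequence[SrnaLocus] = (),
    ambiguous_leader_nt: int = 150,
) -> TxClass:
    """Classify a transcript against the gene annotation.

    * SRNA — covers no ORF.
    * COTRANSCRIPT — covers exactly one ORF plus a 5' leader containing a
      known sRNA locus (a processed sRNA-mRNA cotranscript).
    * MONOCISTRONIC — covers exactly one ORF; with interval evidence, the
      observed maximum must fall below the minimal-dicistron bound with the
      downstream neighbor (exact RACE-derived ends bypass that test).
    * DICISTRON_COMPATIBLE — interval evidence at or above the bound.
    * AMBIGUOUS — anything else, including transcripts whose 5' leader is
      long enough to hide an sRNA (>= ``ambiguous_leader_nt``, default 150,
      just under the ~160 nt of SyR9) when no sRNA list was supplied.
    """
    if not genes:
        raise ValueError("no genes supplied")
    covered = [g for g in genes if _covers(model, g)]
    if not covered:
        return TxClass.SRNA
    if len(covered) >= 2:
        return TxClass.DICISTRON_COMPATIBLE if len(covered) == 2 else TxClass.AMBIGUOUS

    gene = covered[0]
    # leader = transcribed region 5' of the covered ORF
    if model.strand == "+":
        leader = (model.five_prime, gene.start - 1)
    else:
        leader = (gene.end + 1, model.five_prime)
    leader_len = leader[1] - leader[0] + 1
    if leader_len > 0:
        for s in srna_loci:
            if s.strand == model.strand and leader[0] <= s.start and s.end <= leader[1]:
                return TxClass.COTRANSCRIPT

    neighbor = _downstream_neighbor(gene, genes)
    if evidence is not None and neighbor is not None:
        bound = min_dicistron_length(gene, neighbor)
        if evidence.observed_max_nt < bound:
            return TxClass.MONOCISTRONIC
        if evidence.observed_min_nt >= bound:
            return TxClass.DICISTRON_COMPATIBLE
        return TxClass.AMBIGUOUS
    # exact ends: the transcript covers exactly one ORF, but a long leader
    # could still hide an unlisted sRNA
    if leader_len >= ambiguous_leader_nt and not srna_loci:
        return TxClass.AMBIGUOUS
    return TxClass.MONOCISTRONIC


def _downstream_neighbor(gene: GeneFeature,
                         genes: Sequence[GeneFeature]) -> Optional[GeneFeature]:
    same = [g for g in genes
            if g.contig_id == gene.contig_id and g.strand == gene.strand
            and g.gene_id != gene.gene_id]
    if gene.strand == "+":
        down = [g for g in same if g.start > gene.end]
        return min(down, key=lambda g: g.start) if down else None
    down = [g for g in same if g.end < gene.start]
    return max(down, key=lambda g: g.end) if down else None


def utr_lengths(model: TranscriptModel, gene: GeneFeature) -> tuple[int, int]:
    """(5' UTR, 3' trailer) lengths of a gene inside a transcript.

    The 5' UTR counts transcribed nucleotides strictly before the start
    codon, the trailer those strictly after the stop codon; the identity
    5'UTR + ORF + trailer = transcript length always holds.
    """
    lo, hi = model.span
    if not (lo <= gene.start and gene.end <= hi):
        raise ValueError(f"gene {gene.gene_id} not covered by transcript span")
    if gene.strand != model.strand:
        raise ValueError(f"gene {gene.gene_id} on opposite strand")
    if model.strand == "+":
        utr5 = gene.start - model.five_prime
        trailer = model.three_prime - gene.end
    else:
        utr5 = model.five_prime - gene.end
        trailer = gene.start - model.three_prime
    return utr5, trailer


@dataclass
class TssAssignment:
    gene_id: str
    tss: TssRecord
    leader_nt: int
    role: str  # "proximal" or "distal"


def assign_tss(
    tss_table: Iterable[TssRecord],
    genes: Sequence[GeneFeature],
    max_leader_nt: int = 300,
) -> tuple[dict[str, list[TssAssignment]], list[TssRecord]]:
    """Associate TSS with downstream genes; return (per-gene lists, orphans).

    A TSS belongs to a gene when it lies on the same strand, 0 to
    ``max_leader_nt`` upstream of the start codon, with no intervening
    same-strand gene. Among several TSS for one gene the nearest is
    "proximal", the rest "distal". Unassigned TSS come back as orphans —
    candidate sRNA starts.
    """
    assigned: dict[str, list[TssAssignment]] = {}
    orphans: list[TssRecord] = []
    for tss in tss_table:
        best: Optional[tuple[int, GeneFeature]] = None
        for g in genes:
            if g.strand != tss.strand:
                continue
            leader = (g.start - tss.position if g.strand == "+"
                      else tss.position - g.end)
            if not 0 <= leader <= max_leader_nt:
                continue
            # reject if another same-strand gene starts between TSS and gene
            span = ((tss.position, g.start - 1) if g.strand == "+"
                    else (g.end + 1, tss.position))
            blocked = any(
                o.strand == g.strand and o.gene_id != g.gene_id
                and o.contig_id == g.contig_id
                and not (o.end < span[0] or o.start > span[1])
                for o in genes
            )
            if blocked:
                continue
            if best is None or leader < best[0]:
                best = (leader, g)
        if best is None:
            orphans.append(tss)
        else:
            leader, g = best
            assigned.setdefault(g.gene_id, []).append(
                TssAssignment(g.gene_id, tss, leader, "proximal")
            )
    for gene_id, lst in assigned.items():
        lst.sort(key=lambda a: a.leader_nt)
        for a in lst[1:]:
            a.role = "distal"
    return assigned, orphans


def reconstruct_circular_junction(
    junction: tuple[int, int],
    strand: str,
    covered_gene_ids: tuple[str, ...] = (),
) -> TranscriptModel:
    """Build a transcript model from a circular-RACE 3'-5' junction.

    Self-ligation joins the transcript's last transcribed nucleotide to its
    first; sequencing across the junction therefore yields the pair
    (last_transcribed_pos, first_transcribed_pos), from which both ends and
    the exact length follow.
    """
    last_pos, first_pos = junction
    return TranscriptModel(five_prime=first_pos, three_prime=last_pos,
                           strand=strand, covered_gene_ids=covered_gene_ids)
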