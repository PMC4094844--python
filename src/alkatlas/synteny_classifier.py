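"""Classification of the alkane-locus gene arrangement in a genome.

Cyanobacterial genomes carry the two alkane biosynthesis genes (*ado*,
encoding aldehyde deformylating oxygenase, and *aar*, encoding acyl-ACP
reductase) in a handful of recurring layouts: a compact five-gene cluster
together with *accA*, a short-chain dehydrogenase gene and (usually) a GTP
cyclohydrolase I gene; a bare *ado*–*aar* tandem pair; both genes present but
at separate loci; or fully absent. This module assigns exactly one of those
labels per genome from a presence profile, and aggregates cohort prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from .genome_model import Genome, ProductClass
from .ortholog_survey import PresenceProfile


class Arrangement(str, Enum):
    FIVE_GENE_CLUSTER = "FIVE_GENE_CLUSTER"
    TANDEM_PAIR = "TANDEM_PAIR"
    SPLIT = "SPLIT"
    ABSENT = "ABSENT"


@dataclass
class ArrangementCall:
    genome_id: str
    arrangement: Arrangement
    member_gene_ids: dict[ProductClass, str] = field(default_factory=dict)
    evidence: str = ""

    @property
    def single_gene_warning(self) -> bool:
        return "single-gene" in self.evidence


def classify_arrangement(
    genome: Genome,
    profile: PresenceProfile,
    max_gap_nt: int = 500,
    max_intervening_genes: int = 1,
    cluster_window: int = 5,
) -> ArrangementCall:
    """Assign one arrangement label to a genome.

    Tandem adjacency requires *ado* and *aar* on the same contig and strand,
    with at most ``max_intervening_genes`` annotated genes between them and an
    intergenic gap of at most ``max_gap_nt``. A tandem pair is upgraded to
    FIVE_GENE_CLUSTER when *accA* and an SDR gene are detected within
    ``cluster_window`` annotation positions of the pair (GTP cyclohydrolase I
    is recorded as an optional fifth member when present). A genome where
    exactly one of the two core genes was detected is labelled SPLIT with a
    loud single-gene warning: the survey of real cohorts found no such genome,
    so it is always an anomaly worth surfacing.
    """
    if profile.genome_id != genome.genome_id:
        raise ValueError(
            f"profile genome {profile.genome_id!r} does not match genome "
            f"{genome.genome_id!r}"
        )
    det = profile.detected
    ado_hit = det.get(ProductClass.ADO)
    aar_hit = det.get(ProductClass.AAR)

    members: dict[ProductClass, str] = {
        cls: hit.subject_gene_id for cls, hit in det.items() if hit is not None
    }

    if ado_hit is None and aar_hit is None:
        return ArrangementCall(genome.genome_id, Arrangement.ABSENT, {},
                               "neither ado nor aar detected")
    if ado_hit is None or aar_hit is None:
        present = "aar" if ado_hit is None else "ado"
        return ArrangementCall(
            genome.genome_id, Arrangement.SPLIT, members,
            f"WARNING single-gene genome: only {present} detected",
        )

    ado = genome.gene(ado_hit.subject_gene_id)
    aar = genome.gene(aar_hit.subject_gene_id)

    if ado.contig_id != aar.contig_id:
        return ArrangementCall(genome.genome_id, Arrangement.SPLIT, members,
                               "ado and aar on different contigs")

    i, j = genome.order_index[ado.gene_id], genome.order_index[aar.gene_id]
    intervening = abs(i - j) - 1
    left, right = (ado, aar) if ado.start <= aar.start else (aar, ado)
    gap = right.start - left.end - 1
    if ado.strand != aar.strand:
        return ArrangementCall(genome.genome_id, Arrangement.SPLIT, members,
                               "adjacent but on opposite strands")
    if intervening > max_intervening_genes or gap > max_gap_nt:
        return ArrangementCall(
            genome.genome_id, Arrangement.SPLIT, members,
            f"non-adjacent: {intervening} intervening genes, gap {gap} nt",
        )

    # tandem confirmed; check for the flanking cluster genes
    contig_feats = genome.contig_features(ado.contig_id)
    pair_lo, pair_hi = min(i, j), max(i, j)

    def _in_window(cls: ProductClass) -> Optional[str]:
        hit = det.get(cls)
        if hit is None:
            return None
        g = genome.gene(hit.subject_gene_id)
        if g.contig_id != ado.contig_id:
            return None
        k = genome.order_index[g.gene_id]
        if pair_lo - cluster_window <= k <= pair_hi + cluster_window:
            return g.gene_id
        return None

    acca = _in_window(ProductClass.ACCA)
    sdr = _in_window(ProductClass.SDR)
    fole = _in_window(ProductClass.FOLE)
    if acca and sdr:
        note = "five-gene cluster" + (" incl. GTP cyclohydrolase I" if fole else "")
        return ArrangementCall(genome.genome_id, Arrangement.FIVE_GENE_CLUSTER,
                               members, note)
    return ArrangementCall(genome.genome_id, Arrangement.TANDEM_PAIR, members,
                           f"tandem pair, gap {gap} nt")


@dataclass
class CohortStats:
    n: int
    fraction_both_present: float
    fraction_tandem: float
    fraction_five_gene_cluster: float
    count_absent: int
    count_single_gene_warnings: int


def cohort_stats(calls: Iterable[ArrangementCall]) -> CohortStats:
    """Prevalence summary over a cohort of arrangement calls.

    The tandem fraction counts TANDEM_PAIR plus FIVE_GENE_CLUSTER genomes,
    since a five-gene cluster contains the tandem pair. Genomes with a
    single-gene warning count in neither "both present" nor "absent".
    """
    calls = list(calls)
    if not calls:
        raise ValueError("cohort_stats needs at least one call")
    n = len(calls)
    absent = sum(c.arrangement is Arrangement.ABSENT for c in calls)
    single = sum(c.single_gene_warning for c in calls)
    five = sum(c.arrangement is Arrangement.FIVE_GENE_CLUSTER for c in calls)
    tandem = sum(c.arrangement is Arrangement.TANDEM_PAIR for c in calls) + five
    both = n - absent - single
    return CohortStats(
        n=n,
        fraction_both_present=both / n,
        fraction_tandem=tandem / n,
        fraction_five_gene_cluster=five / n,
        count_absent=absent,
        count_single_gene_warnings=single,
    )
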