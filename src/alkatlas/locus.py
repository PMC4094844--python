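"""Reconstruction of the Synechocystis sp. PCC 6803 alkane locus.

The ado (sll0208) / aar (sll0209) locus on the minus strand of the
chromosome, rebuilt from the published coordinate anchors:

* three TSS on the minus strand: TSS1 (distal ado / SyR9 promoter) at
  2512423, TSS2 (proximal ado) at 2512315, TSS3 (aar) at 2511367;
* the ado ORF is 696 nt and its start codon begins 106 nt downstream of
  TSS2 (first nt at 2512209); the SyR9-ado cotranscript ends 75 nt past the
  ado stop codon at 2511439;
* the aar ORF is 1023 nt, its 5' end 72 nt upstream of the start codon and
  its 3' end 64 nt past the stop codon at 2510209;
* SyR9 is an ~160 nt sRNA sharing TSS1 (the 160 nt figure is nominal).

Coordinates are on the forward-strand numbering; the genes read right to
left. ``locus_features``/``locus_tss`` give the features at their true
chromosomal coordinates for pure arithmetic. ``build_demo_genome`` emits a
small fully synthetic genome carrying the same locus shifted near the
origin, with coding sequences back-translated from the synthetic seed
proteins and promoter/terminator elements planted — enough to run every
pipeline stage without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import GeneFeature, Genome, ProductClass, TssRecord
from .txunit import SrnaLocus

# published anchors (forward-strand coordinates, genes on the minus strand)
TSS1 = 2512423   # distal ado promoter P1 = SyR9 TSS
TSS2 = 2512315   # proximal ado promoter P2
TSS3 = 2511367   # aar promoter P3

ADO_ORF_NT = 696
AAR_ORF_NT = 1023

ADO_START_FIRST_NT = TSS2 - 106            # 2512209
ADO_STOP_LAST_NT = ADO_START_FIRST_NT - ADO_ORF_NT + 1   # 2511514
ADO_MRNA_3PRIME = ADO_STOP_LAST_NT - 75    # 2511439

AAR_START_FIRST_NT = TSS3 - 72             # 2511295
AAR_STOP_LAST_NT = AAR_START_FIRST_NT - AAR_ORF_NT + 1   # 2510273
AAR_MRNA_3PRIME = AAR_STOP_LAST_NT - 64    # 2510209

SYR9_NOMINAL_NT = 160

# circular-RACE junctions (last transcribed nt, first transcribed nt)
COTRANSCRIPT_JUNCTION = (ADO_MRNA_3PRIME, TSS1)   # 985-nt SyR9-ado cotranscript
AAR_JUNCTION = (AAR_MRNA_3PRIME, TSS3)            # 1159-nt aar mRNA

CONTIG_ID = "chromosome"


def locus_features(contig_id: str = CONTIG_ID) -> list[GeneFeature]:
    """The ado and aar gene features at their chromosomal coordinates."""
    return [
        GeneFeature("sll0208_ado", contig_id, ADO_STOP_LAST_NT,
                    ADO_START_FIRST_NT, "-", ProductClass.ADO),
        GeneFeature("sll0209_aar", contig_id, AAR_STOP_LAST_NT,
                    AAR_START_FIRST_NT, "-", ProductClass.AAR),
    ]


def locus_tss(contig_id: str = CONTIG_ID) -> list[TssRecord]:
    # read counts reflect the qualitative dRNAseq picture: TSS2 is weak
    return [
        TssRecord(TSS1, "-", 120, "TSS1"),
        TssRecord(TSS2, "-", 8, "TSS2"),
        TssRecord(TSS3, "-", 90, "TSS3"),
    ]


def syr9_locus(contig_id: str = CONTIG_ID) -> SrnaLocus:
    """SyR9 with its nominal 160 nt length (3' end never precisely mapped)."""
    return SrnaLocus("SyR9", contig_id, TSS1 - SYR9_NOMINAL_NT + 1, TSS1, "-")


@dataclass
class DemoLocus:
    genome: Genome
    tss: list[TssRecord]
    srna: SrnaLocus
    offset: int
    terminator_region: tuple[int, int]   # genomic span to search for the hairpin


def build_demo_genome(seed: int = 0, offset: int = 2509900) -> DemoLocus:
    """A small synthetic genome carrying the locus shifted by ``-offset``.

    All pairwise coordinate differences — transcript lengths, UTRs, leaders,
    the minimal-dicistron bound — are preserved. The coding sequences are
    back-translations of the package's synthetic seed proteins, a TATAAT box
    is planted upstream of each TSS (3' edge at -7) and a terminator hairpin
    with a U-tract is planted at the ado mRNA 3' end.
    """
    import numpy as np

    from .synthetic_data import (PlantedPromoter, back_translate,
                                 generate_tss_profile, seed_proteins,
                                 generate_terminator_region, _revcomp)

    rng = np.random.default_rng(seed)
    length = TSS1 - offset + 60
    seq = list("".join(rng.choice(list("ACGT"), size=length)))

    seeds = seed_proteins()
    feats = []
    for f in locus_features("demo"):
        prot = seeds[f.product_class]
        cds = back_translate(prot)
        assert len(cds) == f.length_nt
        start, end = f.start - offset, f.end - offset
        seq[start - 1:end] = list(_revcomp(cds))     # genes on the minus strand
        feats.append(GeneFeature(f.gene_id, "demo", start, end, f.strand,
                                 f.product_class, protein_seq=prot))

    # plant the intrinsic terminator just inside the ado mRNA 3' end
    hp, truth = generate_terminator_region(8, 4, 6, seed=seed + 1, flank=0)
    # on the minus strand the hairpin precedes the 3' end at larger coords
    t_end = ADO_MRNA_3PRIME - offset
    seq[t_end - 1:t_end - 1 + len(hp)] = list(_revcomp(hp))

    genome = Genome("synechocystis_demo", {"demo": "".join(seq)}, feats)
    promoters = [PlantedPromoter("demo", t.position - offset, "-", t.label)
                 for t in locus_tss()]
    genome, _, _ = generate_tss_profile(genome, promoters, seed=seed + 2)
    tss = [TssRecord(t.position - offset, "-", t.read_count, t.label)
           for t in locus_tss()]
    genome.validate()
    s9 = syr9_locus()
    srna = SrnaLocus("SyR9", "demo", s9.start - offset, s9.end - offset, "-")
    return DemoLocus(genome, tss, srna, offset,
                     (t_end, t_end + len(hp) + 10))
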