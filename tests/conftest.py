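import numpy as np
import pytest

from alkatlas import locus
from alkatlas.genome_model import GeneFeature, Genome, ProductClass, TssRecord


@pytest.fixture(scope="session")
def locus_genes():
    """ado/aar features at their reconstructed chromosomal coordinates."""
    return locus.locus_features()


@pytest.fixture(scope="session")
def locus_tss_records():
    return locus.locus_tss()


@pytest.fixture(scope="session")
def demo_locus():
    """Small synthetic genome carrying the shifted Synechocystis locus."""
    return locus.build_demo_genome(seed=0)


@pytest.fixture
def five_gene_genome():
    """One contig, five plus-strand genes with small gaps."""
    feats = []
    pos = 100
    for i in range(5):
        feats.append(GeneFeature(f"gene{i}", "c1", pos, pos + 299, "+",
                                 ProductClass.OTHER))
        pos += 400
    seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=pos + 100))
    return Genome("tiny", {"c1": seq}, feats)


def mirror_genome(genome: Genome) -> Genome:
    """Reverse every contig and flip all strands/coordinates.

    A genome and its mirror describe the same biology; classifiers and
    length arithmetic must be invariant under this transformation.
    """
    from Bio.Seq import Seq

    contigs = {cid: str(Seq(s).reverse_complement())
               for cid, s in genome.contigs.items()}
    feats = []
    for f in genome.features:
        L = len(genome.contigs[f.contig_id])
        feats.append(GeneFeature(
            f.gene_id, f.contig_id, L - f.end + 1, L - f.start + 1,
            "-" if f.strand == "+" else "+", f.product_class, f.protein_seq))
    return Genome(genome.genome_id, contigs, feats)


def mirror_tss(tss: TssRecord, contig_len: int) -> TssRecord:
    return TssRecord(contig_len - tss.position + 1,
                     "-" if tss.strand == "+" else "+",
                     tss.read_count, tss.label)
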