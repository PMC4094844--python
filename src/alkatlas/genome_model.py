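"""Coordinate-aware data model for annotated genomes, TSS tables and hit tables.

All genomic coordinates are 1-based and inclusive (GFF3 convention). A gene's
``start`` is always the numerically smaller coordinate regardless of strand;
the biological 5' end of a minus-strand feature is therefore its ``end``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.Data.CodonTable import unambiguous_dna_by_id


class ProductClass(str, Enum):
    """Functional classes tracked by the alkane-locus survey.

    ADO: aldehyde deformylating oxygenase; AAR: acyl-ACP reductase;
    ACCA: acetyl-CoA carboxyl transferase alpha subunit; SDR: short-chain
    dehydrogenase; FOLE: GTP cyclohydrolase I; OTHER: anything else.
    """

    ADO = "ADO"
    AAR = "AAR"
    ACCA = "ACCA"
    SDR = "SDR"
    FOLE = "FOLE"
    OTHER = "OTHER"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene. ``start <= end`` always; strand is '+' or '-'."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product_class: ProductClass = ProductClass.OTHER
    protein_seq: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"feature {self.gene_id}: invalid coordinates "
                f"{self.start}..{self.end} (need 1 <= start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.gene_id}: strand must be '+' or '-'")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def start_codon_first_nt(self) -> int:
        """Genomic position of the first nucleotide of the start codon."""
        return self.start if self.strand == "+" else self.end

    @property
    def stop_codon_last_nt(self) -> int:
        """Genomic position of the last nucleotide of the stop codon."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class TssRecord:
    """A transcriptional start site: the +1 nucleotide of a primary transcript."""

    position: int
    strand: str
    read_count: int = 0
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("TSS position must be >= 1")
        if self.read_count < 0:
            raise ValueError("TSS read_count must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("TSS strand must be '+' or '-'")


@dataclass(frozen=True)
class HitRecord:
    """A protein similarity hit against one genome."""

    query_id: str
    subject_gene_id: str
    genome_id: str
    raw_score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be nonnegative")


@dataclass
class Genome:
    """Contigs plus an ordered gene collection.

    Features are kept sorted by (contig, start); ``order_index`` maps
    gene_id -> annotation rank within its contig, the adjacency notion used
    by the synteny classifier.
    """

    genome_id: str
    contigs: dict[str, str]
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self.features.sort(key=lambda f: (f.contig_id, f.start, f.gene_id))
        self.order_index: dict[str, int] = {}
        self._by_id: dict[str, GeneFeature] = {}
        counters: dict[str, int] = {}
        for f in self.features:
            if f.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {f.gene_id!r}")
            self._by_id[f.gene_id] = f
            idx = counters.get(f.contig_id, 0)
            self.order_index[f.gene_id] = idx
            counters[f.contig_id] = idx + 1

    def validate(self) -> None:
        for f in self.features:
            if f.contig_id not in self.contigs:
                raise ValueError(
                    f"feature {f.gene_id}: contig {f.contig_id!r} missing from sequence set"
                )
            if f.end > len(self.contigs[f.contig_id]):
                raise ValueError(
                    f"feature {f.gene_id}: end {f.end} exceeds contig "
                    f"{f.contig_id} length {len(self.contigs[f.contig_id])}"
                )

    def gene(self, gene_id: str) -> GeneFeature:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def contig_features(self, contig_id: str) -> list[GeneFeature]:
        return [f for f in self.features if f.contig_id == contig_id]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_GFF_ATTR_CLASS = "product_class"


def _parse_gff3(path: Path) -> list[GeneFeature]:
    import gffutils

    feats = []
    for rec in gffutils.iterators.DataIterator(str(path)):
        if rec.featuretype not in ("CDS", "gene"):
            continue
        gene_id = rec.attributes.get("ID", rec.attributes.get("Name", [None]))[0]
        if gene_id is None:
            raise ValueError(f"GFF3 row lacks ID attribute: {rec}")
        pclass = ProductClass(rec.attributes.get(_GFF_ATTR_CLASS, ["OTHER"])[0])
        feats.append(
            GeneFeature(gene_id, rec.seqid, rec.start, rec.end, rec.strand, pclass)
        )
    return feats


def _parse_feature_table(path: Path) -> list[GeneFeature]:
    """Minimal 6-column tabular dialect: gene_id contig start end strand class."""
    feats = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            gene_id, contig, start, end, strand, pclass = row[:6]
            feats.append(
                GeneFeature(gene_id, contig, int(start), int(end), strand,
                            ProductClass(pclass))
            )
    return feats


def read_genome(annotation_path, sequence_path, genome_id: Optional[str] = None) -> Genome:
    """Load a genome from GFF3 (or the 6-column tabular fallback) + FASTA.

    Features are validated against contig bounds; out-of-bounds coordinates
    or a feature referencing a missing contig raise ``ValueError`` naming the
    offending feature.
    """
    annotation_path = Path(annotation_path)
    sequence_path = Path(sequence_path)
    contigs = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(sequence_path), "fasta")}
    first = annotation_path.read_text().lstrip().splitlines()
    is_gff = bool(first) and (first[0].startswith("##gff") or
                              len(first[0].split("\t")) == 9)
    feats = _parse_gff3(annotation_path) if is_gff else _parse_feature_table(annotation_path)
    g = Genome(genome_id or annotation_path.stem, contigs, feats)
    g.validate()
    return g


def write_genome(genome: Genome, annotation_path, sequence_path) -> None:
    """Write GFF3 + FASTA such that ``read_genome`` round-trips exactly."""
    with open(annotation_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in genome.features:
            attrs = f"ID={f.gene_id};{_GFF_ATTR_CLASS}={f.product_class.value}"
            fh.write(
                f"{f.contig_id}\talkatlas\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
            )
    with open(sequence_path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_tss_table(path) -> list[TssRecord]:
    """TSV with columns: position, strand, read_count, label (header optional)."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            cols = line.split("\t")
            label = cols[3] if len(cols) > 3 and cols[3] else None
            records.append(TssRecord(int(cols[0]), cols[1], int(cols[2]), label))
    return records


def write_tss_table(records: Iterable[TssRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tstrand\tread_count\tlabel\n")
        for r in records:
            fh.write(f"{r.position}\t{r.strand}\t{r.read_count}\t{r.label or ''}\n")


def read_hits_table(path, genome_id: str) -> list[HitRecord]:
    """Ingest a 12-column tabular alignment file (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore)."""
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"hit table row has {len(cols)} columns, need 12")
            hits.append(HitRecord(
                query_id=cols[0], subject_gene_id=cols[1], genome_id=genome_id,
                raw_score=float(cols[11]), evalue=float(cols[10]),
            ))
    return hits


# ---------------------------------------------------------------------------
# sequence operations
# ---------------------------------------------------------------------------

_TABLE11 = unambiguous_dna_by_id[11]


def extract_cds(feature: GeneFeature, genome: Genome) -> str:
    """Return the coding-strand nucleotide sequence of a feature."""
    seq = genome.contigs[feature.contig_id][feature.start - 1:feature.end]
    if feature.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate_cds(feature: GeneFeature, genome: Genome) -> str:
    """Translate a CDS feature under the bacterial code (table 11).

    Reverse-strand features are reverse-complemented first; the trailing stop
    codon is removed. An internal stop raises ``ValueError`` naming the codon
    position, as does a length not divisible by 3.
    """
    nt = extract_cds(feature, genome)
    if len(nt) % 3 != 0:
        raise ValueError(
            f"feature {feature.gene_id}: CDS length {len(nt)} not divisible by 3"
        )
    aa = str(Seq(nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        pos = aa.index("*")
        raise ValueError(
            f"feature {feature.gene_id}: internal stop codon at codon {pos + 1}"
        )
    return aa


def neighborhood(genome: Genome, gene_id: str, k: int) -> list[GeneFeature]:
    """Up to ``k`` annotated genes on each side of ``gene_id``, same contig,
    in genomic order (the gene itself included)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    centre = genome.gene(gene_id)
    contig_feats = genome.contig_features(centre.contig_id)
    idx = next(i for i, f in enumerate(contig_feats) if f.gene_id == gene_id)
    return contig_feats[max(0, idx - k):idx + k + 1]
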