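"""Synthetic input generation with planted ground truth.

Every stage of the pipeline consumes inputs this module can fabricate:
genome cohorts with alkane-locus arrangements planted at chosen frequencies,
TSS tables with -10 promoter boxes written into the sequence, terminator
hairpins with U-tracts, rifampicin decay time-courses, and aligned
16S-like sequences evolved down a given tree. Each generator is a pure
function of its spec plus a seed, and returns the planted truth alongside
the data so downstream detectors can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .genome_model import GeneFeature, Genome, ProductClass, TssRecord
from .synteny_classifier import Arrangement

_NT = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_COMP = str.maketrans("ACGT", "TGCA")

# one codon per amino acid (bacterial code, table 11); used for back-translation
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAT", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTT",
    "W": "TGG", "Y": "TAC",
}

# Lengths of the seed proteins, in amino acids. ADO and AAR mirror the
# Synechocystis ORF arithmetic (696 and 1023 nt CDS including the stop codon);
# the remaining three are typical lengths for their families.
_SEED_LENGTHS = {
    ProductClass.ADO: 231,   # 696 / 3 - 1
    ProductClass.AAR: 340,   # 1023 / 3 - 1
    ProductClass.ACCA: 315,
    ProductClass.SDR: 250,
    ProductClass.FOLE: 220,
}
_SEED_PROTEIN_SEED = 7_654_321  # fixed: seed proteins are part of the package


def seed_proteins() -> dict[ProductClass, str]:
    """Deterministic synthetic reference proteins, one per product class.

    These stand in for the Synechocystis ADO/AAR and Anabaena AccA/SDR/FolE
    reference sequences used in real screens; they are synthetic and carry no
    biological motif content.
    """
    rng = np.random.default_rng(_SEED_PROTEIN_SEED)
    out = {}
    for cls in (ProductClass.ADO, ProductClass.AAR, ProductClass.ACCA,
                ProductClass.SDR, ProductClass.FOLE):
        n = _SEED_LENGTHS[cls]
        body = "".join(rng.choice(list(_AA20), size=n - 1))
        out[cls] = "M" + body
    return out


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NT, size=n)) if n > 0 else ""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def mutate_protein(protein: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute residues uniformly so the expected identity is ``identity``.

    No indels are introduced; the initial methionine is kept so the product
    stays a valid CDS start.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    out = list(protein)
    for i in range(1, len(out)):
        if rng.random() > identity:
            choices = _AA20.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(protein: str) -> str:
    """Protein -> CDS nucleotides under a fixed codon choice, plus TAA stop."""
    return "".join(_CODON[aa] for aa in protein) + "TAA"


# ---------------------------------------------------------------------------
# genome cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Composition of a synthetic genome cohort.

    ``arrangement_frequencies`` maps each arrangement to its cohort
    proportion (must sum to 1); planted counts are the rounded products,
    adjusted on the most frequent class so they sum to ``n_genomes``.
    """

    n_genomes: int
    arrangement_frequencies: dict[Arrangement, float]
    ortholog_identity: float = 1.0
    seed: int = 0
    n_decoys: int = 4

    def planted_counts(self) -> dict[Arrangement, int]:
        freqs = self.arrangement_frequencies
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"arrangement frequencies sum to {total}, not 1")
        if any(v < 0 for v in freqs.values()):
            raise ValueError("negative arrangement frequency")
        counts = {a: round(self.n_genomes * f) for a, f in freqs.items()}
        drift = self.n_genomes - sum(counts.values())
        if drift:
            top = max(freqs, key=lambda a: (freqs[a], a.value))
            counts[top] += drift
            if counts[top] < 0:
                raise ValueError("frequency vector cannot be realised")
        return counts


@dataclass
class Cohort:
    genomes: list[Genome]
    truth: dict[str, Arrangement]
    member_truth: dict[str, dict[ProductClass, str]] = field(default_factory=dict)


def _plant_genes(
    rng: np.random.Generator,
    plan: list[tuple[str, ProductClass, str, str]],
) -> tuple[str, list[GeneFeature]]:
    """Lay genes (gene_id, class, protein, strand) on one contig, in order,
    separated by random 50-300 nt gaps except where a gap is forced large."""
    parts = [_random_dna(rng, int(rng.integers(100, 200)))]
    pos = len(parts[0])
    feats = []
    for gene_id, cls, protein, strand in plan:
        cds = back_translate(protein)
        if strand == "-":
            cds = _revcomp(cds)
        start = pos + 1
        end = pos + len(cds)
        parts.append(cds)
        pos = end
        feats.append(GeneFeature(gene_id, "c1", start, end, strand, cls,
                                 protein_seq=protein))
        gap = _random_dna(rng, int(rng.integers(50, 300)))
        parts.append(gap)
        pos += len(gap)
    parts.append(_random_dna(rng, 100))
    return "".join(parts), feats


def _decoy(rng: np.random.Generator, seeds: dict[ProductClass, str]) -> str:
    """Shuffle a seed protein body — composition preserved, signal destroyed."""
    base = seeds[list(seeds)[int(rng.integers(len(seeds)))]]
    body = np.array(list(base[1:]))
    rng.shuffle(body)
    return "M" + "".join(body)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a genome cohort with planted arrangement ground truth.

    Each genome carries homologs mutated to ``ortholog_identity`` plus
    shuffled-decoy genes; all features record their true protein so the
    survey stage can run without re-translation. Deterministic per seed.
    """
    counts = spec.planted_counts()
    seeds = seed_proteins()
    rng = np.random.default_rng(spec.seed)
    assignments: list[Arrangement] = []
    for arr in sorted(counts, key=lambda a: a.value):
        assignments.extend([arr] * counts[arr])
    perm = rng.permutation(len(assignments))
    assignments = [assignments[i] for i in perm]
    genomes: list[Genome] = []
    truth: dict[str, Arrangement] = {}
    member_truth: dict[str, dict[ProductClass, str]] = {}

    for idx, arr in enumerate(assignments):
        gid = f"g{idx:03d}"
        grng = np.random.default_rng([spec.seed, idx])
        mut = {cls: mutate_protein(p, spec.ortholog_identity, grng)
               for cls, p in seeds.items()}
        decoys = [(f"{gid}_dec{i}", ProductClass.OTHER, _decoy(grng, seeds), "+")
                  for i in range(spec.n_decoys)]
        plan: list[tuple[str, ProductClass, str, str]] = []
        members: dict[ProductClass, str] = {}

        def _core(cls: ProductClass, strand: str = "+"):
            name = f"{gid}_{cls.value.lower()}"
            members[cls] = name
            return (name, cls, mut[cls], strand)

        if arr is Arrangement.FIVE_GENE_CLUSTER:
            plan = [decoys[0], _core(ProductClass.ACCA), _core(ProductClass.SDR),
                    _core(ProductClass.ADO), _core(ProductClass.AAR),
                    _core(ProductClass.FOLE), *decoys[1:]]
        elif arr is Arrangement.TANDEM_PAIR:
            plan = [decoys[0], _core(ProductClass.ADO), _core(ProductClass.AAR),
                    *decoys[1:]]
        elif arr is Arrangement.SPLIT:
            # separate the pair by several decoys => non-adjacent by order
            plan = [_core(ProductClass.ADO), *decoys,
                    _core(ProductClass.AAR)]
        else:  # ABSENT
            plan = list(decoys)

        seq, feats = _plant_genes(grng, plan)
        g = Genome(gid, {"c1": seq}, feats)
        g.validate()
        genomes.append(g)
        truth[gid] = arr
        member_truth[gid] = members
    return Cohort(genomes, truth, member_truth)


# ---------------------------------------------------------------------------
# TSS profiles with planted promoters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPromoter:
    contig_id: str
    position: int     # +1 nucleotide
    strand: str
    label: Optional[str] = None


def generate_tss_profile(
    genome: Genome,
    planted_promoters: Sequence[PlantedPromoter],
    hexamer: str = "TATAAT",
    offset: int = -7,
    mean_read_count: float = 50.0,
    seed: int = 0,
) -> tuple[Genome, list[TssRecord], list[dict]]:
    """Write a -10 box upstream of each planted TSS and emit the TSS table.

    The hexamer's 3' edge sits at ``offset`` relative to the +1 position
    (default -7, i.e. occupying -12..-7 in transcript coordinates). Read
    counts are geometric with the given mean; they are cosmetic. Returns the
    modified genome, the TSS records and the planted-truth list. Overlapping
    planted hexamers raise ``ValueError``.
    """
    rng = np.random.default_rng(seed)
    contigs = {cid: list(seq) for cid, seq in genome.contigs.items()}
    spans: list[tuple[str, int, int]] = []
    truth = []
    records = []
    for p in planted_promoters:
        seq = contigs[p.contig_id]
        if p.strand == "+":
            # transcript coordinate x < 0 maps to genomic p.position + x
            hi = p.position + offset          # 3' edge
            lo = hi - len(hexamer) + 1
            planted = hexamer
        else:
            # upstream of a minus-strand +1 lies at larger genomic coordinates
            lo = p.position - offset
            hi = lo + len(hexamer) - 1
            planted = _revcomp(hexamer)
        if lo < 1 or hi > len(seq):
            raise ValueError(f"planted promoter at {p.position} out of bounds")
        for (c0, l0, h0) in spans:
            if c0 == p.contig_id and not (hi < l0 or lo > h0):
                raise ValueError(
                    f"planted elements overlap at {p.contig_id}:{lo}-{hi}"
                )
        spans.append((p.contig_id, lo, hi))
        seq[lo - 1:hi] = list(planted)
        count = int(rng.geometric(1.0 / mean_read_count))
        records.append(TssRecord(p.position, p.strand, count, p.label))
        truth.append({"contig_id": p.contig_id, "position": p.position,
                      "strand": p.strand, "hexamer_span": (lo, hi),
                      "offset": offset})
    new_genome = Genome(genome.genome_id,
                        {cid: "".join(s) for cid, s in contigs.items()},
                        list(genome.features))
    return new_genome, records, truth


# ---------------------------------------------------------------------------
# terminator regions
# ---------------------------------------------------------------------------

def generate_terminator_region(
    stem_len: int,
    loop_len: int,
    u_tract_len: int,
    seed: int = 0,
    flank: int = 30,
    gc_stem: bool = True,
) -> tuple[str, dict]:
    """Random DNA with one planted intrinsic-terminator hairpin + U(T)-tract.

    Returns (sequence, truth) where truth holds the 1-based stem-arm and
    U-tract coordinates within the returned string. ``gc_stem`` plants a
    GC-only stem (maximal pairing score) as real terminator stems are GC-rich.
    """
    if stem_len < 3:
        raise ValueError("stem_len must be >= 3")
    if not 3 <= loop_len <= 10:
        raise ValueError("loop_len must be in [3, 10]")
    if u_tract_len < 0:
        raise ValueError("u_tract_len must be >= 0")
    rng = np.random.default_rng(seed)
    arm_alphabet = np.array(list("GC")) if gc_stem else _NT
    arm = "".join(rng.choice(arm_alphabet, size=stem_len))
    loop = "".join(rng.choice(np.array(list("AT")), size=loop_len))
    left = _random_dna(rng, flank)
    right = _random_dna(rng, flank)
    # pin the hairpin boundaries so chance flank bases cannot extend the
    # stem: C before the 5' arm cannot pair with the T (or pinned T) after
    # the 3' arm
    if left:
        left = left[:-1] + "C"
    if u_tract_len == 0 and right:
        right = "T" + right[1:]
    hairpin = arm + loop + _revcomp(arm) + "T" * u_tract_len
    seq = left + hairpin + right
    s0 = len(left) + 1
    truth = {
        "stem5_span": (s0, s0 + stem_len - 1),
        "loop_span": (s0 + stem_len, s0 + stem_len + loop_len - 1),
        "stem3_span": (s0 + stem_len + loop_len, s0 + 2 * stem_len + loop_len - 1),
        "u_tract_span": (s0 + 2 * stem_len + loop_len,
                         s0 + 2 * stem_len + loop_len + u_tract_len - 1),
        "stem_len": stem_len,
        "loop_len": loop_len,
        "u_tract_len": u_tract_len,
    }
    return seq, truth


# ---------------------------------------------------------------------------
# decay series
# ---------------------------------------------------------------------------

@dataclass
class DecaySpec:
    """Parameters of a synthetic rifampicin decay time-course.

    Default sampling matches the experimental design: a sample before the
    rifampicin block (t = 0) and 3, 5, 10 and 15 minutes after.
    """

    initial_signal: float
    half_life_min: float
    times_min: tuple[float, ...] = (0.0, 3.0, 5.0, 10.0, 15.0)
    noise_sd_log: float = 0.0
    seed: int = 0
    transcript_id: str = "tx"

    def __post_init__(self) -> None:
        if self.initial_signal <= 0 or self.half_life_min <= 0:
            raise ValueError("initial_signal and half_life_min must be positive")
        if self.noise_sd_log < 0:
            raise ValueError("noise_sd_log must be >= 0")
        t = tuple(self.times_min)
        if not t or t[0] != 0 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("times must start at 0 and increase strictly")


def generate_decay_series(spec: DecaySpec):
    """signal(t) = S0 * 2^(-t / half_life) * exp(eps), eps ~ N(0, sd_log)."""
    from .decay_kinetics import DecaySeries

    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times_min, dtype=float)
    signal = spec.initial_signal * np.power(2.0, -t / spec.half_life_min)
    if spec.noise_sd_log > 0:
        signal = signal * np.exp(rng.normal(0.0, spec.noise_sd_log, size=t.size))
    return DecaySeries(spec.transcript_id, tuple(t), tuple(signal))


# ---------------------------------------------------------------------------
# sequence evolution on a tree
# ---------------------------------------------------------------------------

def generate_alignment_on_tree(
    newick_with_lengths: str,
    seq_len: int,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve a root sequence down a tree under Jukes-Cantor.

    Branch lengths are expected substitutions per site: along a branch of
    length t each site changes with probability (3/4)(1 - e^(-4t/3)), to one
    of the other three bases uniformly. Returns {taxon: sequence}; the output
    is gap-free and aligned by construction.
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    try:
        tree = dendropy.Tree.get(data=newick_with_lengths, schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed newick tree: {exc}") from exc
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_len)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        if t < 0:
            raise ValueError("negative branch length")
        parent = seqs[id(node.parent_node)]
        p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
        child = parent.copy()
        flip = rng.random(seq_len) < p_change
        # uniform over the three other bases
        child[flip] = (child[flip] + rng.integers(1, 4, size=int(flip.sum()))) % 4
        seqs[id(node)] = child
    out = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label if leaf.taxon else "?"
        out[name] = "".join(_NT[seqs[id(leaf)]])
    return out
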