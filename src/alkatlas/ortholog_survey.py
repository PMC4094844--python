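"""Protein-level ortholog screen across genome cohorts.

Each genome is scanned for homologs of five reference proteins (ADO, AAR,
AccA, a short-chain dehydrogenase and GTP cyclohydrolase I) by optimal local
alignment (Smith-Waterman with affine gaps, BLOSUM62 by default) followed by
Karlin-Altschul E-value thresholding at E <= 1e-5. The result is one
presence profile per genome: the single best hit per product class, or
absence. "Ortholog" here means best one-way hit above threshold; a
reciprocal-best check is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp
from typing import Iterable, Mapping, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_model import Genome, HitRecord, ProductClass, translate_cds

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# standard gapped BLOSUM62 Karlin-Altschul parameters
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_EVALUE_THRESHOLD = 1e-5


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty protein sequence")
    for i, aa in enumerate(seq):
        if aa not in _AA_ALPHABET:
            raise ValueError(f"{name}: illegal residue {aa!r} at position {i + 1}")


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # BLAST convention: a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align_score(
    query: str,
    subject: str,
    substitution_matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Optimal Smith-Waterman local alignment score with affine gaps.

    A gap of length L costs ``gap_open + L * gap_extend`` (BLAST convention).
    The score is >= 0 (the empty alignment is always admissible) and symmetric
    in its sequence arguments.
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    _check_protein(query, "query")
    _check_protein(subject, "subject")
    if substitution_matrix is None:
        substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    return max(0.0, float(aligner.score(query, subject)))


def evalue(
    score: float,
    m: int,
    n: int,
    lam: float = DEFAULT_LAMBDA,
    k_const: float = DEFAULT_K,
) -> float:
    """Karlin-Altschul expected hit count E = K * m * n * exp(-lambda * S).

    ``m`` is the query length and ``n`` the total number of subject letters
    searched; E decreases strictly in the score and scales linearly in both
    lengths.
    """
    if lam <= 0 or k_const <= 0:
        raise ValueError("lambda and K must be positive")
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return k_const * m * n * exp(-lam * score)


@dataclass
class PresenceProfile:
    """Best hit (or absence) per product class for one genome."""

    genome_id: str
    detected: dict[ProductClass, Optional[HitRecord]] = field(default_factory=dict)

    @property
    def present_classes(self) -> set[ProductClass]:
        return {c for c, h in self.detected.items() if h is not None}


def find_orthologs(
    genome: Genome,
    queries: Mapping[ProductClass, str],
    threshold_evalue: float = DEFAULT_EVALUE_THRESHOLD,
    substitution_matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    lam: float = DEFAULT_LAMBDA,
    k_const: float = DEFAULT_K,
    reciprocal_best: bool = False,
) -> PresenceProfile:
    """Screen one genome's proteome for the query classes.

    For each class the best hit is the highest raw score, ties broken by
    smaller E-value then lexicographic gene id; it is reported only when its
    E-value is at or below ``threshold_evalue``. With ``reciprocal_best`` the
    hit must also score higher against its own query than against any other.
    """
    if not queries:
        raise ValueError("empty query set")
    if substitution_matrix is None:
        substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)

    proteome: dict[str, str] = {}
    for f in genome.features:
        prot = f.protein_seq if f.protein_seq is not None else translate_cds(f, genome)
        proteome[f.gene_id] = prot
    n_total = sum(len(p) for p in proteome.values()) or 1

    scores: dict[tuple[ProductClass, str], float] = {}
    for cls, query in queries.items():
        _check_protein(query, f"query {cls.value}")
        for gid, prot in proteome.items():
            scores[(cls, gid)] = max(0.0, float(aligner.score(query, prot)))

    detected: dict[ProductClass, Optional[HitRecord]] = {}
    for cls, query in queries.items():
        best: Optional[HitRecord] = None
        for gid in sorted(proteome):
            s = scores[(cls, gid)]
            e = evalue(s, len(query), n_total, lam, k_const)
            if e > threshold_evalue:
                continue
            if reciprocal_best and any(
                scores[(other, gid)] > s for other in queries if other != cls
            ):
                continue
            cand = HitRecord(cls.value, gid, genome.genome_id, s, e)
            if best is None or (cand.raw_score, -cand.evalue) > (best.raw_score, -best.evalue):
                best = cand
        detected[cls] = best
    return PresenceProfile(genome.genome_id, detected)


def profile_from_hits(
    hits: Iterable[HitRecord],
    genome_id: str,
    classes: Iterable[ProductClass],
    threshold_evalue: float = DEFAULT_EVALUE_THRESHOLD,
) -> PresenceProfile:
    """Build a presence profile from precomputed tabular alignment hits.

    This path lets cohort-scale screens run through an external aligner and
    feed its 12-column output in; the built-in aligner is for desk-scale use.
    Query ids must equal the product-class names.
    """
    detected: dict[ProductClass, Optional[HitRecord]] = {c: None for c in classes}
    for h in hits:
        if h.genome_id != genome_id or h.evalue > threshold_evalue:
            continue
        cls = ProductClass(h.query_id)
        cur = detected.get(cls)
        if cur is None or (h.raw_score, -h.evalue, cur.subject_gene_id) > (
            cur.raw_score, -cur.evalue, h.subject_gene_id
        ):
            detected[cls] = h
    return PresenceProfile(genome_id, detected)


def cooccurrence_summary(profiles: Iterable[PresenceProfile]) -> dict[str, int]:
    """Count genomes by joint ado/aar presence.

    Returns {"both", "ado_only", "aar_only", "neither"}; the four counts
    partition the cohort. The published screen found the ado_only and
    aar_only cells empty in all 181 genomes — the two genes travel together.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    counts = {"both": 0, "ado_only": 0, "aar_only": 0, "neither": 0}
    for p in profiles:
        ado = p.detected.get(ProductClass.ADO) is not None
        aar = p.detected.get(ProductClass.AAR) is not None
        key = ("both" if ado and aar else
               "ado_only" if ado else
               "aar_only" if aar else "neither")
        counts[key] += 1
    return counts
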