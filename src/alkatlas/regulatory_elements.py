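"""Sequence-level callers for promoter -10 boxes and intrinsic terminators.

Two small detectors used to support transcript-unit calls:

* ``scan_minus10`` slides a 6-mer position-specific scoring matrix (PSSM,
  built from the sigma70 TATAAT consensus by default) over a short window
  upstream of a TSS and reports the best placement above threshold.
* ``find_terminator_hairpin`` exhaustively enumerates stem-loop placements
  in a 3' region and scores base-pairing; a call additionally requires a
  U-rich tract immediately after the stem, the hallmark of Rho-independent
  termination. Sequences are handled in DNA space (T for U; GT wobble
  stands in for GU).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Optional

import numpy as np

from .genome_model import TssRecord

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGT", "TGCA")

# pair scores for stem pairing (DNA space): GC 3, AT 2, GT wobble 1
_PAIR_SCORE = {("G", "C"): 3.0, ("C", "G"): 3.0,
               ("A", "T"): 2.0, ("T", "A"): 2.0}
_WOBBLE_SCORE = {("G", "T"): 1.0, ("T", "G"): 1.0}


def build_pssm(consensus: str = "TATAAT", pseudocount: float = 0.1,
               background: float = 0.25) -> np.ndarray:
    """Log2-odds PSSM from a single consensus sequence with pseudocounts."""
    L = len(consensus)
    pssm = np.empty((L, 4))
    for i, base in enumerate(consensus):
        counts = np.full(4, pseudocount)
        counts[_IDX[base]] += 1.0
        probs = counts / counts.sum()
        pssm[i] = [log2(p / background) for p in probs]
    return pssm


DEFAULT_PSSM = build_pssm()
# ~70% of the consensus maximum (~9.9 bits): only near-consensus hexamers
# pass, which keeps the false-positive rate on random background well
# below 5% per scanned window set.
DEFAULT_MIN10_SCORE = 7.0


@dataclass(frozen=True)
class PromoterCall:
    tss: TssRecord
    hexamer_seq: str
    hexamer_offset: int   # 3' edge of the hexamer relative to +1 (negative)
    score: float


def _score_hexamer(hexamer: str, pssm: np.ndarray) -> float:
    return float(sum(pssm[i, _IDX[b]] for i, b in enumerate(hexamer)))


def scan_minus10(
    sequence: str,
    tss: TssRecord,
    window: tuple[int, int] = (-16, -4),
    pssm: Optional[np.ndarray] = None,
    min_score: float = DEFAULT_MIN10_SCORE,
) -> Optional[PromoterCall]:
    """Best -10 hexamer placement upstream of a TSS, or None below threshold.

    ``window`` bounds the allowed offsets of the hexamer's 3' edge relative
    to the +1 nucleotide (default -16..-4, the standard spacer range around
    the canonical -7). Ties in score are broken toward the offset nearest
    -7. Raises ``ValueError`` when the scan would run off the contig.
    """
    if pssm is None:
        pssm = DEFAULT_PSSM
    lo_off, hi_off = window
    if not (lo_off < hi_off < 0):
        raise ValueError("window must be negative offsets (lo < hi < 0)")
    hexlen = pssm.shape[0]
    best: Optional[tuple[float, int, int, str]] = None  # (score, |o+7|, -o, seq)
    for off in range(lo_off, hi_off + 1):
        if tss.strand == "+":
            hi = tss.position + off
            lo = hi - hexlen + 1
            if lo < 1 or hi > len(sequence):
                raise ValueError("TSS too close to contig edge for scan window")
            hexamer = sequence[lo - 1:hi]
        else:
            lo = tss.position - off
            hi = lo + hexlen - 1
            if lo < 1 or hi > len(sequence):
                raise ValueError("TSS too close to contig edge for scan window")
            hexamer = sequence[lo - 1:hi].translate(_COMP)[::-1]
        s = _score_hexamer(hexamer, pssm)
        key = (s, -abs(off + 7), off)
        if best is None or key > (best[0], -abs(best[1] + 7), best[1]):
            best = (s, off, 0, hexamer)
    assert best is not None
    score, off, _, hexamer = best
    if score < min_score:
        return None
    return PromoterCall(tss, hexamer, off, score)


@dataclass(frozen=True)
class TerminatorCall:
    stem_len: int
    loop_len: int
    pairing_score: float
    u_tract_len: int
    start: int   # 1-based, first nt of the 5' stem arm
    end: int     # last nt of the 3' stem arm


DEFAULT_TERMINATOR_MIN_SCORE = 16.0


def find_terminator_hairpin(
    sequence: str,
    search_span: Optional[tuple[int, int]] = None,
    min_stem: int = 4,
    max_stem: int = 15,
    loop_range: tuple[int, int] = (3, 10),
    u_min: int = 3,
    u_window: int = 6,
    allow_gu: bool = True,
    min_score: float = DEFAULT_TERMINATOR_MIN_SCORE,
) -> Optional[TerminatorCall]:
    """Exhaustive stem-loop scan for a Rho-independent terminator.

    Every (start, stem length, loop length) placement whose arms are fully
    reverse-complementary under the allowed pairs is scored as
    ``3*GC + 2*AT + 1*GT - 0.5*loop_len``; a placement qualifies only when
    at least ``u_min`` T's fall in the ``u_window`` nucleotides after the 3'
    stem arm (the U-tract is mandatory). Returns the best call by score,
    ties toward longer stems then leftmost placement, or None when nothing
    reaches ``min_score``.
    """
    if min_stem < 3 or max_stem < min_stem:
        raise ValueError("need 3 <= min_stem <= max_stem")
    lo_loop, hi_loop = loop_range
    if not 3 <= lo_loop <= hi_loop <= 10:
        raise ValueError("loop_range must lie within [3, 10]")
    if u_min < 1 or u_window < u_min:
        raise ValueError("need 1 <= u_min <= u_window")
    if search_span is None:
        search_span = (1, len(sequence))
    lo, hi = search_span
    if lo < 1 or hi > len(sequence) or lo > hi:
        raise ValueError("search_span outside sequence")

    pair = dict(_PAIR_SCORE)
    if allow_gu:
        pair.update(_WOBBLE_SCORE)

    best: Optional[TerminatorCall] = None
    region = sequence
    for start in range(lo, hi + 1):
        for stem in range(min_stem, max_stem + 1):
            for loop in range(lo_loop, hi_loop + 1):
                end = start + 2 * stem + loop - 1
                if end > hi:
                    continue
                score = -0.5 * loop
                ok = True
                for k in range(stem):
                    a = region[start - 1 + k]
                    b = region[end - 1 - k]
                    ps = pair.get((a, b))
                    if ps is None:
                        ok = False
                        break
                    score += ps
                if not ok:
                    continue
                tail = region[end:end + u_window]
                if tail.count("T") < u_min:
                    continue
                # U-tract length: longest T-run starting within 2 nt of the stem
                u_len = 0
                for off in range(min(3, len(tail))):
                    if tail[off] != "T":
                        continue
                    run = 0
                    j = end + off
                    while j < len(region) and region[j] == "T":
                        run += 1
                        j += 1
                    u_len = max(u_len, run)
                    break
                cand = TerminatorCall(stem, loop, score, u_len, start, end)
                if best is None or (cand.pairing_score, cand.stem_len, -cand.start) > (
                        best.pairing_score, best.stem_len, -best.start):
                    best = cand
    if best is None or best.pairing_score < min_score:
        return None
    return best
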