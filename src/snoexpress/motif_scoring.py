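"""Box-motif detection and Hamming-distance box scores for snoRNAs.

C/D box snoRNAs carry a C box (consensus RUGAUGA, R a purine) near the 5'
end, a D box (CUGA) near the 3' end, and an internal C'/D' copy; H/ACA box
snoRNAs carry an H box (ANANNA) in the unpaired hinge and a 3'-terminal
ACA. The box score sums Hamming distances to those consensus motifs; a
motif that cannot be identified contributes its full length, so the score
ranges over [0, 22] for C/D and {0, 3, 6, 9} for H/ACA snoRNAs.

Search rules: the C and D boxes are looked for only within the first and
last 20 nt respectively (exact consensus preferred, at most 3 and 2
mismatches tolerated); the C'/D' pair is the total-Hamming-minimizing pair
inside the 21st..21st-to-last region with D' upstream of C'; H and ACA are
exact-match only, H restricted to structurally unpaired positions and ACA
to the last 10 nt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

CONSENSUS: Mapping[str, str] = {
    "C": "RUGAUGA",
    "D": "CUGA",
    "Cprime": "RUGAUGA",
    "Dprime": "CUGA",
    "H": "ANANNA",
    "ACA": "ACA",
}
MOTIF_LENGTHS: Mapping[str, int] = {k: len(v) for k, v in CONSENSUS.items()}
MISMATCH_CAPS: Mapping[str, int] = {"C": 3, "D": 2, "H": 0, "ACA": 0}
TERMINAL_WINDOW = 20  # C/D search confinement, nt
ACA_WINDOW = 10
CD_MOTIFS = ("C", "D", "Cprime", "Dprime")
HACA_MOTIFS = ("H", "ACA")

_IDX = {c: i for i, c in enumerate("ACGU")}
_IUPAC = {"R": "AG", "N": "ACGUN", "A": "A", "C": "C", "G": "G", "U": "U"}


@dataclass(frozen=True)
class MotifHit:
    kind: str
    start: int | None
    observed: str | None
    hamming: int
    found: bool

    @staticmethod
    def not_found(kind: str) -> "MotifHit":
        return MotifHit(kind, None, None, MOTIF_LENGTHS[kind], False)


@dataclass(frozen=True)
class BoxScore:
    hits: Mapping[str, MotifHit]
    total: int


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_IDX.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


def _allowed_mask(consensus: str) -> np.ndarray:
    mask = np.zeros((len(consensus), 5), dtype=bool)
    for k, ch in enumerate(consensus):
        for nt in _IUPAC[ch]:
            mask[k, _IDX.get(nt, 4)] = True
    return mask


_MASKS = {kind: _allowed_mask(cons) for kind, cons in CONSENSUS.items()}


def hamming(seq: str, consensus: str) -> int:
    """Mismatches of `seq` against an IUPAC consensus of equal length."""
    if len(seq) != len(consensus):
        raise ValueError("length mismatch")
    return sum(nt not in _IUPAC[c] for nt, c in zip(seq, consensus))


def _profile(encoded: np.ndarray, kind: str) -> np.ndarray:
    """Hamming distance of every window of the motif's length; empty when
    the sequence is shorter than the motif."""
    mask = _MASKS[kind]
    L = mask.shape[0]
    if len(encoded) < L:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(encoded, L)
    return (~mask[np.arange(L), windows]).sum(axis=1)


def find_c_box(seq: str) -> MotifHit:
    """C box (RUGAUGA, <=3 mismatches) within the first 20 nt; ties go to
    the offset nearest the 5' end."""
    prof = _profile(_encode(seq[:TERMINAL_WINDOW]), "C")
    if prof.size == 0:
        return MotifHit.not_found("C")
    off = int(np.argmin(prof))  # first minimum = nearest 5' end
    if prof[off] > MISMATCH_CAPS["C"]:
        return MotifHit.not_found("C")
    return MotifHit("C", off, seq[off : off + 7], int(prof[off]), True)


def find_d_box(seq: str) -> MotifHit:
    """D box (CUGA, <=2 mismatches) within the last 20 nt; ties go to the
    offset nearest the 3' end."""
    window = seq[-TERMINAL_WINDOW:]
    base = len(seq) - len(window)
    prof = _profile(_encode(window), "D")
    if prof.size == 0:
        return MotifHit.not_found("D")
    off = int(prof.size - 1 - np.argmin(prof[::-1]))  # last minimum
    if prof[off] > MISMATCH_CAPS["D"]:
        return MotifHit.not_found("D")
    start = base + off
    return MotifHit("D", start, seq[start : start + 4], int(prof[off]), True)


def find_cprime_dprime(seq: str) -> tuple[MotifHit, MotifHit]:
    """Best internal D'/C' pair minimizing total Hamming distance.

    Both motifs are confined to positions 20..len-21 (the 21st through
    21st-to-last nucleotide), with the D' box entirely upstream of the C'
    box. There is no mismatch cap: any admissible pair is reported. Ties
    break lexicographically on (D' offset, C' offset). A region too short
    to hold the pair (< 11 nt) returns both motifs as not found.
    """
    lo, hi = TERMINAL_WINDOW, len(seq) - TERMINAL_WINDOW  # half-open region
    if hi - lo < MOTIF_LENGTHS["Dprime"] + MOTIF_LENGTHS["Cprime"]:
        return MotifHit.not_found("Dprime"), MotifHit.not_found("Cprime")

    region = _encode(seq[lo:hi])
    dprof = _profile(region, "Dprime")  # offsets lo .. hi-4
    cprof = _profile(region, "Cprime")  # offsets lo .. hi-7

    best: tuple[int, int, int] | None = None  # (total, d_off, c_off), offsets absolute
    pm_val, pm_off = np.iinfo(np.int64).max, -1
    j = 0
    for ci in range(cprof.size):
        c_abs = lo + ci
        while j < dprof.size and lo + j + MOTIF_LENGTHS["Dprime"] <= c_abs:
            if dprof[j] < pm_val:
                pm_val, pm_off = int(dprof[j]), lo + j
            j += 1
        if pm_off < 0:
            continue
        total = pm_val + int(cprof[ci])
        cand = (total, pm_off, c_abs)
        if best is None or cand < best:
            best = cand
    if best is None:
        return MotifHit.not_found("Dprime"), MotifHit.not_found("Cprime")

    _, d_off, c_off = best
    d_h = hamming(seq[d_off : d_off + 4], CONSENSUS["Dprime"])
    c_h = hamming(seq[c_off : c_off + 7], CONSENSUS["Cprime"])
    return (
        MotifHit("Dprime", d_off, seq[d_off : d_off + 4], d_h, True),
        MotifHit("Cprime", c_off, seq[c_off : c_off + 7], c_h, True),
    )


def find_h_box(seq: str, structure: str | None = None) -> MotifHit:
    """First exact ANANNA whose six positions are all unpaired in the
    secondary structure (exact-match only).

    Without a structure the search falls back to positions 20..len-21 with
    a logged warning.
    """
    if structure is not None:
        if len(structure) != len(seq):
            raise ValueError("structure length != sequence length")
        offsets = range(0, len(seq) - 5)
    else:
        logger.warning("H-box search without structure; using internal region")
        offsets = range(TERMINAL_WINDOW, len(seq) - TERMINAL_WINDOW - 5)
    for i in offsets:
        window = seq[i : i + 6]
        if hamming(window, CONSENSUS["H"]) == 0 and (
            structure is None or structure[i : i + 6] == "......"
        ):
            return MotifHit("H", i, window, 0, True)
    return MotifHit.not_found("H")


def find_aca_box(seq: str) -> MotifHit:
    """3'-most exact ACA within the last 10 nt (canonically 3 nt from the
    3' end)."""
    window = seq[-ACA_WINDOW:]
    pos = window.rfind("ACA")
    if pos < 0:
        return MotifHit.not_found("ACA")
    start = len(seq) - len(window) + pos
    return MotifHit("ACA", start, "ACA", 0, True)


def box_score(seq: str, sno_type: str, structure: str | None = None) -> BoxScore:
    """Per-snoRNA box score: the sum of motif Hamming distances, with
    unidentifiable motifs contributing their full length."""
    if sno_type == "CD":
        dprime, cprime = find_cprime_dprime(seq)
        hits = {
            "C": find_c_box(seq),
            "D": find_d_box(seq),
            "Dprime": dprime,
            "Cprime": cprime,
        }
    elif sno_type == "HACA":
        hits = {"H": find_h_box(seq, structure), "ACA": find_aca_box(seq)}
    else:
        raise ValueError(f"unknown snoRNA type {sno_type!r}")
    return BoxScore(hits, sum(h.hamming for h in hits.values()))
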