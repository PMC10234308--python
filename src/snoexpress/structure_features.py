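"""Folding-derived snoRNA features: global stability and the terminal stem.

The terminal stem is the duplex formed by the sequences flanking the two
ends of a snoRNA: the 15-nt genomic flanks, each extended into the snoRNA
body (C/D: 5 nt on both sides; H/ACA: 5 nt at the 5' end but only 3 nt at
the 3' end, leaving the ACA motif out of the stem). Co-folding the two
extended strands yields the stem stability (MFE, kcal/mol) and a length
score: the number of intermolecularly paired nucleotides minus the number
of nucleotides inside gaps within the stem.

The folding engine is pluggable. The default wraps the ViennaRNA
thermodynamic model (RNAfold/RNAcofold, default parameters); a built-in
maximum-complementarity scorer exists only for engine-free environments
and is explicitly non-thermodynamic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

logger = logging.getLogger(__name__)

MIN_SNO_LENGTH = {"CD": 10, "HACA": 8}
_EXTENSION_5P = 5
_EXTENSION_3P = {"CD": 5, "HACA": 3}


@dataclass(frozen=True)
class FoldResult:
    structure: str
    mfe: float


@dataclass(frozen=True)
class DuplexResult:
    """Co-fold of the two terminal-stem strands.

    `structure` is the combined dot-bracket over strand5 + strand3 with the
    strand boundary at `cut` (= len(strand5)). Intermolecular pairs are
    indexed (i on strand5, j on strand3), both 0-based within the combined
    string.
    """

    strand5: str
    strand3: str
    structure: str
    mfe: float

    @property
    def cut(self) -> int:
        return len(self.strand5)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return parse_pairs(self.structure)

    @property
    def intermolecular_pairs(self) -> tuple[tuple[int, int], ...]:
        cut = self.cut
        return tuple((i, j) for i, j in self.pairs if i < cut <= j)


class EngineUnavailableError(RuntimeError):
    pass


class ViennaFoldingEngine:
    """Thermodynamic MFE folding via the ViennaRNA bindings (default
    parameters, energies in kcal/mol)."""

    name = "vienna"

    def __init__(self) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - engine present in CI image
            raise EngineUnavailableError(
                "ViennaRNA Python bindings not importable; install the "
                "viennarna package or select engine='maxcomp'"
            ) from exc
        self._rna = RNA

    def fold(self, seq: str) -> FoldResult:
        structure, mfe = self._rna.fold(seq)
        return FoldResult(structure, round(float(mfe), 2))

    def cofold(self, seq_a: str, seq_b: str) -> tuple[str, float]:
        structure, mfe = self._rna.cofold(f"{seq_a}&{seq_b}")
        return structure, round(float(mfe), 2)


class MaxComplementarityEngine:
    """NON-THERMODYNAMIC fallback: maximum weighted complementarity.

    Nussinov-style maximization with pair weights GC=3, AU=2, GU=1 and a
    minimum hairpin loop of 3 nt; the pseudo-energy is -(total weight)/2
    kcal/mol. Useful only where ViennaRNA is absent; magnitudes are not
    comparable to thermodynamic MFEs.
    """

    name = "maxcomp"
    _WEIGHTS = {
        ("G", "C"): 3, ("C", "G"): 3,
        ("A", "U"): 2, ("U", "A"): 2,
        ("G", "U"): 1, ("U", "G"): 1,
    }

    def _solve(self, seq: str, min_loop_of) -> tuple[str, float]:
        n = len(seq)
        W = np.zeros((n + 1, n + 1))
        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                best = max(W[i + 1][j], W[i][j - 1])
                w = self._WEIGHTS.get((seq[i], seq[j]), 0)
                if w and j - i - 1 >= min_loop_of(i, j):
                    best = max(best, W[i + 1][j - 1] + w)
                for k in range(i + 1, j):
                    best = max(best, W[i][k] + W[k + 1][j])
                W[i][j] = best
        structure = ["."] * n

        def trace(i: int, j: int) -> None:
            while i < j:
                if W[i][j] == W[i + 1][j]:
                    i += 1
                    continue
                if W[i][j] == W[i][j - 1]:
                    j -= 1
                    continue
                w = self._WEIGHTS.get((seq[i], seq[j]), 0)
                if w and j - i - 1 >= min_loop_of(i, j) and W[i][j] == W[i + 1][j - 1] + w:
                    structure[i], structure[j] = "(", ")"
                    i, j = i + 1, j - 1
                    continue
                for k in range(i + 1, j):
                    if W[i][j] == W[i][k] + W[k + 1][j]:
                        trace(i, k)
                        i = k + 1
                        break
                else:  # pragma: no cover - defensive
                    break

        if n:
            trace(0, n - 1)
        return "".join(structure), -W[0][n - 1] / 2.0

    def fold(self, seq: str) -> FoldResult:
        structure, energy = self._solve(seq, lambda i, j: 3)
        return FoldResult(structure, energy)

    def cofold(self, seq_a: str, seq_b: str) -> tuple[str, float]:
        cut = len(seq_a)
        # no loop-size constraint across the strand boundary
        return self._solve(
            seq_a + seq_b, lambda i, j: 0 if i < cut <= j else 3
        )


@lru_cache(maxsize=None)
def get_engine(name: str = "vienna"):
    if name == "vienna":
        return ViennaFoldingEngine()
    if name == "maxcomp":
        return MaxComplementarityEngine()
    raise ValueError(f"unknown folding engine {name!r}")


def parse_pairs(structure: str) -> tuple[tuple[int, int], ...]:
    """Base pairs (i, j), i < j, from a dot-bracket string."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for k, ch in enumerate(structure):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), k))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} in dot-bracket string")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return tuple(sorted(pairs))


def fold_global(seq: str, engine=None) -> FoldResult:
    """Global MFE structure of a snoRNA (feature `sno_stability`)."""
    if not seq:
        raise ValueError("empty sequence")
    engine = engine or get_engine()
    result = engine.fold(seq)
    if len(result.structure) != len(seq):
        raise RuntimeError("engine returned structure of wrong length")
    return result


def build_stem_strands(
    sequence: str, sno_type: str, upstream: str, downstream: str
) -> tuple[str, str]:
    """Assemble the two terminal-stem strands from the 15-nt flanks.

    strand5 = upstream flank + first 5 snoRNA nt; strand3 = last 5 (C/D)
    or last 3 (H/ACA) snoRNA nt + downstream flank.
    """
    minimum = MIN_SNO_LENGTH[sno_type]
    if len(sequence) < minimum:
        raise ValueError(
            f"snoRNA of {len(sequence)} nt too short for stem strands "
            f"(minimum {minimum} for {sno_type})"
        )
    ext3 = _EXTENSION_3P[sno_type]
    return upstream + sequence[:_EXTENSION_5P], sequence[-ext3:] + downstream


def cofold_stem(strand5: str, strand3: str, engine=None) -> DuplexResult:
    """Co-fold the terminal-stem strands (feature `terminal_stem_stability`)."""
    if not strand5 or not strand3:
        raise ValueError(f"empty stem strand (strand5={strand5!r}, strand3={strand3!r})")
    engine = engine or get_engine()
    structure, mfe = engine.cofold(strand5, strand3)
    if len(structure) != len(strand5) + len(strand3):
        raise RuntimeError(
            f"engine returned structure of wrong length for {strand5}&{strand3}"
        )
    return DuplexResult(strand5, strand3, structure, mfe)


def stem_length_score(duplex: DuplexResult, mode: str = "nucleotides") -> int:
    """Terminal-stem length score: intermolecularly paired nucleotides minus
    nucleotides within gaps inside the stem.

    `mode="nucleotides"` counts both partners of each pair (2 per pair);
    `mode="pairs"` counts pairs once. Gap nucleotides are the unpaired
    positions on either strand lying strictly between that strand's
    outermost intermolecular pairs. No intermolecular pair -> 0.
    """
    inter = duplex.intermolecular_pairs
    if not inter:
        return 0
    if mode == "nucleotides":
        paired = 2 * len(inter)
    elif mode == "pairs":
        paired = len(inter)
    else:
        raise ValueError(f"unknown length_score_mode {mode!r}")

    gaps = 0
    for positions in (sorted(i for i, _ in inter), sorted(j for _, j in inter)):
        span = range(positions[0] + 1, positions[-1])
        engaged = set(positions)
        gaps += sum(
            1 for k in span if k not in engaged and duplex.structure[k] == "."
        )
    return paired - gaps
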