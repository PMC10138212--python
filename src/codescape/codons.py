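"""Genetic codes, codon indexing, and the random-code ensemble constraints.

A genetic code is a 64-entry mapping from codons to the 20 amino acids or
the stop signal.  Codons are indexed 0..63 in the order UUU, UUC, ..., GGG
(base order U, C, A, G; index = 16*b1 + 4*b2 + b3), matching the standard
codon-table layout.  Internally a code is an ``int8`` array of length 64
holding amino-acid indices 0..19 (alphabetical one-letter order) with -1 at
the three stop positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "UCAG"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")

#: One-letter amino-acid codes in the internal index order (alphabetical).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
STOP = "*"

#: Codon indices of the three SGC stop codons (UAA, UAG, UGA).
STOP_CODONS = (10, 11, 14)
SENSE_CODONS = tuple(i for i in range(64) if i not in STOP_CODONS)

N_CODONS = 64
N_SENSE = 61
N_AA = 20

_SGC_ROWS = {
    "U": ("FFLL", "SSSS", "YY**", "CC*W"),
    "C": ("LLLL", "PPPP", "HHQQ", "RRRR"),
    "A": ("IIIM", "TTTT", "NNKK", "SSRR"),
    "G": ("VVVV", "AAAA", "DDEE", "GGGG"),
}


def codon_index(bases: str) -> int:
    """Return the 0-based index of a codon given as a 3-letter RNA string.

    UUU maps to 0 and GGG to 63; the enumeration runs U < C < A < G in each
    position, most-significant first.
    """
    if len(bases) != 3:
        raise ValueError(f"codon must have 3 bases, got {bases!r}")
    idx = 0
    for b in bases:
        pos = BASES.find(b)
        if pos < 0:
            raise ValueError(f"unknown base {b!r} in codon {bases!r}")
        idx = idx * 4 + pos
    return idx


def codon_from_index(index: int) -> str:
    """Inverse of :func:`codon_index`."""
    if not 0 <= index < 64:
        raise ValueError(f"codon index out of range: {index}")
    return BASES[index >> 4] + BASES[(index >> 2) & 3] + BASES[index & 3]


ALL_CODONS = tuple(codon_from_index(i) for i in range(64))


def is_transition(b1: str, b2: str) -> bool:
    """True iff the base interchange b1 <-> b2 is a transition.

    A transition swaps within the purines (A <-> G) or within the
    pyrimidines (C <-> U); everything else is a transversion.  Identical
    bases are rejected: they are neither.
    """
    for b in (b1, b2):
        if b not in PURINES and b not in PYRIMIDINES:
            raise ValueError(f"unknown base {b!r}")
    if b1 == b2:
        raise ValueError("identical bases are neither transition nor transversion")
    return (b1 in PURINES) == (b2 in PURINES)


@dataclass(frozen=True)
class EnsembleConstraints:
    """The conditions defining the fully random genetic-code ensemble.

    Defaults: stop codons pinned to the SGC positions, all 20 amino acids
    present, and at least two Asp and two Glu (the counts in the SGC).  The
    relaxed ensemble drops the Asp/Glu floor to one (still implied by
    requiring all 20 amino acids).
    """

    stop_positions_fixed: bool = True
    require_all_20: bool = True
    min_asp: int = 2
    min_glu: int = 2

    def minima(self) -> np.ndarray:
        """Per-amino-acid minimum multiplicities as an int array."""
        base = 1 if self.require_all_20 else 0
        m = np.full(N_AA, base, dtype=np.int64)
        m[AA_INDEX["D"]] = max(base, self.min_asp)
        m[AA_INDEX["E"]] = max(base, self.min_glu)
        return m


RELAXED_CONSTRAINTS = EnsembleConstraints(min_asp=1, min_glu=1)


class GeneticCode:
    """A 64-codon genetic code.

    Parameters
    ----------
    assignments
        Either a 64-character string over the amino-acid one-letter codes
        plus ``*`` for stop, or an int array of length 64 with values in
        0..19 and -1 at stop positions.
    """

    __slots__ = ("assign",)

    def __init__(self, assignments):
        if isinstance(assignments, str):
            if len(assignments) != 64:
                raise ValueError("code string must have 64 characters")
            arr = np.empty(64, dtype=np.int8)
            for i, ch in enumerate(assignments):
                if ch == STOP:
                    arr[i] = -1
                elif ch in AA_INDEX:
                    arr[i] = AA_INDEX[ch]
                else:
                    raise ValueError(f"unknown symbol {ch!r} at codon {i}")
        else:
            arr = np.asarray(assignments, dtype=np.int8).copy()
            if arr.shape != (64,):
                raise ValueError("assignment array must have shape (64,)")
            if arr.min() < -1 or arr.max() > 19:
                raise ValueError("assignment values must lie in -1..19")
        self.assign = arr

    # -- serialization -------------------------------------------------
    def to_string(self) -> str:
        """64-character serialization in codon-index order ('*' = stop)."""
        return "".join(
            STOP if a < 0 else AMINO_ACIDS[a] for a in self.assign
        )

    def to_dict(self) -> dict:
        """JSON-style mapping {codon triple: one-letter symbol}."""
        s = self.to_string()
        return {ALL_CODONS[i]: s[i] for i in range(64)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "GeneticCode":
        chars = [mapping[c] for c in ALL_CODONS]
        return cls("".join(chars))

    # -- queries -------------------------------------------------------
    def symbol(self, codon: int | str) -> str:
        if isinstance(codon, str):
            codon = codon_index(codon)
        a = self.assign[codon]
        return STOP if a < 0 else AMINO_ACIDS[a]

    def stop_positions(self) -> tuple:
        return tuple(int(i) for i in np.flatnonzero(self.assign < 0))

    def aa_counts(self) -> np.ndarray:
        """Count of each of the 20 amino acids over the 64 entries."""
        sense = self.assign[self.assign >= 0]
        return np.bincount(sense, minlength=N_AA).astype(np.int64)

    def __eq__(self, other):
        return isinstance(other, GeneticCode) and np.array_equal(
            self.assign, other.assign
        )

    def __hash__(self):
        return hash(self.assign.tobytes())

    def __repr__(self):
        return f"GeneticCode({self.to_string()!r})"


def sgc() -> GeneticCode:
    """The standard genetic code (3 stops at UAA/UAG/UGA, 61 sense codons)."""
    chars = []
    for b1 in BASES:
        for row in _SGC_ROWS[b1]:
            chars.append(row)
    return GeneticCode("".join(chars))


def validate_code(code: GeneticCode, constraints: EnsembleConstraints) -> list:
    """List the ensemble-condition violations of ``code`` (empty = valid).

    Violations are returned as human-readable strings naming the failed
    condition: stop placement/count, missing amino acids, or Asp/Glu
    multiplicities below the floor.
    """
    violations = []
    stops = code.stop_positions()
    if constraints.stop_positions_fixed and stops != STOP_CODONS:
        violations.append(
            f"stop codons at {stops}, expected SGC positions {STOP_CODONS}"
        )
    counts = code.aa_counts()
    if constraints.require_all_20:
        missing = [AMINO_ACIDS[i] for i in range(N_AA) if counts[i] == 0]
        if missing:
            violations.append(f"missing amino acids: {''.join(missing)}")
    if counts[AA_INDEX["D"]] < constraints.min_asp:
        violations.append(
            f"Asp count {counts[AA_INDEX['D']]} < required {constraints.min_asp}"
        )
    if counts[AA_INDEX["E"]] < constraints.min_glu:
        violations.append(
            f"Glu count {counts[AA_INDEX['E']]} < required {constraints.min_glu}"
        )
    return violations
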