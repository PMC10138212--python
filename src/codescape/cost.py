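"""Translational-misreading cost of a genetic code.

The cost of a code is the mean substitution penalty over single-base
misreading events,

    cost(a) = sum_{c,c'} P(c'|c) d(a(c), a(c')),

where the misreading weight of an ordered codon pair depends only on which
base position changes and on whether the change is a transition (TS) or a
transversion (TV): third base, any change, 1; first base, 1 (TS) or 0.5
(TV); second base, 0.5 (TS) or 0.1 (TV); multi-base changes never occur.
P(c'|c) is the raw weight divided by the total raw weight over all ordered
sense-sense neighbor pairs; pairs involving a stop codon carry constant
costs c0/c1 (default 0) and are excluded from the normalization.  The
default penalty d is the squared polar-requirement difference, under which
the standard code scores 2.63.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import (
    ALL_CODONS,
    GeneticCode,
    N_AA,
    N_CODONS,
    STOP_CODONS,
    is_transition,
)
from .scales import PropertyScale

#: Raw misreading weights by (changed position, TS?) per the error spectrum.
POSITION_WEIGHTS = {
    (0, True): 1.0,
    (0, False): 0.5,
    (1, True): 0.5,
    (1, False): 0.1,
    (2, True): 1.0,
    (2, False): 1.0,
}


def _neighbor_tables() -> tuple[np.ndarray, np.ndarray]:
    """(64, 9) neighbor codon indices and raw weights for single-base changes."""
    nb = np.empty((N_CODONS, 9), dtype=np.int64)
    wt = np.empty((N_CODONS, 9), dtype=np.float64)
    for c in range(N_CODONS):
        digits = [(c >> 4) & 3, (c >> 2) & 3, c & 3]
        k = 0
        for pos in range(3):
            for alt in range(4):
                if alt == digits[pos]:
                    continue
                d2 = digits.copy()
                d2[pos] = alt
                c2 = (d2[0] << 4) | (d2[1] << 2) | d2[2]
                b1, b2 = "UCAG"[digits[pos]], "UCAG"[alt]
                ts = is_transition(b1, b2)
                nb[c, k] = c2
                wt[c, k] = POSITION_WEIGHTS[(pos, ts)]
                k += 1
    return nb, wt


@dataclass(frozen=True)
class MisreadingModel:
    """Sparse single-base misreading weight structure over the 64 codons."""

    neighbors: np.ndarray  # (64, 9) int64
    raw_weights: np.ndarray  # (64, 9) float64

    def weight(self, c: int, c2: int) -> float:
        """Raw weight of the ordered pair (c, c2); 0 unless single-base neighbors."""
        hits = np.flatnonzero(self.neighbors[c] == c2)
        return float(self.raw_weights[c, hits[0]]) if hits.size else 0.0

    def normalization(self, stop_positions=STOP_CODONS) -> float:
        """Total raw weight over ordered sense-sense neighbor pairs."""
        stop = np.zeros(N_CODONS, dtype=bool)
        stop[list(stop_positions)] = True
        mask = ~stop[:, None] & ~stop[self.neighbors]
        return float(self.raw_weights[mask].sum())


def misreading_weights() -> MisreadingModel:
    """The standard-model misreading weights (TS/TV, per-position)."""
    nb, wt = _neighbor_tables()
    return MisreadingModel(nb, wt)


@dataclass(frozen=True)
class SubstitutionPenalty:
    """Symmetric amino-acid substitution penalty d(a, a').

    ``kind`` is "squared-property-difference" (d = (v_a - v_b)^2, zero
    diagonal) or "matrix-derived" (a score matrix turned into a distance).
    """

    kind: str
    matrix: np.ndarray  # (20, 20) float64, symmetric

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (N_AA, N_AA):
            raise ValueError("penalty matrix must be 20x20")
        if not np.allclose(m, m.T):
            raise ValueError("penalty matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def squared_difference(cls, scale: PropertyScale) -> "SubstitutionPenalty":
        v = scale.values
        return cls("squared-property-difference", (v[:, None] - v[None, :]) ** 2)

    @classmethod
    def from_score_matrix(cls, scores: np.ndarray) -> "SubstitutionPenalty":
        """Distance from a similarity-score matrix (e.g. BLOSUM62).

        Uses d(a,b) = (S(a,a) + S(b,b))/2 - S(a,b) after symmetrizing S: a
        monotone-decreasing transform of the score with zero diagonal.
        """
        s = np.asarray(scores, dtype=np.float64)
        s = (s + s.T) / 2.0
        diag = np.diag(s)
        d = (diag[:, None] + diag[None, :]) / 2.0 - s
        return cls("matrix-derived", d)

    @classmethod
    def blosum62(cls) -> "SubstitutionPenalty":
        """The BLOSUM62-derived penalty variant."""
        from Bio.Align import substitution_matrices

        from .codons import AMINO_ACIDS

        bl = substitution_matrices.load("BLOSUM62")
        idx = [bl.alphabet.index(a) for a in AMINO_ACIDS]
        scores = np.asarray(bl)[np.ix_(idx, idx)]
        return cls.from_score_matrix(scores)


@dataclass(frozen=True)
class CostConfig:
    """Cost-function configuration.

    ``c0`` is the constant cost of misreading a sense codon as a stop,
    ``c1`` of misreading a stop as sense; both default to 0 (they only
    shift the baseline).  ``source_weights`` optionally weights each term
    by the frequency of the source amino acid (the amino-acid-frequency
    cost variant); ``None`` means uniform.
    """

    penalty: SubstitutionPenalty
    c0: float = 0.0
    c1: float = 0.0
    source_weights: np.ndarray | None = None

    @classmethod
    def polar_requirement_default(cls) -> "CostConfig":
        from .scales import polar_requirement

        return cls(SubstitutionPenalty.squared_difference(polar_requirement()))


class CostEvaluator:
    """Precomputed structures for fast cost evaluation of 64-codon codes.

    Holds the masked pair weights (stop pairs zeroed), the normalization,
    and the 20x20 penalty matrix; provides full, incremental (single-flip)
    and batch cost computation.
    """

    def __init__(
        self,
        model: MisreadingModel | None = None,
        config: CostConfig | None = None,
        stop_positions=STOP_CODONS,
    ):
        self.model = model if model is not None else misreading_weights()
        self.config = (
            config if config is not None else CostConfig.polar_requirement_default()
        )
        self.stop_positions = tuple(stop_positions)
        stop = np.zeros(N_CODONS, dtype=bool)
        stop[list(self.stop_positions)] = True
        self.is_stop = stop
        self.neighbors = self.model.neighbors
        # effective weights: zero when either side of the pair is a stop
        w = self.model.raw_weights.copy()
        w[stop, :] = 0.0
        w[stop[self.neighbors]] = 0.0
        self.eff_weights = w
        self.norm = float(w.sum())
        self.D = self.config.penalty.matrix
        self.sense_positions = np.flatnonzero(~stop).astype(np.int64)
        if self.config.source_weights is not None:
            sw = np.asarray(self.config.source_weights, dtype=np.float64)
            if sw.shape != (N_AA,) or sw.min() < 0 or sw.sum() <= 0:
                raise ValueError("source_weights must be 20 nonnegative values")
            self.source_weights = sw / sw.sum()
        else:
            self.source_weights = None
        # constant baseline from stop-involving pairs (zero unless c0/c1 set)
        raw = self.model.raw_weights
        w_to_stop = float(raw[~stop[:, None] & stop[self.neighbors]].sum())
        w_from_stop = float(raw[stop, :].sum())
        self.baseline = (
            self.config.c0 * w_to_stop + self.config.c1 * w_from_stop
        ) / self.norm

    # -- full evaluation ----------------------------------------------
    def cost(self, code: GeneticCode | np.ndarray) -> float:
        assign = code.assign if isinstance(code, GeneticCode) else np.asarray(code)
        return float(self.batch_costs(assign[None, :])[0])

    def batch_costs(self, assigns: np.ndarray) -> np.ndarray:
        """Costs of a (n, 64) batch of assignment arrays (stops = -1)."""
        assigns = np.asarray(assigns)
        if assigns.ndim == 1:
            assigns = assigns[None, :]
        a_src = assigns[:, :, None]
        a_dst = assigns[:, self.neighbors]
        pen = self.D[a_src.clip(0), a_dst.clip(0)]
        w = self.eff_weights[None, :, :]
        if self.source_weights is not None:
            sw = self.source_weights[a_src.clip(0)] * (a_src >= 0)
            num = (w * sw * pen).sum(axis=(1, 2))
            den = (w * sw * np.ones_like(pen)).sum(axis=(1, 2))
            return num / den + self.baseline
        num = (w * pen).sum(axis=(1, 2))
        return num / self.norm + self.baseline

    # -- incremental evaluation ---------------------------------------
    def delta(self, code: GeneticCode | np.ndarray, position: int, new_symbol: int) -> float:
        """Cost change from reassigning one sense codon, touching only its
        9 neighbors.  Exact to floating tolerance against full recomputation."""
        assign = code.assign if isinstance(code, GeneticCode) else np.asarray(code)
        if self.is_stop[position]:
            raise ValueError(f"codon {position} is a stop position; cannot flip")
        old = int(assign[position])
        if new_symbol == old:
            raise ValueError("new symbol equals current symbol")
        if not 0 <= new_symbol < N_AA:
            raise ValueError("new symbol out of range")
        if self.source_weights is not None:
            flipped = assign.copy()
            flipped[position] = new_symbol
            return float(self.batch_costs(flipped)[0] - self.batch_costs(assign)[0])
        acc = 0.0
        for k in range(9):
            nb = self.neighbors[position, k]
            w = self.eff_weights[position, k]
            if w == 0.0:
                continue
            a_nb = int(assign[nb])
            acc += 2.0 * w * (self.D[new_symbol, a_nb] - self.D[old, a_nb])
        return acc / self.norm


def code_cost(
    code: GeneticCode,
    model: MisreadingModel | None = None,
    config: CostConfig | None = None,
    scale: PropertyScale | None = None,
) -> float:
    """Misreading cost of a single code.

    If ``config`` is omitted it is built from ``scale`` (squared-difference
    penalty) or from the polar-requirement default.
    """
    if config is None and scale is not None:
        config = CostConfig(SubstitutionPenalty.squared_difference(scale))
    return CostEvaluator(model, config).cost(code)


def delta_cost(
    code: GeneticCode,
    position: int,
    new_symbol: int | str,
    evaluator: CostEvaluator | None = None,
) -> float:
    """Cost change from flipping codon ``position`` to ``new_symbol``."""
    from .codons import AA_INDEX

    if isinstance(new_symbol, str):
        new_symbol = AA_INDEX[new_symbol]
    ev = evaluator if evaluator is not None else CostEvaluator()
    return ev.delta(code, position, new_symbol)
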