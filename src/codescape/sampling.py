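"""Reference samplers over genetic-code ensembles.

``naive_sample`` draws uniformly from the fully random constrained
ensemble (rejection), ``block_sample`` from the classic block-structure
ensemble (the 20! permutations of amino acids over the SGC's blocks), and
``propose_flip`` is the single-codon move shared by the Monte Carlo
samplers and the genetic algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .codons import (
    EnsembleConstraints,
    GeneticCode,
    N_AA,
    N_CODONS,
    N_SENSE,
    STOP_CODONS,
    sgc,
)
from .cost import CostEvaluator


@dataclass
class SampleBatch:
    """A batch of sampled codes with their costs."""

    assigns: np.ndarray  # (n, 64) int8, -1 at stops
    costs: np.ndarray  # (n,) float64
    seed: int
    ensemble_tag: str

    def __len__(self):
        return self.assigns.shape[0]

    def code(self, i: int) -> GeneticCode:
        return GeneticCode(self.assigns[i])

    def to_csv(self, path) -> None:
        """Stream (cost, 64-char code string) rows."""
        import pandas as pd

        strings = ["".join(GeneticCode(a).to_string()) for a in self.assigns]
        pd.DataFrame({"cost": self.costs, "code": strings}).to_csv(path, index=False)


def _count_rows(assigns: np.ndarray) -> np.ndarray:
    """Per-row amino-acid counts of a (n, n_sense) int matrix."""
    n = assigns.shape[0]
    offsets = (np.arange(n)[:, None] * N_AA + assigns).ravel()
    return np.bincount(offsets, minlength=n * N_AA).reshape(n, N_AA)


def naive_sample(
    n: int,
    constraints: EnsembleConstraints = EnsembleConstraints(),
    seed: int = 0,
    evaluator: CostEvaluator | None = None,
    chunk: int = 200_000,
) -> SampleBatch:
    """Uniform sample of ``n`` codes from the constrained ensemble.

    Each sense codon is drawn uniformly over the 20 amino acids and whole
    codes violating the constraints are rejected, which is exact uniform
    sampling on the constrained set (the acceptance rate is the ensemble
    fraction of 20^61, about 0.27 under the default constraints).
    """
    if n < 1:
        raise ValueError("need n >= 1")
    ev = evaluator if evaluator is not None else CostEvaluator()
    rng = np.random.default_rng(seed)
    minima = constraints.minima()
    sense = np.array([c for c in range(N_CODONS) if c not in STOP_CODONS])
    keep_a = []
    kept = 0
    while kept < n:
        raw = rng.integers(0, N_AA, size=(chunk, N_SENSE), dtype=np.int64)
        counts = _count_rows(raw)
        ok = (counts >= minima[None, :]).all(axis=1)
        good = raw[ok]
        keep_a.append(good)
        kept += good.shape[0]
    sense_assign = np.concatenate(keep_a)[:n]
    assigns = np.full((n, N_CODONS), -1, dtype=np.int8)
    assigns[:, sense] = sense_assign.astype(np.int8)
    costs = _batch_costs_chunked(ev, assigns, chunk)
    return SampleBatch(assigns, costs, seed, "fully-random")


def block_sample(
    n: int,
    seed: int = 0,
    evaluator: CostEvaluator | None = None,
    chunk: int = 200_000,
) -> SampleBatch:
    """Sample from the block-structure ensemble of the earlier literature.

    Each code is a uniformly random permutation of the 20 amino acids over
    the SGC's amino-acid blocks (stops untouched): an ensemble of exactly
    20! codes.  The identity permutation is the SGC itself.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    ev = evaluator if evaluator is not None else CostEvaluator()
    rng = np.random.default_rng(seed)
    block = sgc().assign.astype(np.int64)  # block id == SGC amino-acid index
    out_a = np.empty((n, N_CODONS), dtype=np.int8)
    costs = np.empty(n, dtype=np.float64)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        perms = rng.permuted(
            np.tile(np.arange(N_AA, dtype=np.int8), (m, 1)), axis=1
        )
        a = perms[:, block.clip(0)]
        a[:, block < 0] = -1
        out_a[done : done + m] = a
        costs[done : done + m] = ev.batch_costs(a)
        done += m
    return SampleBatch(out_a, costs, seed, "sgc-blocks")


def _batch_costs_chunked(ev: CostEvaluator, assigns: np.ndarray, chunk: int):
    out = np.empty(assigns.shape[0], dtype=np.float64)
    for i in range(0, assigns.shape[0], chunk):
        out[i : i + chunk] = ev.batch_costs(assigns[i : i + chunk])
    return out


def propose_flip(code: GeneticCode, rng: np.random.Generator) -> GeneticCode:
    """One uniformly chosen sense codon reassigned to a uniformly chosen
    different amino acid.  The candidate may violate the ensemble
    constraints; rejection is the caller's policy.  Stops never move."""
    assign = code.assign.copy()
    sense = np.flatnonzero(assign >= 0)
    pos = int(rng.choice(sense))
    old = int(assign[pos])
    new = int(rng.integers(0, N_AA - 1))
    if new >= old:
        new += 1
    assign[pos] = new
    return GeneticCode(assign)


def fraction_below(
    batch: SampleBatch, threshold: float, strict: bool = True
) -> tuple[float, tuple[float, float]]:
    """Fraction of sampled costs below ``threshold`` with a 95% CI.

    ``strict`` counts costs strictly below; ``strict=False`` counts ties
    as hits ("equally or more robust").
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    hits = int(
        (batch.costs < threshold).sum()
        if strict
        else (batch.costs <= threshold).sum()
    )
    n = len(batch)
    ci = binomtest(hits, n).proportion_ci(confidence_level=0.95, method="wilson")
    return hits / n, (float(ci.low), float(ci.high))
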