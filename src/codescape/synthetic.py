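"""Synthetic systems with exact oracles.

Toy codon systems are small enough to enumerate every assignment exactly,
so the Monte Carlo machinery (cost, Wang-Landau, multicanonical DOS,
detailed balance) can be validated against ground truth.  Toys reuse the
real model's structure: single-position misreading neighbors, a
class-structured weight table (last position most error-prone, earlier
positions down-weighted, transition/transversion asymmetry for 4-letter
alphabets), a property scale whose two designated symbols hold the largest
values (emulating Asp/Glu), and per-symbol minimum-multiplicity
constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .counting import count_assignments
from .multicanonical import CostGrid, SamplingSystem


@dataclass
class ToySystem:
    """An enumerable miniature codon system."""

    n_bases: int
    codon_len: int
    n_aa: int
    seed: int
    values: np.ndarray  # per-symbol property values
    minima: np.ndarray
    nb: np.ndarray
    w: np.ndarray
    norm: float
    designated_max: tuple = (0, 1)

    @property
    def n_codons(self) -> int:
        return self.n_bases ** self.codon_len

    @property
    def n_states(self) -> int:
        return self.n_aa ** self.n_codons

    def system(self) -> SamplingSystem:
        D = (self.values[:, None] - self.values[None, :]) ** 2
        return SamplingSystem(
            nb=self.nb,
            w=self.w,
            norm=self.norm,
            D=D,
            sense=np.arange(self.n_codons, dtype=np.int64),
            minima=self.minima.astype(np.int64),
            template=np.zeros(self.n_codons, dtype=np.int8),
            n_symbols=self.n_aa,
        )

    def describe(self) -> dict:
        return {
            "n_bases": self.n_bases,
            "codon_len": self.codon_len,
            "n_aa": self.n_aa,
            "seed": self.seed,
            "values": self.values.tolist(),
            "minima": self.minima.tolist(),
            "norm": self.norm,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.describe(), fh, indent=1)


def _toy_weights(n_bases: int, codon_len: int):
    """Neighbor and weight tables mirroring the real error-class structure."""
    n_codons = n_bases ** codon_len
    max_nb = codon_len * (n_bases - 1)
    nb = np.zeros((n_codons, max_nb), dtype=np.int64)
    w = np.zeros((n_codons, max_nb), dtype=np.float64)
    pos_weight = np.full(codon_len, 0.5)
    pos_weight[-1] = 1.0
    purine = lambda d: d >= n_bases // 2  # split alphabet into two classes
    for c in range(n_codons):
        digits = []
        x = c
        for _ in range(codon_len):
            digits.append(x % n_bases)
            x //= n_bases
        digits.reverse()
        k = 0
        for pos in range(codon_len):
            for alt in range(n_bases):
                if alt == digits[pos]:
                    continue
                d2 = digits.copy()
                d2[pos] = alt
                c2 = 0
                for dd in d2:
                    c2 = c2 * n_bases + dd
                wt = pos_weight[pos]
                if n_bases == 4 and pos != codon_len - 1:
                    ts = purine(digits[pos]) == purine(alt)
                    wt *= 1.0 if ts else 0.2
                nb[c, k] = c2
                w[c, k] = wt
                k += 1
    return nb, w


def make_toy(
    n_bases: int,
    codon_len: int,
    n_aa: int,
    seed: int = 0,
    minima=None,
    cap: int = 2_000_000,
) -> ToySystem:
    """Build a reproducible toy system.

    The property scale is drawn uniformly on [4, 10] and its two largest
    values (12.5 and 13.0, mirroring Glu/Asp) are placed on the designated
    symbols 0 and 1.  ``minima`` defaults to requiring every symbol at
    least once.
    """
    n_codons = n_bases ** codon_len
    if n_aa ** n_codons > cap:
        raise ValueError(
            f"toy state count {n_aa}^{n_codons} exceeds the enumeration cap {cap}"
        )
    rng = np.random.default_rng(seed)
    values = rng.uniform(4.0, 10.0, size=n_aa)
    if n_aa >= 2:
        values[0], values[1] = 13.0, 12.5
    if minima is None:
        minima = np.ones(n_aa, dtype=np.int64)
    minima = np.asarray(minima, dtype=np.int64)
    if minima.shape != (n_aa,):
        raise ValueError("minima must have one entry per symbol")
    nb, w = _toy_weights(n_bases, codon_len)
    return ToySystem(
        n_bases=n_bases,
        codon_len=codon_len,
        n_aa=n_aa,
        seed=seed,
        values=values,
        minima=minima,
        nb=nb,
        w=w,
        norm=float(w.sum()),
    )


def enumerate_states(toy: ToySystem) -> tuple[np.ndarray, np.ndarray]:
    """All constraint-satisfying assignments and their exact costs."""
    n_states = toy.n_states
    shape = (toy.n_aa,) * toy.n_codons
    A = np.stack(
        np.unravel_index(np.arange(n_states), shape), axis=1
    )  # (n_states, n_codons)
    ok = np.ones(n_states, dtype=bool)
    for s in range(toy.n_aa):
        if toy.minima[s] > 0:
            ok &= (A == s).sum(axis=1) >= toy.minima[s]
    A = A[ok]
    sysm = toy.system()
    pairs_i, pairs_k = np.nonzero(toy.w)
    ci = pairs_i
    cj = toy.nb[pairs_i, pairs_k]
    wp = toy.w[pairs_i, pairs_k]
    costs = (sysm.D[A[:, ci], A[:, cj]] * wp[None, :]).sum(axis=1) / toy.norm
    return A.astype(np.int8), costs


def exact_dos(toy: ToySystem, grid: CostGrid) -> np.ndarray:
    """Exact per-bin state counts by exhaustive enumeration."""
    _, costs = enumerate_states(toy)
    return np.bincount(grid.bin_of(costs), minlength=grid.nbins)


def toy_count(toy: ToySystem) -> int:
    """Constrained state count via the inclusion-exclusion counter."""
    return count_assignments(toy.n_codons, toy.minima)


def planted_blobs(
    k: int,
    separation: float,
    n_per_blob: int,
    dim: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic unit-variance Gaussian clusters with centers at pairwise
    distance ``separation`` (times the within-cluster spread).

    Returns (points, labels).  With k <= dim+1 the centers sit on a
    regular simplex so all pairwise distances equal ``separation``;
    otherwise random centers are rescaled so the minimum pairwise distance
    is ``separation``.
    """
    if k < 1:
        raise ValueError("need k >= 1")
    rng = np.random.default_rng(seed)
    if k == 1:
        centers = np.zeros((1, dim))
    elif k <= dim + 1:
        # regular simplex, isometrically embedded into k-1 coordinates
        centered = np.eye(k) - 1.0 / k
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        coords = (u * s)[:, : k - 1]
        coords /= np.linalg.norm(coords[0] - coords[1])
        centers = np.zeros((k, dim))
        centers[:, : k - 1] = coords * separation
    else:
        centers = rng.standard_normal((k, dim))
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        dmin = d[~np.eye(k, dtype=bool)].min()
        if dmin > 0:
            centers *= separation / dmin
    labels = np.repeat(np.arange(k), n_per_blob)
    pts = centers[labels] + rng.standard_normal((k * n_per_blob, dim))
    return pts, labels
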