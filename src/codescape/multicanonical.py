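"""Multicanonical Monte Carlo over the cost axis.

The sampler performs a random walk in cost space under a weight
w(cost) proportional to 1/Omega(cost), the inverse density of states, so
that all cost levels — including codes twenty orders of magnitude rarer
than typical — are visited with comparable frequency.  The weight is
trained with the Wang-Landau flat-histogram algorithm; a subsequent
fixed-weight run yields the density of states as Omega ∝ H/w from the
sampling histogram H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .codons import EnsembleConstraints, N_AA, N_CODONS, STOP_CODONS
from .cost import CostEvaluator


@dataclass(frozen=True)
class CostGrid:
    """Half-open uniform binning of the cost axis; out-of-range costs
    clamp to the edge bins."""

    lo: float
    hi: float
    width: float = 0.01

    def __post_init__(self):
        if not (self.hi > self.lo and self.width > 0):
            raise ValueError("need hi > lo and width > 0")

    @property
    def nbins(self) -> int:
        return int(np.ceil((self.hi - self.lo) / self.width))

    @property
    def edges(self) -> np.ndarray:
        return self.lo + self.width * np.arange(self.nbins + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.lo + self.width * (np.arange(self.nbins) + 0.5)

    def bin_of(self, cost) -> np.ndarray:
        b = np.floor((np.asarray(cost, dtype=float) - self.lo) / self.width)
        return np.clip(b, 0, self.nbins - 1).astype(np.int64)


@dataclass
class WeightFunction:
    """Multicanonical log-weights per grid bin (defined up to a constant)."""

    grid: CostGrid
    log_w: np.ndarray
    visited: np.ndarray  # bool mask of bins seen during training

    def to_tsv(self, path) -> None:
        import pandas as pd

        e = self.grid.edges
        pd.DataFrame(
            {
                "bin_left": e[:-1],
                "bin_right": e[1:],
                "log_weight": self.log_w,
                "visited": self.visited.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "WeightFunction":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        lo = float(df["bin_left"].iloc[0])
        width = float(df["bin_right"].iloc[0] - df["bin_left"].iloc[0])
        hi = float(df["bin_right"].iloc[-1])
        grid = CostGrid(lo, hi, width)
        return cls(
            grid,
            df["log_weight"].to_numpy(float),
            df["visited"].to_numpy(int).astype(bool),
        )


@dataclass
class DOSEstimate:
    """Binned (log) density of states.

    ``mode`` is "relative" (arbitrary additive constant in log space),
    "fraction" (exponentials over unmasked bins sum to 1) or "absolute"
    (fraction times the exact ensemble count).  Unvisited bins are masked
    (NaN), not zero.
    """

    grid: CostGrid
    log_dos: np.ndarray  # NaN where undefined
    mode: str = "relative"
    total: float | None = None

    def mask(self) -> np.ndarray:
        return np.isfinite(self.log_dos)

    def as_fraction(self) -> "DOSEstimate":
        m = self.mask()
        if not m.any():
            raise ValueError("empty DOS")
        ref = self.log_dos[m].max()
        logz = ref + np.log(np.exp(self.log_dos[m] - ref).sum())
        out = self.log_dos - logz
        return DOSEstimate(self.grid, out, "fraction", self.total)

    def as_absolute(self, total: float | None = None) -> "DOSEstimate":
        tot = total if total is not None else self.total
        if tot is None:
            raise ValueError("absolute normalization needs the ensemble count")
        frac = self.as_fraction()
        return DOSEstimate(frac.grid, frac.log_dos + np.log(tot), "absolute", tot)

    def to_tsv(self, path) -> None:
        import pandas as pd

        e = self.grid.edges
        pd.DataFrame(
            {"bin_left": e[:-1], "bin_right": e[1:], "log_dos": self.log_dos}
        ).to_csv(path, sep="\t", index=False)


def tail_fraction(dos: DOSEstimate, threshold: float) -> float:
    """Fraction of ensemble states with cost below ``threshold``.

    Sums the exponentiated fraction-mode DOS over bins whose centers lie
    strictly below the threshold (0 if the threshold is below the grid).
    """
    frac = dos.as_fraction() if dos.mode != "fraction" else dos
    m = frac.mask() & (frac.grid.centers < threshold)
    if not m.any():
        return 0.0
    return float(np.exp(frac.log_dos[m]).sum())


def empirical_dos(costs: np.ndarray, grid: CostGrid) -> DOSEstimate:
    """Fraction-mode DOS from direct (uniform) samples, e.g. naive sampling."""
    hist = np.bincount(grid.bin_of(costs), minlength=grid.nbins)
    with np.errstate(divide="ignore"):
        log_dos = np.where(hist > 0, np.log(hist), np.nan)
    return DOSEstimate(grid, log_dos, "relative").as_fraction()


# ---------------------------------------------------------------------------
# sampling systems: the arrays the numba kernels consume
# ---------------------------------------------------------------------------


@dataclass
class SamplingSystem:
    """Array bundle driving the Monte Carlo kernels (full code or toy)."""

    nb: np.ndarray
    w: np.ndarray
    norm: float
    D: np.ndarray
    sense: np.ndarray
    minima: np.ndarray
    template: np.ndarray  # int8 assignment with -1 at excluded positions
    n_symbols: int

    @classmethod
    def standard(
        cls,
        evaluator: CostEvaluator | None = None,
        constraints: EnsembleConstraints = EnsembleConstraints(),
    ) -> "SamplingSystem":
        ev = evaluator if evaluator is not None else CostEvaluator()
        template = np.zeros(N_CODONS, dtype=np.int8)
        template[list(ev.stop_positions)] = -1
        return cls(
            nb=ev.neighbors,
            w=ev.eff_weights,
            norm=ev.norm,
            D=ev.D,
            sense=ev.sense_positions,
            minima=constraints.minima(),
            template=template,
            n_symbols=N_AA,
        )

    def cost(self, assign: np.ndarray) -> float:
        return float(
            _kernels.cost_full(
                np.asarray(assign, dtype=np.int8), self.nb, self.w, self.norm, self.D
            )
        )

    def random_state(self, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        for _ in range(100_000):
            assign = self.template.copy()
            assign[self.sense] = rng.integers(
                0, self.n_symbols, size=self.sense.size, dtype=np.int8
            )
            counts = np.bincount(
                assign[self.sense].astype(int), minlength=self.n_symbols
            )
            if (counts >= self.minima).all():
                return assign
        raise RuntimeError("could not draw a valid state")

    def counts(self, assign: np.ndarray) -> np.ndarray:
        return np.bincount(
            assign[self.sense].astype(int), minlength=self.n_symbols
        ).astype(np.int64)


@dataclass(frozen=True)
class WangLandauSchedule:
    """Wang-Landau schedule: initial log modification factor, halved on
    every flat-histogram pass, until it drops below ``log_f_min``."""

    log_f0: float = 1.0
    log_f_min: float = 1e-6
    flatness: float = 0.8
    check_every: int = 100_000
    max_steps: int = 500_000_000


class WangLandauError(RuntimeError):
    pass


@dataclass
class WangLandauResult:
    weight: WeightFunction
    log_g: np.ndarray
    steps: int
    final_log_f: float
    converged: bool
    n_passes: int
    final_state: np.ndarray


def wang_landau_train(
    system: SamplingSystem,
    grid: CostGrid,
    schedule: WangLandauSchedule = WangLandauSchedule(),
    seed: int = 0,
    start: np.ndarray | None = None,
    strict: bool = True,
) -> WangLandauResult:
    """Train the multicanonical weight by the Wang-Landau algorithm.

    Returns the trained weight (log w = -log g, flattened histogram) and
    diagnostics.  With ``strict`` a run that exhausts ``max_steps`` before
    the modification factor reaches ``log_f_min`` raises
    :class:`WangLandauError` (the result so far is attached).
    """
    assign = (
        np.asarray(start, dtype=np.int8).copy()
        if start is not None
        else system.random_state(seed ^ 0x5EED)
    )
    counts = system.counts(assign)
    log_g, visited, steps, log_f, converged, n_passes = _kernels.wang_landau_kernel(
        assign,
        counts,
        system.nb,
        system.w,
        float(system.norm),
        system.D,
        system.sense,
        system.minima,
        float(grid.lo),
        float(grid.width),
        grid.nbins,
        float(schedule.log_f0),
        float(schedule.log_f_min),
        float(schedule.flatness),
        int(schedule.check_every),
        int(schedule.max_steps),
        int(seed) & 0x7FFFFFFF,
    )
    log_w = np.where(visited, -log_g, 0.0)
    if visited.any():
        # anchor the rarest visited bin at log-weight 0; untrained bins get
        # a strongly negative weight so a fixed-weight chain avoids them
        # (and immediately leaves if it ever lands in one) instead of
        # treating them as infinitely attractive traps
        log_w -= log_w[visited].max()
        log_w[~visited] = log_w[visited].min() - 50.0
    result = WangLandauResult(
        WeightFunction(grid, log_w, visited),
        log_g,
        int(steps),
        float(log_f),
        bool(converged),
        int(n_passes),
        assign,
    )
    if strict and not converged:
        raise WangLandauError(
            f"Wang-Landau did not converge: log_f={log_f:.2e} after {steps} "
            f"steps ({n_passes} flat passes, {int(visited.sum())} bins visited)"
        )
    return result


@dataclass
class MucaRun:
    """Output of a fixed-weight multicanonical run."""

    weight: WeightFunction
    hist: np.ndarray
    rec_assigns: np.ndarray
    rec_costs: np.ndarray
    flows: np.ndarray | None
    final_state: np.ndarray
    steps: int
    seed: int

    def flat_ratio(self) -> float:
        """min/mean visited-bin count ratio of the run histogram."""
        h = self.hist[self.hist > 0]
        return float(h.min() / h.mean()) if h.size else 0.0


def multicanonical_sample(
    system: SamplingSystem,
    weight: WeightFunction,
    steps: int,
    seed: int = 0,
    thinning: int = 0,
    record_below: float = np.inf,
    max_records: int = 200_000,
    track_flows: bool = False,
    start: np.ndarray | None = None,
) -> MucaRun:
    """Markov chain with acceptance min(1, w(cost')/w(cost)) at fixed
    weight.  Rejected steps re-record the current state.  States with cost
    below ``record_below`` are retained every ``thinning`` steps."""
    if steps < 1:
        raise ValueError("need steps >= 1")
    grid = weight.grid
    assign = (
        np.asarray(start, dtype=np.int8).copy()
        if start is not None
        else system.random_state(seed ^ 0xACE5)
    )
    counts = system.counts(assign)
    hist, rec_assign, rec_costs, n_rec, flows = _kernels.muca_kernel(
        assign,
        counts,
        system.nb,
        system.w,
        float(system.norm),
        system.D,
        system.sense,
        system.minima,
        weight.log_w,
        float(grid.lo),
        float(grid.width),
        grid.nbins,
        int(steps),
        int(thinning),
        float(record_below),
        int(max_records if thinning > 0 else 0),
        1 if track_flows else 0,
        int(seed) & 0x7FFFFFFF,
    )
    return MucaRun(
        weight,
        hist,
        rec_assign[:n_rec],
        rec_costs[:n_rec],
        flows if track_flows else None,
        assign,
        int(steps),
        int(seed),
    )


def estimate_dos(
    hist: np.ndarray,
    weight: WeightFunction,
    mode: str = "fraction",
    total: float | None = None,
) -> DOSEstimate:
    """Density of states from a fixed-weight histogram: Omega ∝ H/w.

    Empty bins are masked.  ``mode``: "relative" leaves the additive
    constant arbitrary; "fraction" normalizes the exponentials to 1;
    "absolute" scales the fraction by ``total`` (the exact ensemble
    count)."""
    hist = np.asarray(hist)
    if hist.shape != weight.log_w.shape:
        raise ValueError("histogram does not match the weight grid")
    with np.errstate(divide="ignore"):
        log_dos = np.where(hist > 0, np.log(hist), np.nan) - weight.log_w
    est = DOSEstimate(weight.grid, log_dos, "relative", total)
    if mode == "relative":
        return est
    if mode == "fraction":
        return est.as_fraction()
    if mode == "absolute":
        return est.as_absolute(total)
    raise ValueError(f"unknown mode {mode!r}")
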