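"""Truncation-selection genetic algorithm on the code fitness landscape.

Each generation the best half of a population of N codes survives, each
survivor is copied exactly once (sampling without replacement), and the
copies are mutated per codon at rate mu; mutated copies violating the
ensemble constraints are redrawn.  There is no crossover.  The survivors
persist unmutated, so the best cost is nonincreasing — the dynamics of a
greedy adaptive walk with a population.

The path-dependence diagnostic is Delta_PR: the mean polar requirement
over the right-half columns of the codon table (2nd base A/G) minus the
left-half columns (2nd base U/C), over sense codons.  Its sign separates
the narrow "blue" fitness peak (high polar requirement on the left) from
the other three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .codons import GeneticCode, N_CODONS, STOP_CODONS
from .multicanonical import SamplingSystem
from .scales import PropertyScale, polar_requirement

#: +1 for codons in the right half of the table (2nd base A or G), else 0.
COLUMN_RIGHT = np.array([1 if ((c >> 2) & 3) >= 2 else 0 for c in range(N_CODONS)], dtype=np.int8)


@dataclass(frozen=True)
class GAConfig:
    """GA parameters; the defaults are the study conditions (N=100, top
    half selected, mu=0.1 per element, 500 generations, no crossover)."""

    population_size: int = 100
    selection_fraction: float = 0.5
    mutation_rate: float = 0.1
    generations: int = 500
    mutate_survivors: bool = False
    retry_cap: int = 1000

    def __post_init__(self):
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population size must be even and >= 2")
        if self.selection_fraction != 0.5:
            raise ValueError(
                "only top-50% truncation is supported (copy-each-survivor-once "
                "refill requires selection_fraction = 0.5)"
            )
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation rate must be in [0, 1]")


@dataclass
class GABatch:
    """Trajectories of a batch of independent GA runs.

    ``best_cost``/``best_dpr`` are (runs, generations) arrays for the best
    individual of each generation; ``slice_assigns`` holds, per run, the
    latest best code whose cost fell inside the recording slice (valid
    where ``has_slice``)."""

    config: GAConfig
    seed: int
    best_cost: np.ndarray
    best_dpr: np.ndarray
    slice_assigns: np.ndarray
    has_slice: np.ndarray
    final_assigns: np.ndarray
    final_cost: np.ndarray
    slice_bounds: tuple

    @property
    def n_runs(self) -> int:
        return self.best_cost.shape[0]

    def reached(self) -> np.ndarray:
        """Runs whose best cost entered the recording slice."""
        return self.has_slice

    def to_csv(self, path) -> None:
        import pandas as pd

        r, g = np.meshgrid(
            np.arange(self.n_runs), np.arange(self.best_cost.shape[1]), indexing="ij"
        )
        pd.DataFrame(
            {
                "run": r.ravel(),
                "generation": g.ravel(),
                "best_cost": self.best_cost.ravel(),
                "best_delta_pr": self.best_dpr.ravel(),
            }
        ).to_csv(path, index=False)


def ga_run(
    config: GAConfig,
    system: SamplingSystem,
    scale: PropertyScale | None = None,
    seed: int = 0,
    n_runs: int = 1,
    slice_bounds: tuple = (2.5283, 2.7283),
) -> GABatch:
    """Run ``n_runs`` independent GA optimizations (seeded, reproducible).

    ``slice_bounds`` is the half-open cost window in which the latest
    best-of-generation code is retained for landscape analysis (default:
    the SGC cost +/- 0.1).
    """
    vals = (scale or polar_requirement()).values
    out = _kernels.ga_kernel(
        int(n_runs),
        int(config.population_size),
        int(config.generations),
        float(config.mutation_rate),
        int(config.retry_cap),
        system.nb,
        system.w,
        float(system.norm),
        system.D,
        system.sense,
        system.minima,
        vals,
        COLUMN_RIGHT[: system.nb.shape[0]],
        float(slice_bounds[0]),
        float(slice_bounds[1]),
        1 if config.mutate_survivors else 0,
        int(seed) & 0x7FFFFFFF,
    )
    best_cost, best_dpr, slice_assign, has_slice, final_assign, final_cost, n_fail = out
    if n_fail:
        raise RuntimeError(
            f"{n_fail} mutation redraws exhausted the retry cap "
            f"({config.retry_cap}); constraints may be too tight"
        )
    return GABatch(
        config,
        int(seed),
        best_cost,
        best_dpr,
        slice_assign,
        has_slice,
        final_assign,
        final_cost,
        tuple(slice_bounds),
    )


def delta_pr(code: GeneticCode, scale: PropertyScale | None = None) -> float:
    """Delta_PR = <PR over right-half columns> - <PR over left-half
    columns> of the code's sense codons (2nd base A/G vs U/C)."""
    vals = (scale or polar_requirement()).values
    assign = code.assign
    sense = assign >= 0
    right = sense & (COLUMN_RIGHT == 1)
    left = sense & (COLUMN_RIGHT == 0)
    v = vals[assign.clip(0)]
    return float(v[right].mean() - v[left].mean())


def delta_pr_of_vectors(vectors: np.ndarray) -> np.ndarray:
    """Delta_PR computed directly from 64-dim property vectors (sense
    codons only; the three stop positions are excluded)."""
    sense = np.ones(N_CODONS, dtype=bool)
    sense[list(STOP_CODONS)] = False
    right = sense & (COLUMN_RIGHT == 1)
    left = sense & (COLUMN_RIGHT == 0)
    V = np.atleast_2d(vectors)
    return V[:, right].mean(axis=1) - V[:, left].mean(axis=1)


@dataclass
class TrajectoryStats:
    """Cost-binned statistics over a batch of GA trajectories."""

    bin_edges: np.ndarray
    visits: np.ndarray  # generation-visits per bin
    trans_pos_to_neg: np.ndarray  # sign-transition rate per bin
    trans_neg_to_pos: np.ndarray
    trans_any: np.ndarray
    latest_dpr: np.ndarray  # (runs, bins), NaN where never visited
    frac_negative: np.ndarray  # fraction of runs with latest Delta_PR < 0
    frac_negative_conditional: np.ndarray  # restricted to conditioned runs

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "visits": self.visits,
                "rate_pos_to_neg": self.trans_pos_to_neg,
                "rate_neg_to_pos": self.trans_neg_to_pos,
                "rate_any": self.trans_any,
                "frac_dpr_negative": self.frac_negative,
                "frac_dpr_negative_reached": self.frac_negative_conditional,
            }
        )


def trajectory_stats(
    batch: GABatch,
    bin_width: float = 0.1,
    cost_range: tuple | None = None,
    condition: np.ndarray | None = None,
) -> TrajectoryStats:
    """Sign-transition rates, latest-value curves and Delta_PR<0 fractions
    binned by the cost experienced along each run's best-of-generation
    trajectory.

    Transitions are counted in the bin of the generation where the new
    sign appears; rates divide by total generation-visits per bin.  The
    latest-value curve keeps, per run and bin, only the last Delta_PR seen
    there (so each run contributes a univalent curve in cost).  The
    conditional fraction restricts to ``condition`` (default: runs that
    reached the recording slice).
    """
    costs, dprs = batch.best_cost, batch.best_dpr
    if condition is None:
        condition = batch.reached()
    lo = np.floor(costs.min() / bin_width) * bin_width if cost_range is None else cost_range[0]
    hi = np.ceil(costs.max() / bin_width) * bin_width if cost_range is None else cost_range[1]
    nbins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    bins = np.clip(((costs - lo) / bin_width).astype(np.int64), 0, nbins - 1)

    n_runs, n_gen = costs.shape
    visits = np.bincount(bins.ravel(), minlength=nbins).astype(np.float64)
    sign = np.sign(dprs)
    flip = sign[:, 1:] * sign[:, :-1] < 0
    to_neg = flip & (sign[:, 1:] < 0)
    to_pos = flip & (sign[:, 1:] > 0)
    tb = bins[:, 1:]
    t_pn = np.bincount(tb[to_neg].ravel(), minlength=nbins).astype(np.float64)
    t_np = np.bincount(tb[to_pos].ravel(), minlength=nbins).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_pn = np.where(visits > 0, t_pn / visits, np.nan)
        rate_np = np.where(visits > 0, t_np / visits, np.nan)
        rate_any = np.where(visits > 0, (t_pn + t_np) / visits, np.nan)

    latest = np.full((n_runs, nbins), np.nan)
    rows = np.repeat(np.arange(n_runs), n_gen)
    latest[rows, bins.ravel()] = dprs.ravel()  # later assignments overwrite

    def _frac_neg(mask_runs):
        sub = latest[mask_runs]
        defined = np.isfinite(sub)
        with np.errstate(invalid="ignore"):
            frac = np.where(
                defined.sum(axis=0) > 0,
                (sub < 0).sum(axis=0) / defined.sum(axis=0),
                np.nan,
            )
        return frac

    return TrajectoryStats(
        bin_edges=edges,
        visits=visits,
        trans_pos_to_neg=rate_pn,
        trans_neg_to_pos=rate_np,
        trans_any=rate_any,
        latest_dpr=latest,
        frac_negative=_frac_neg(np.ones(n_runs, dtype=bool)),
        frac_negative_conditional=_frac_neg(np.asarray(condition, dtype=bool)),
    )
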