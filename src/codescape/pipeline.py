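"""Config-driven pipeline tying the stages together.

Every stochastic stage takes an explicit seed derived from the run seed,
so a pipeline re-run with the same config is byte-reproducible.  Stages
can be called individually or through :func:`run_pipeline`, which
executes the full analysis — cost of the standard code, exact ensemble
count, block-ensemble rarity, Wang-Landau training, fixed-weight
multicanonical sampling, DOS/tail estimation, GA batch, and landscape
reconstruction — and optionally writes TSV/JSON artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .codons import EnsembleConstraints, sgc
from .cost import CostEvaluator
from .counting import count_ensemble
from .ga import GAConfig, delta_pr_of_vectors, ga_run, trajectory_stats
from .landscape import (
    assign_clusters,
    cluster_occupancy,
    elbow_k,
    fit_clusters,
    name_clusters,
    pca_fit,
    vectorize,
)
from .multicanonical import (
    CostGrid,
    SamplingSystem,
    WangLandauSchedule,
    estimate_dos,
    multicanonical_sample,
    tail_fraction,
    wang_landau_train,
)
from .sampling import block_sample, fraction_below

log = logging.getLogger("codescape")


@dataclass
class RunConfig:
    """Flat configuration with one section per stage (YAML round-trips)."""

    seed: int = 0
    min_asp: int = 2
    min_glu: int = 2

    # cost grid
    grid_lo: float = 2.0
    grid_hi: float = 16.0
    grid_width: float = 0.01

    # Wang-Landau schedule
    wl_log_f0: float = 1.0
    wl_log_f_min: float = 1e-5
    wl_flatness: float = 0.8
    wl_check_every: int = 200_000
    wl_max_steps: int = 600_000_000

    # fixed-weight multicanonical run
    muca_steps: int = 400_000_000  # total over all chains
    muca_chains: int = 4  # independent chains pooled (decorrelates peaks)
    muca_thinning: int = 100
    muca_max_records: int = 400_000
    # thinned all-cost reference run (Delta_PR-vs-cost curve)
    muca_ref_steps: int = 100_000_000
    muca_ref_thinning: int = 2000

    # block-ensemble sampling
    block_samples: int = 10_000_000

    # GA
    ga_runs: int = 1000
    ga_population: int = 100
    ga_mutation_rate: float = 0.1
    ga_generations: int = 500

    # landscape
    slice_delta: float = 0.1  # slice half-width around the SGC cost
    k_max: int = 8
    kmeans_restarts: int = 50
    ga_bin_width: float = 0.1

    def constraints(self) -> EnsembleConstraints:
        return EnsembleConstraints(min_asp=self.min_asp, min_glu=self.min_glu)

    def grid(self) -> CostGrid:
        return CostGrid(self.grid_lo, self.grid_hi, self.grid_width)

    def schedule(self) -> WangLandauSchedule:
        return WangLandauSchedule(
            self.wl_log_f0,
            self.wl_log_f_min,
            self.wl_flatness,
            self.wl_check_every,
            self.wl_max_steps,
        )

    def ga_config(self) -> GAConfig:
        return GAConfig(
            population_size=self.ga_population,
            mutation_rate=self.ga_mutation_rate,
            generations=self.ga_generations,
        )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") & 0x7FFFFFFF

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute the full analysis; returns a results dict and optionally
    writes artifacts (TSV curves, JSON metadata) under ``outdir``."""
    t0 = time.time()
    results: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    constraints = config.constraints()
    ev = CostEvaluator()
    system = SamplingSystem.standard(ev, constraints)
    sgc_cost = ev.cost(sgc())
    results["sgc_cost"] = sgc_cost
    log.info("SGC cost: %.4f", sgc_cost)

    count, log10_count = count_ensemble(constraints)
    results["ensemble_count_log10"] = log10_count
    log.info("ensemble count: 10^%.3f", log10_count)

    # --- block-structure ensemble rarity
    t = time.time()
    blocks = block_sample(
        config.block_samples, seed=config.stage_seed("block"), evaluator=ev
    )
    frac, ci = fraction_below(blocks, sgc_cost, strict=False)
    results["block_fraction_at_or_below_sgc"] = frac
    results["block_fraction_ci"] = ci
    log.info(
        "block ensemble: %.3g of %d at/below SGC cost (%.0fs)",
        frac,
        config.block_samples,
        time.time() - t,
    )
    del blocks

    # --- Wang-Landau training
    t = time.time()
    grid = config.grid()
    wl = wang_landau_train(
        system,
        grid,
        config.schedule(),
        seed=config.stage_seed("wang-landau"),
        strict=False,
    )
    results["wl_converged"] = wl.converged
    results["wl_steps"] = wl.steps
    results["wl_final_log_f"] = wl.final_log_f
    log.info(
        "Wang-Landau: %d steps, log_f=%.2e, converged=%s (%.0fs)",
        wl.steps,
        wl.final_log_f,
        wl.converged,
        time.time() - t,
    )
    if out is not None:
        wl.weight.to_tsv(out / "weight.tsv")

    # --- fixed-weight multicanonical production runs: several independent
    # chains pooled, so the low-cost region is entered many times and the
    # retained peak composition decorrelates across sojourns
    t = time.time()
    record_below = sgc_cost + config.slice_delta
    n_chains = max(int(config.muca_chains), 1)
    chain_steps = config.muca_steps // n_chains
    hist = None
    rec_assigns, rec_costs = [], []
    for j in range(n_chains):
        run = multicanonical_sample(
            system,
            wl.weight,
            steps=chain_steps,
            seed=config.stage_seed(f"muca-{j}"),
            thinning=config.muca_thinning,
            record_below=record_below,
            max_records=config.muca_max_records // n_chains,
            start=wl.final_state if j == 0 else None,
        )
        hist = run.hist if hist is None else hist + run.hist
        rec_assigns.append(run.rec_assigns)
        rec_costs.append(run.rec_costs)
    rec_assigns = np.concatenate(rec_assigns)
    rec_costs = np.concatenate(rec_costs)
    flat = hist[hist > 0]
    flat_ratio = float(flat.min() / flat.mean()) if flat.size else 0.0
    results["muca_steps"] = chain_steps * n_chains
    results["muca_chains"] = n_chains
    results["muca_flat_ratio"] = flat_ratio
    results["muca_records"] = int(rec_costs.size)
    log.info(
        "multicanonical: %d chains x %d steps, flat ratio %.2f, %d low-cost records (%.0fs)",
        n_chains,
        chain_steps,
        flat_ratio,
        rec_costs.size,
        time.time() - t,
    )

    # --- density of states and tails
    dos = estimate_dos(hist, wl.weight, mode="fraction", total=float(count))
    tail = tail_fraction(dos, sgc_cost)
    results["tail_fraction_below_sgc"] = tail
    results["tail_log10"] = float(np.log10(tail)) if tail > 0 else float("-inf")
    results["n_codes_below_sgc_log10"] = (
        results["tail_log10"] + log10_count if tail > 0 else float("-inf")
    )
    log.info("DOS tail below SGC cost: 10^%.2f", results["tail_log10"])
    results["dos_bin_centers"] = grid.centers.tolist()
    results["dos_log10_fraction"] = (dos.log_dos / np.log(10)).tolist()
    if out is not None:
        dos.to_tsv(out / "dos.tsv")

    # --- landscape reconstruction on retained multicanonical samples
    t = time.time()
    slice_bounds = (sgc_cost - config.slice_delta, sgc_cost + config.slice_delta)
    V = vectorize(rec_assigns)
    proj = pca_fit(V, rec_costs, cutoff=record_below)
    k_sel, sse = elbow_k(
        V, config.k_max, seed=config.stage_seed("elbow"), n_restarts=config.kmeans_restarts
    )
    model = fit_clusters(
        V, 4, seed=config.stage_seed("kmeans"), n_restarts=config.kmeans_restarts
    )
    model = name_clusters(model, V)
    occ = cluster_occupancy(model.labels, rec_costs, slice_bounds, model.k)
    model.occupancy = occ
    occ_by_color = {model.color_of[i]: float(occ[i]) for i in range(model.k)}
    results["elbow_k"] = int(k_sel)
    results["sse_curve"] = sse.tolist()
    results["pc1_evr"] = float(proj.explained_variance_ratio[0])
    results["pc2_evr"] = float(proj.explained_variance_ratio[1])
    results["muca_occupancy"] = occ_by_color
    log.info(
        "landscape: k=%d, EVR=%.3f/%.3f, occupancy=%s (%.0fs)",
        k_sel,
        results["pc1_evr"],
        results["pc2_evr"],
        occ_by_color,
        time.time() - t,
    )

    # --- genetic algorithm batch
    t = time.time()
    ga = ga_run(
        config.ga_config(),
        system,
        seed=config.stage_seed("ga"),
        n_runs=config.ga_runs,
        slice_bounds=slice_bounds,
    )
    reached = ga.reached()
    results["ga_runs"] = config.ga_runs
    results["ga_fraction_reached_slice"] = float(reached.mean())
    stats = trajectory_stats(ga, bin_width=config.ga_bin_width)
    if out is not None:
        stats.to_frame().to_csv(out / "ga_stats.tsv", sep="\t", index=False)

    if reached.any():
        ga_labels = assign_clusters(model, vectorize(ga.slice_assigns[reached]))
        ga_occ = np.bincount(ga_labels, minlength=model.k) / ga_labels.size
        results["ga_occupancy"] = {
            model.color_of[i]: float(ga_occ[i]) for i in range(model.k)
        }
        blue = [i for i, c in model.color_of.items() if c == "blue"][0]
        results["ga_blue_over_muca_blue"] = (
            float(ga_occ[blue] / occ[blue]) if occ[blue] > 0 else float("inf")
        )
    log.info("GA: %.2f reached slice (%.0fs)", reached.mean(), time.time() - t)

    # transition-rate shape summaries (rates above vs below cost ~4.5)
    centers = (stats.bin_edges[:-1] + stats.bin_edges[1:]) / 2
    low = centers < 4.0
    high = (centers > 5.0) & (centers < 10.0)
    with np.errstate(invalid="ignore"):
        rate_low = np.nansum(stats.trans_any[low] * stats.visits[low]) / max(
            np.nansum(stats.visits[low]), 1
        )
        rate_high = np.nansum(stats.trans_any[high] * stats.visits[high]) / max(
            np.nansum(stats.visits[high]), 1
        )
    results["ga_transition_rate_below_4"] = float(rate_low)
    results["ga_transition_rate_5_to_10"] = float(rate_high)
    results["ga_frac_neg_bins"] = stats.bin_edges.tolist()
    results["ga_frac_neg_conditional"] = stats.frac_negative_conditional.tolist()
    results["ga_frac_neg_all"] = stats.frac_negative.tolist()

    # multicanonical reference: fraction of Delta_PR<0 codes per cost bin,
    # from a thinned all-cost run (within a bin multicanonical samples are
    # ensemble-distributed, so raw fractions apply bin by bin)
    ref = multicanonical_sample(
        system,
        wl.weight,
        steps=config.muca_ref_steps,
        seed=config.stage_seed("muca-ref"),
        thinning=config.muca_ref_thinning,
        record_below=np.inf,
        max_records=config.muca_max_records,
        start=run.final_state,
    )
    dpr_mc = delta_pr_of_vectors(vectorize(ref.rec_assigns))
    nbin = len(stats.bin_edges) - 1
    mc_bins = np.clip(
        ((ref.rec_costs - stats.bin_edges[0]) / config.ga_bin_width).astype(int),
        0,
        nbin - 1,
    )
    tot = np.bincount(mc_bins, minlength=nbin).astype(float)
    neg = np.bincount(mc_bins[dpr_mc < 0], minlength=nbin).astype(float)
    with np.errstate(invalid="ignore"):
        results["muca_frac_neg"] = np.where(tot > 0, neg / tot, np.nan).tolist()

    results["elapsed_s"] = time.time() - t0
    if out is not None:
        meta = {k: v for k, v in results.items() if not isinstance(v, np.ndarray)}
        with open(out / "results.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=float)
        config.to_yaml(out / "config.yaml")
    return results
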