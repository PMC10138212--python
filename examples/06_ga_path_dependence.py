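"""Evolutionary path dependence under the multi-peaked landscape.

Runs a batch of truncation-selection GA optimizations and follows
Delta_PR — the right-minus-left column contrast in polar requirement —
along each trajectory.  Sign transitions die out early (above cost ~4-5),
so which peak a run ends in is decided long before it gets there.
Takes a minute or two.
"""

import numpy as np

from codescape import (
    CostEvaluator,
    EnsembleConstraints,
    GAConfig,
    SamplingSystem,
    delta_pr,
    ga_run,
    sgc,
    trajectory_stats,
)

ev = CostEvaluator()
system = SamplingSystem.standard(ev, EnsembleConstraints())
sgc_cost = ev.cost(sgc())
print(f"Delta_PR of the SGC itself: {delta_pr(sgc()):+.2f} (right-half enriched)")

batch = ga_run(
    GAConfig(), system, seed=41, n_runs=200,
    slice_bounds=(sgc_cost - 0.1, sgc_cost + 0.1),
)
reached = batch.reached()
print(f"{reached.sum()}/{batch.n_runs} runs reached the SGC-cost slice; "
      f"final best costs {batch.final_cost.min():.2f}..{batch.final_cost.max():.2f}")

stats = trajectory_stats(batch, bin_width=0.1)
centers = (stats.bin_edges[:-1] + stats.bin_edges[1:]) / 2


def window(vals, lo, hi):
    m = (centers >= lo) & (centers < hi) & np.isfinite(vals)
    return float(np.nanmean(vals[m])) if m.any() else float("nan")


print("\nDelta_PR sign-transition rate per generation:")
for lo, hi in [(2.5, 4.0), (4.0, 5.0), (5.0, 7.0), (7.0, 10.0)]:
    print(f"  cost {lo:4.1f}-{hi:4.1f}: {window(stats.trans_any, lo, hi):.2e}")

print("\nfraction of trajectories with Delta_PR < 0 (runs reaching the slice):")
for lo, hi in [(2.6, 3.0), (3.0, 4.0), (4.0, 5.0), (6.0, 8.0)]:
    print(f"  cost {lo:4.1f}-{hi:4.1f}: {window(stats.frac_negative_conditional, lo, hi):.2f}")

neg_final = float((batch.best_dpr[reached, -1] < 0).mean())
print(f"\nshare of slice-reaching runs ending with Delta_PR < 0: {neg_final:.2f}")
print("\nThe plateau below cost 4-5 is the GA's bias frozen in early: an")
print("unbiased sample of SGC-grade codes puts only ~3% in the blue peak.")
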