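"""Validating the samplers on an exactly enumerable toy system.

A miniature codon system (4 two-letter codons over 2 bases, 3 amino
acids) is small enough to enumerate every assignment, giving an exact
density of states.  Wang-Landau training plus fixed-weight multicanonical
sampling must reproduce it bin by bin — the same code path later applied
to the 20^61-state real problem.
"""

import numpy as np

from codescape import (
    CostGrid,
    WangLandauSchedule,
    estimate_dos,
    multicanonical_sample,
    tail_fraction,
    wang_landau_train,
)
from codescape.synthetic import enumerate_states, exact_dos, make_toy

toy = make_toy(n_bases=2, codon_len=2, n_aa=3, seed=1)
states, costs = enumerate_states(toy)
print(f"toy system: {toy.n_codons} codons, {toy.n_aa} amino acids, "
      f"{toy.n_states} assignments, {len(states)} satisfy the constraints")

grid = CostGrid(np.floor(costs.min()), np.ceil(costs.max()) + 0.5, 0.5)
exact = exact_dos(toy, grid)

wl = wang_landau_train(
    toy.system(), grid,
    WangLandauSchedule(log_f_min=1e-5, check_every=20_000, max_steps=20_000_000),
    seed=5,
)
print(f"Wang-Landau converged after {wl.steps} steps ({wl.n_passes} flat passes)")

run = multicanonical_sample(toy.system(), wl.weight, steps=2_000_000, seed=6)
dos = estimate_dos(run.hist, wl.weight, mode="fraction")

print("\n  bin center   exact fraction   estimated fraction")
for b in np.flatnonzero(exact > 0):
    print(f"  {grid.centers[b]:10.2f}   {exact[b] / exact.sum():14.4f}   "
          f"{np.exp(dos.log_dos[b]):18.4f}")

thr = float(np.median(costs))
print(f"\ntail below cost {thr:.2f}: estimated {tail_fraction(dos, thr):.4f}, "
      f"exact {exact[grid.centers < thr].sum() / exact.sum():.4f}")
print("\nAgreement within Monte-Carlo error certifies the estimator before")
print("it is trusted twenty orders of magnitude beyond what enumeration")
print("or naive sampling can reach.")
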