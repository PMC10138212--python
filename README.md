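# codescape

**Rare-event sampling of the genetic code fitness landscape.**

Nearly all organisms share the same genetic code — the standard 64-codon
→ 20-amino-acid + stop mapping (SGC) — and a long line of work measures
how exceptional it is by its robustness to translational misreading: the
cost

&nbsp;&nbsp;&nbsp;&nbsp;cost(*a*) = Σ<sub>c</sub> Σ<sub>c′</sub> P(c′|c) · d(a(c), a(c′)),

where P(c′|c) weights single-base misreadings by position and
transition/transversion class, and d is the squared difference in polar
requirement (Woese's hydrophilicity scale) between the encoded amino
acids.  The SGC scores 2.63; typical random codes score ≈ 12.

`codescape` is a library for asking how rare SGC-grade codes are — not
in the classic block-permutation ensemble of 20! codes, but in the full
constrained ensemble of ~10⁷⁹ codes in which every codon may encode any
amino acid (stops fixed, all 20 present, ≥ 2 Asp and Glu).  At that
rarity (~10⁻²⁰) naive sampling is hopeless, so the package implements:

- **Exact combinatorics** — inclusion–exclusion ensemble counting;
- **Multicanonical Monte Carlo** — Wang–Landau training of a weight
  w ∝ 1/Ω(cost), fixed-weight sampling, density-of-states and tail
  estimation, numba-compiled at ~10⁷ steps/s;
- **Landscape reconstruction** — PCA of polar-requirement vectors,
  elbow/k-means peak detection, per-peak occupancies and average codes;
- **Genetic-algorithm path dependence** — truncation-selection GA
  batches with Δ_PR trajectory analytics showing how a narrow fitness
  peak captures far more evolutionary runs than its volume warrants;
- **Exactly enumerable toy systems** so every estimator is validated
  against ground truth before being trusted 20 orders of magnitude out.

It is aimed at molecular-evolution researchers studying code optimality
and, more broadly, anyone estimating densities of states of rugged
discrete landscapes.

## Worked example

Cost of the standard code (`examples/01_cost_of_the_standard_code.py`):

```
standard genetic code: FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG
constraint violations: []
misreading cost of the SGC: 2.6283
```

Ensemble size and what naive sampling can (not) see
(`examples/02_ensemble_counting_and_naive_sampling.py`):

```
constrained ensemble size: 10^78.787  (~6.12e+78)
naive sampling (n=1e5): cost mean 12.68, min 6.90  (SGC: 2.63)
fraction below the SGC cost: 0.0  (95% CI 0.00e+00..3.84e-05)
block-permutation ensemble (n=1e6): fraction at/below SGC 1.0e-06  (95% CI 1.8e-07..5.7e-06)
```

A hundred thousand random codes never come within four cost units of
the SGC; only the heavily constrained block ensemble reaches it at all,
about once per million draws.  The multicanonical estimate of the same
quantity in the full ensemble (`examples/04_rarity_of_the_standard_code.py`):

```
Wang-Landau: 4.64e+07 steps, converged=True, 1400/1400 bins covered
fixed-weight run: flat-histogram ratio 0.91

fraction of random codes more robust than the SGC: 10^-20.28
absolute number of such codes: 10^58.50
```

One in ~10²⁰ random codes beats the standard code — yet ~10⁵⁹ such
codes exist.  `examples/05_landscape_reconstruction.py` then shows the
low-cost region splitting into four peaks (occupancies ≈ 43/31/23/3%,
the SGC in the third), and `examples/06_ga_path_dependence.py` shows a
genetic algorithm delivering up to ~30% of its runs into the ~3% "blue"
peak, because peak choice is frozen in before cost 4–5 — evolutionary
outcome tracks basin size, not peak volume.

The whole analysis is also available as one configurable call
(`examples/07_full_pipeline.py`):

```python
from codescape import RunConfig, run_pipeline
results = run_pipeline(RunConfig(seed=1), outdir="pipeline_output")
```

## Layout

```
src/codescape/
  codons.py          codes, codon indexing, ensemble constraints, SGC
  scales.py          amino-acid property scales (polar requirement fixture)
  counting.py        exact inclusion-exclusion ensemble counts
  cost.py            misreading model, penalties, full/incremental cost
  sampling.py        naive + block-permutation samplers, flip proposal
  multicanonical.py  cost grids, Wang-Landau, fixed-weight sampling, DOS
  ga.py              genetic algorithm, Delta_PR trajectory statistics
  landscape.py       PCA, elbow/k-means, occupancies, stacked landscape
  synthetic.py       enumerable toys, planted blobs (exact oracles)
  pipeline.py        config-driven end-to-end pipeline and artifacts
```
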