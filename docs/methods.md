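# Methods

## The model

A genetic code is a map `a` from the 64 codons to the 20 amino acids or
the stop signal; codons are indexed 0 (UUU) … 63 (GGG) with base order
U, C, A, G.  Robustness against translational misreading is measured by

    cost(a) = Σ_c Σ_c' P(c'|c) · d(a(c), a(c')),

where `P(c'|c)` is nonzero only for single-base neighbors and depends on
the changed position and on whether the change is a transition (within
purines or within pyrimidines) or a transversion:

| change                  | raw weight |
|-------------------------|-----------:|
| 3rd base, any           | 1          |
| 1st base, transition    | 1          |
| 1st base, transversion  | 0.5        |
| 2nd base, transition    | 0.5        |
| 2nd base, transversion  | 0.1        |
| ≥2 bases                | 0          |

and `d(a, a') = (PR(a) − PR(a'))²` is the squared difference of polar
requirement, Woese's chromatographic hydrophilicity scale (shipped as a
data fixture; Asp 13.0 and Glu 12.5 are its two largest values).
Misreadings to or from a stop codon carry constant costs `c0`, `c1`,
zero by default — they only shift the baseline.

**Normalization.**  Raw weights are divided by their total over all
ordered sense–sense neighbor pairs (pairs involving a stop are excluded
from numerator and denominator, consistently with `c0 = c1 = 0`).  This
is the weighted-mean convention of the classic error-minimization
literature, and under it the standard genetic code (SGC) scores 2.6283 —
the printed "2.6".  Normalizing over all pairs including stops instead
would give 2.40; the convention is pinned by that published value.

Two cost variants are exposed as extension points and validated only
qualitatively: weighting each term by the frequency of the source amino
acid, and replacing `d` by a score-derived penalty
`d(a,b) = (S(a,a)+S(b,b))/2 − S(a,b)` built from a substitution matrix
such as BLOSUM62 (symmetric, zero diagonal, monotone decreasing in the
score).  The exact constants of the published variants are not
reproduced here.

## The random-code ensemble

Codes vary freely — no block structure — subject to four conditions:
(1) every codon encodes one of the 20 amino acids, (2) the three stops
sit at the SGC's positions, (3) all 20 amino acids appear, and (4) Asp
and Glu appear at least twice each (their SGC multiplicities; without
this floor nearly all low-cost codes keep a single copy of each, because
these two residues dominate the penalty range).  A relaxed variant drops
(4) to single copies.

The ensemble size is computed exactly by inclusion–exclusion through
exponential generating functions: each amino acid with multiplicity
floor m contributes a factor `(e^x − Σ_{j<m} x^j/j!)`, and the count is
`61! [x^61]` of the product, evaluated in exact integer/rational
arithmetic.  The default ensemble holds 6.118×10⁷⁸ codes (log₁₀ =
78.79, i.e. "~10⁷⁹"); the generic counter is cross-checked against
brute-force enumeration on every toy space.

## Multicanonical estimation of the density of states

Typical random codes cost ≈ 12 ± 2; SGC-grade codes (cost ≤ 2.63) are
~20 orders of magnitude too rare for direct sampling.  The package
therefore samples the Markov chain of single-codon reassignments under
the multicanonical weight `w(cost) ∝ 1/Ω(cost)` (Ω = density of states),
with acceptance `min(1, w(cost')/w(cost))`; candidates violating
conditions (3)/(4) are rejected in place, which preserves the stationary
distribution on the constrained set.  The chain then random-walks along
the cost axis, and the DOS follows from a fixed-weight run's histogram
as `Ω ∝ H/w`.

The weight is trained by Wang–Landau iteration: visiting a bin adds
`log f` to its running `log g` estimate, and whenever the histogram over
*all bins ever visited* is flat (minimum ≥ 80% of the mean), `log f` is
halved and the histogram reset, from `log f = 1` down to 10⁻⁵ (10⁻⁶ for
desk-scale toys).  Checking flatness over the global visited set, not
just the current pass, matters: bins discovered late start with a
grossly underbuilt `log g`, and a pass may only complete once the chain
has re-integrated them — otherwise the production run treats them as
near-inescapable traps.  For the same reason, bins never visited during
training are assigned a log-weight 50 below the minimum trained value,
so the production chain avoids them rather than falling in.

**Grid.**  Costs are binned at width 0.01 over [2, 16) with clamping
edge bins; the range was fixed from pilot runs (bulk at 12 ± 2.2,
reachable floor near 1.2 at vanishing density).  The bottom clamp bin
aggregates all states below cost 2, which is exactly what the tail
integral at the SGC cost needs, and bounding the range keeps Wang–Landau
range discovery from stalling convergence.  Bin width 0.01 resolves the
SGC ± 0.1 slice.

**Normalization.**  Fraction mode normalizes `Σ exp(log Ω) = 1` over
visited bins; absolute mode multiplies by the exact ensemble count — a
stronger anchor than matching the naive-sampling histogram, which is
instead used as a consistency check in the high-cost overlap region.
Empty bins are masked, never set to zero.

At the shipped problem sizes (Wang–Landau to `log f < 10⁻⁵`, ≈ 4×10⁷
steps; production sampling pooled over four independent chains of 10⁸
steps each) the tail below the SGC cost comes out at 10⁻²⁰·³ of the
ensemble, about 10⁵⁸·⁵ codes in absolute count.  Pooling independent
chains matters less for the tail than for the landscape: each descent
into the low-cost region tends to stay within one fitness peak, so the
retained peak composition decorrelates across chains, not within one.  On
enumerable toys the same machinery reproduces the exact DOS within 0.2
in log₁₀ per bin and the exact tail fractions within Monte-Carlo error.

## Landscape reconstruction

Low-cost states (cost < SGC + 0.1) are retained from the production
chains (thinning 100, ~2×10⁵ states pooled) and embedded as 64-vectors whose entry c
is the polar requirement of the amino acid at codon c (stop positions
hold a constant and carry no variance).  PCA is fitted on this low-cost
set with mean-centering only — all coordinates share polar-requirement
units, so rescaling would distort the geometry.  Signs are fixed
deterministically: PC1 so the SGC scores nonnegative, PC2 so it
correlates positively with Δ_PR (below).  PC1/PC2 explain ≈ 26%/15% of
the variance.

Cluster count selection and k-means run on the full 64-dimensional
vectors, not the 2-D projection.  The tiny fourth peak (~3% of the
slice) barely reduces 2-D SSE, and a 2-D elbow reads k = 3; in 64
dimensions the SSE falls rapidly to k = 4 and slowly after, and both
knee readings agree on 4.  The knee rule is the largest relative
drop-off — the k maximizing (SSE drop achieved by k)/(SSE drop achieved
by k+1) — with a featureless curve (all ratios < 3) reporting k = 1; on
planted Gaussian blobs it recovers the planted count for separations ≥ 5
within-cluster standard deviations.  k-means uses 50 seeded restarts
(10 in the quick examples).

Peak names follow the conventional coloring, assigned by rule rather
than by eye: *green* is the cluster whose center is nearest the SGC,
*blue* the one with the most negative mean Δ_PR (high polar requirement
in the left half of the table), *red*/*orange* the larger/smaller of the
rest.  Occupancies within the SGC ± 0.1 cost slice use raw sample
fractions: the multicanonical weight depends only on cost, so inside a
narrow slice retained states are already ensemble-distributed.  At the
shipped sizes the slice splits ≈ 43/31/23/3% (red/orange/green/blue).

## Genetic algorithm and path dependence

The GA holds N = 100 codes, initialized uniformly from the constrained
ensemble.  Each generation the population is ranked by cost, the best
half survives unchanged, and each survivor is copied exactly once
("sampling without replacement" — the only reading that reaches exactly
N and yields the elitism the dynamics show); copies are mutated per
sense codon at rate μ = 0.1, redrawing the whole mutated copy if it
violates conditions (3)/(4) (capped at 1000 redraws; exceeding the cap
is an error).  No crossover.  500 generations.  A config switch mutates
survivors too, for the alternative reading; it breaks the nonincreasing
best-cost guarantee and is off by default.  Ranking ties are broken by
numpy's deterministic argsort; tied individuals are in practice
identical copies, so the choice cannot affect the dynamics, and fixed
seeds reproduce runs bit for bit.

Trajectories are summarized by the best individual per generation and
its Δ_PR = ⟨PR⟩_R − ⟨PR⟩_L, the mean polar requirement over sense codons
with second base A/G minus those with U/C.  Statistics are binned at
width 0.1 in cost (the slice convention): sign-transition rates per
generation-visit, a per-run "latest value" curve (revisited bins keep
the latest Δ_PR, making each run univalent in cost), and the fraction of
runs with Δ_PR < 0, unconditional and conditioned on reaching the
SGC ± 0.1 slice.  With 10³ runs, ~92% reach the slice; ~29% of those
land in the blue peak — an ~10× enrichment over the unbiased ~3% —
while sign transitions collapse below cost ≈ 4–5 (rate ~2×10⁻⁴ per
generation vs ~6×10⁻² at cost 5–10) and the conditional Δ_PR < 0
fraction is flat below that point.  Peak membership of a GA code is the
nearest 64-D k-means center from the multicanonical clustering.

## Synthetic systems

Toy systems shrink every structural feature of the real problem —
single-position misreading neighbors, a class-structured weight table
(last position weight 1, earlier positions 0.5, and for 4-letter
alphabets a transition/transversion split of ×1 vs ×0.2), a property
scale whose two designated symbols hold the top values 13.0/12.5
(emulating Asp/Glu), per-symbol multiplicity floors — while keeping the
state count enumerable (cap 2×10⁶).  They exercise the identical kernel
code paths, so exact-DOS agreement on toys certifies the estimator
logic, though not, of course, the mixing behavior at 10⁷⁹ states; that
is checked on the full problem via the flat-histogram diagnostic and the
naive-sampling overlap.  `planted_blobs` generates isotropic Gaussian
clusters at controlled separation (regular-simplex centers when k ≤
dim+1) for elbow/k-means recovery tests.

## Problem sizes and determinism

Shipped defaults per stage: block ensemble 10⁷ permutations;
Wang–Landau ≤ 6×10⁸ steps (converges in ~4×10⁷); production sampling
4×10⁸ steps over four pooled chains, plus a 10⁸-step thinned reference
run for the Δ_PR-vs-cost curve; GA 10³ runs.  The published analysis used 10¹¹ sampling steps and 10⁵ GA
runs; at the shipped sizes the tail estimate carries roughly ±1 decade
and occupancies a few percentage points, which the acceptance checks
reflect.  Every stochastic stage takes an explicit seed derived from the
run seed by hashing the stage name; identical configs reproduce all
outputs byte for byte.  All heavy loops are numba-compiled
(~10⁷ Monte-Carlo steps/s on one core).

## Known limitations

- The misreading model is position/TS-TV only; context-dependent or
  mutational (DNA-level) error models are out of scope.
- Stop placement never varies, so the landscape is conditional on the
  SGC's stop positions (the source of its asymmetric shape).
- Wang–Landau convergence is diagnosed by histogram flatness; systematic
  weight error beyond the flatness level is controlled only through the
  toy oracles, the exact-count anchor, and the naive-sampling overlap.
- The published variant cost functions (amino-acid frequency, BLOSUM)
  are implemented as interfaces with reasonable transforms, not as
  reproductions of the published constants.
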