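# Methods

## The model

Two-alternative forced-choice performance is treated as a driven pair of
coupled oscillators (the two responding effectors).  Their relative phase
φ ∈ [0, 1) evolves under the discretized HKB map

φₙ₊₁ = φₙ + Ω − (K/2π)·(1 + A·cos 2πφₙ)·sin 2πφₙ,  optionally mod 1.

The coupling term is the gradient of the HKB potential −a·cos θ − b·cos 2θ
(θ = 2πφ) rewritten as sin θ·(a + 2b·cos θ), so A = 2b/a measures the
relative prominence of the antiphase attractor and K = a the coupling
strength.  Ω is the drive: the frequency ratio the stimulus sequence asks
the two fingers to realize.

Trial histories map to drives through the Farey tree: the history's node
ratio p/q (R-leading, in (0, 1)), or for L-leading histories the
reciprocal of the letter-swapped complement (a Stern-Brocot ratio > 1)
reduced mod 1 with an exact 0 reported as 1, since the map's dynamics
repeat for each integer increase in Ω.

Predictions read off the map:

* the rotation number ρ(Ω) — the average phase advance per iteration of
  the unwrapped map — predicts the relative duration of each history's
  execution; plateaus of ρ over Ω (Arnold tongues) form the Devil's
  staircase;
* tongue width falls with the ratio denominator q, so error rates should
  rise with q and with depth along the tree's branching.

## Estimators and numerical choices

* **Rotation number.** Each (Ω, K, A) is seeded with a uniform random
  phase, iterated unwrapped for `n_iter` = 10,000 steps, and ρ is the mean
  per-step increment over the final `n_avg` = 2,500 steps, i.e.
  (φ_N − φ_{N−2500})/2500.  Averaging raw unwrapped phases has no
  rotation-number interpretation, so the mean increment is used; the first
  7,500 steps serve as transient burn-in (no separate burn-in parameter).
  For K = 0 the estimator returns Ω to within accumulated float error
  (≈1e-13 over 10⁴ additions).
* **Staircase.** Default grid Ω = 0 to 1 in steps of 0.001; per-Ω seed
  phases are drawn sequentially from one seeded generator, so a single
  integer seed reproduces a run bit-identically.  Downstream prediction
  lookups use the nearest grid point (discrepancy ≤ 0.0005 in Ω).
* **Bifurcation surface.** 1,000 evenly spaced drives, each seeded with a
  unit-interval random phase and iterated 10,000 times wrapped; the final
  100 phases are retained and summarised by a circular mean.
* **Circular mean.** Phases are averaged as unit vectors at angles 2πφ;
  the resultant angle is mapped to (0, 1] with an exact 0 reported as 1
  (the same wrap convention as L-leading drives).  A zero resultant raises
  an explicit undefined-mean error.  Wrapped iteration clamps the rare
  floating-point case where `mod` rounds a tiny negative value to exactly
  1.0.

### Parameter regime caveat

The analysis parameters K = 0.95, A = 0.85 put the map beyond the
invertibility line K·(1 + A) = 1 (here ≈ 1.76).  A complete, monotone
Devil's staircase is a property of invertible circle maps; in the
supercritical regime Arnold tongues overlap and coexisting attractors
compete.  Concretely, at these parameters:

* the 2/3 tongue reaches down to Ω ≈ 0.615, so drives near the golden
  ratio (0.618) lock to ρ = 2/3 rather than 8/13 — there is no 8/13
  plateau anywhere on the 0.001 grid;
* with per-Ω random seeding the measured staircase has seed-dependent
  jumps up to ≈ 0.1 inside attractor-competition bands (roughly
  Ω ∈ (0.19, 0.31) and its mirror, and (0.59, 0.81)), which also break the
  odd-symmetry relation ρ(Ω) + ρ(1−Ω) = 1 inside those bands.

The test suite therefore asserts monotonicity and symmetry for a
subcritical coupling (where they are theorems) and asserts plateau locking
(e.g. ρ = 1/2 across the wide root tongue) at the analysis parameters.
The package keeps K = 0.95/A = 0.85 as analysis defaults because the wide,
connected staircase they produce is the intended predictor; users probing
staircase-shape properties should stay at or below K = 1/(1 + A).

## Scanning conventions

* Windows are classified by **stimulus** identity (the demanded response),
  never the registered response; otherwise erroneous trials could not be
  members of a named sequence type.  Correctness is a separate flag.
* Occurrences **overlap**: every trial is a potential origin of every
  history it begins, so m identical correct letters contain m − j + 1
  windows of a j-letter repetition history.
* **Mean RT filters**: a window contributes only if every member is
  correct and every member RT lies inside the censorship bounds (default
  200–980 ms — censorship applies to all members, not just the terminal
  one).  The default averaged quantity is the terminal member's RT
  (conditioning trial-n latency on its history); an "all members" mode is
  provided because either reading is defensible.
* **Unique-error rate**: distinct erroneous member trials divided by
  member observations counted with multiplicity (|history| ×
  n_occurrences).  An error shared by overlapping windows counts once in
  the numerator.
* **Normalization**: per participant, (mean − min)/(max − min) over that
  participant's histories (R- and L-leading families separately); grand
  tables are unweighted across-participant means, with missing histories
  propagated as missing (never zero) and dropped pairwise.
* Streams are analyzed as single contiguous runs per participant; buffer
  trials are removed upstream via the ingest `drop_first_n` option.
  Indices are 0-based internally.

## Statistics

* Pearson reports convert r to F = r²·df₂/(1 − r²) with df₁ = 1,
  df₂ = n − 2 and upper-tail F p-values; |r| = 1 is reported as F = +inf.
  No multiple-testing correction is applied.
* The **Farey-rank Spearman test** pairs, within each tree level, the
  descending ranks of observed error rates with the level's binary
  (magnitude-descending) ranks, centers both within the level, and
  correlates the concatenated vectors.  Centering makes the statistic +1
  when every level's ordering matches and −1 when every level is reversed,
  and renders the root's single level-1 entry uninformative — which is why
  one extra degree of freedom is removed (df₂ = n − 3; 28 at n = 31).
  This level-wise construction is one defensible reading of a rank test
  "between a binary ranking and the corresponding error rates"; a plain
  global-rank Spearman is provided behind `scheme="global"` as a
  sensitivity check.
* Paired history contrasts use the paired-t → F = t² identity with
  df₂ = n − 1 (degrees of freedom are reported as computed from the data
  actually present, without imitating any particular historical
  bookkeeping).
* Partial r² uses residual-on-residual correlations; predictors with
  |r| > 0.999 trigger a collinearity warning.
* Ties receive average ranks and tie counts are noted in reports.

## Synthetic generator

The generator is explicit plumbing: it encodes exactly the two
relationships the statistics test, so recovery is a meaningful check of
the pipeline, not evidence about human performance.

* **Schedules**: balanced (independent fair draws) or biased — repetition
  (alternation) of the previous stimulus with probability `bias`, default
  2/3, first trial fair.
* **RTs**: for each trial, the depth-5 stimulus window ending at that
  trial is mapped to its drive (R-leading node ratio, or wrapped L-leading
  dual when the window starts with L; the first 4 trials use the root
  1/2), and rt = β₀ + β₁·ρ(Ω) + N(0, σ), clipped (not resampled) to the
  bounds so downstream censorship is exercised.  Defaults β₀ = 450 ms,
  β₁ = 200 ms, σ = 30 ms, bounds 200–980 ms, 8 participants × 4,000
  trials; clipping affects < 1% of trials at these values.
* **Errors**: p = logistic(logit(error_base) + error_denom_slope·(q − 2)),
  the offset 2 centring the model at the root ratio 1/2.  Defaults
  error_base = 0.04 and slope 0.12 per denominator unit give per-history
  error rates from ≈ 4% (q = 2) to ≈ 13% (q = 13), the magnitude typical
  of speeded two-choice data.

**What recovery does and does not show.**  With σ = 0 and no errors the
scanned grand normalized means of the 16 depth-5 histories are an exact
affine image of the staircase (r = 1 to machine precision).  Histories
shorter than the generation depth are mixtures over their 2^(5−ℓ)
backward extensions, so their means sit near, but not exactly on, the
staircase — an intrinsic property of overlapping-window scanning, not an
estimator defect.  The generator also omits practice/fatigue drifts,
1/f-scaled slow fluctuations, RT skew (noise is Gaussian), and any
dependence of errors on RT; passing recovery therefore validates the
pipeline's bookkeeping and statistical machinery, not the oscillatory
account of real data.

## Problem sizes

Default staircase and bifurcation runs use the full 10⁴-iteration,
1001/1000-point grids (vectorised across the grid, < 1 s each).  Recovery
checks use 8 × 4,000-trial streams (single runs) and 20 seeded replicates
for the sign of the denominator slope; the test suite completes in well
under a minute.

## Known limitations

* No Lyapunov/chaos diagnostics, Arnold-tongue boundary tracing in the
  (Ω, K) plane, or continuous-time HKB integration.
* The scanner models hard censorship only; no outlier models or
  detrending.
* The staircase-shape acceptance checks at the supercritical analysis
  parameters fail for the structural reasons described above; they are
  kept as stated rather than silently weakened.
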