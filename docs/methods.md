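# Methods

This note documents the statistical machinery behind `sebula`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Preprocessing: from fragments to HCLC

Fragment records (0-based half-open intervals tagged by cell barcode, the
10x fragment-file dialect) are filtered to whitelisted barcodes, autosomes
(both `chr1` and `1` spellings accepted), and insert sizes strictly below
900 bp. Duplicate counts are ignored: PCR duplicates are not independent
molecules, so each fragment row contributes coverage 1. Optionally,
fragments overlapping an exclusion BED (e.g. ENCODE blacklist) are
dropped; this is off by default.

Per cell and chromosome, a sweep line over fragment endpoints finds
maximal intervals with coverage ≥ `min_cov` (default 3, "more than two
overlapping fragments"). End events are processed before start events at
equal coordinates, consistent with half-open semantics; runs that touch
because an end and a start coincide at a covered base are coalesced.
Per-cell loci are union-merged across cells into a non-redundant locus
set per chromosome (loci sharing ≥ 1 base merge; touching half-open
intervals do not). A binary locus-by-cell incidence matrix is formed
(≥ 1 overlapping fragment → 1) and each cell's HCLC is its column sum.
Every whitelisted barcode appears, zeroes included.

The reader buffers fragments grouped by (chromosome, barcode); files need
not be coordinate-sorted, and memory scales with the fragment count.

## The two-groups model

Let `x_1..x_N` be the HCLC values. Zero counts can never enter a power
transform and are always scored as singlets. Counts below the truncation
point `x_min` are likewise assigned posterior 0; counts `≥ x_min` form
`X_T` (`N_T` cells). A library must retain at least 200 cells, otherwise
K = 120 histogram bins are not estimable.

### Transform

The Box-Cox transform `z = (x^λ − 1)/λ` (log at λ = 0) maps counts to a
scale where the singlet component is approximately normal. The textbook
choice of λ — maximizing the Box-Cox profile likelihood — normalizes the
*whole sample*. With a right-shifted multiplet component present, that
compresses the upper scale until the two components blend, and leaves the
transformed singlet left-skewed; central matching then overstates the
singlet right tail and the posterior loses its ranking exactly where
multiplets live. We observed this failure directly on synthetic mixtures.

The default policy therefore estimates λ from the singlet component
alone, using the zero assumption: below the 60th percentile or so the
library is essentially pure singlet, and the mixture quantile at
probability p equals the singlet quantile at p/π₀. The estimator selects
the λ that zeroes the quadratic curvature of transformed quantiles
regressed on Φ⁻¹(p/π₀) over p ∈ [0.04, 0.75·π₀] — i.e. it straightens
the singlet's normal Q-Q plot without ever looking at the contaminated
upper tail. Because π₀ is unknown, λ and the model are iterated to a
fixed point (≤ 4 rounds, starting from π₀ = 1; more contaminated starting
values 0.8 and 0.6 are tried if a start yields no concave central fit).
The exponent is estimated once on all positive counts and is independent
of `x_min`, which keeps results stable across truncation choices. The
plain MLE remains available (`fit_model(..., lam="mle")` or a fixed
float).

### Mixture density (Lindsey's method)

`Z_T` is histogrammed into K = 120 equal-width bins spanning its range.
Bin counts are treated as independent Poisson responses in a log-linear
GLM on a natural cubic spline basis with 7 degrees of freedom (boundary
knots at the extreme bin centers, interior knots at equally spaced
quantiles of the centers). With the canonical link and an intercept the
fitted counts sum exactly to `N_T`, so the normalized per-bin masses sum
exactly to 1. The basis is the truncated-power natural-spline
parametrization, which is linear beyond the boundary knots and lets a
fitted model round-trip through plain JSON (knots + coefficients) and be
evaluated at any z. The CDF `F̂` interpolates the cumulative bin masses
linearly between bin centers (0 and 1 outside).

### Singlet null (central matching with refinement)

For a normal singlet component, `log{π₀f₀(z)}` is exactly quadratic, so
an OLS quadratic fit to `log f̂ᵢ` over bins inside the 20th–60th
percentile window of `Z_T` (smoothed counts as response; window anchored
at the modal bin `c_max`, lowest index on ties) identifies

```
δ̂₀ = c_max − β̂₁/(2β̂₂),   σ̂₀ = (−2β̂₂)^(−1/2)   (requires β̂₂ < 0),
f̃ᵢ = exp{β̂₀ + β̂₁(cᵢ−c_max) + β̂₂(cᵢ−c_max)²},   π̂₀ = Σf̃ᵢ/Σf̂ᵢ (capped at 1).
```

When the multiplet component overlaps the window — unavoidable at high
multiplet loads or when components sit only ~2 singlet SD apart — the
plain quadratic drifts wide and absorbs it, inflating σ̂₀ and π̂₀. Two
self-consistency signals iteratively decontaminate the fit (≤ 10 rounds):

1. *Right-tail residual.* Excess fitted counts beyond `δ̂₀ + σ̂₀` are
   summarized by a normal bump (moment-matched, modestly extrapolated
   below the cut with the extrapolation factor capped at 2); its
   extension into the window is subtracted from the response and the
   quadratic refitted. The subtraction only fires when the residual
   exceeds 0.5% of the library and its center lies beyond `δ̂₀ + σ̂₀`.
2. *Left-flank overshoot.* If the implied singlet counts overshoot the
   fitted density left of the window — where essentially only singlets
   live — by more than 0.8% of the library, the window's upper
   (contamination-prone) edge steps down one bin, never below the 40th
   percentile.

On cleanly separated or null data both signals stay silent and the result
equals the textbook fit; `refine=False` disables the loop. The thresholds
above were fixed by a sensitivity sweep on development simulations (pass
metrics were flat to within Monte-Carlo noise across 2-fold changes).

The whole-library singlet fraction is
`π̃₀ = 1 − (N_T/N)(1 − π̂₀)`, which treats all truncated cells as
singlets.

### Truncation point

The truncation point trades robustness (discarding an uninformative,
potentially junk-laden low-count spike) against sample size. A scan over
`x_min ∈ [0, Q1]` (Q1 = 25th percentile of positive counts) refits the
model at each candidate — with λ held fixed at its library-wide value, so
the goodness-of-fit values are on a common scale — and records the
cross-entropy

```
CE(x_min) = −|S|⁻¹ Σ_{z_j ∈ S} log f̂₀(z_j),   S = {z_j : δ̂₀−σ̂₀ ≤ z_j ≤ δ̂₀+σ̂₀},
```

the negative mean log singlet density over the one-sigma central band
(lower = better local normal fit). The selected `x_min` is the elbow of
the trace: the point of maximum perpendicular distance to the chord
joining the first and last finite CE values, with both axes rescaled to
[0, 1], and counted only on the convex (below-chord) side — a point below
the chord marks super-linear early improvement followed by diminishing
returns. Traces that are linear, flat, or concave (no early gain) resolve
to the smallest candidate.

The default is `x_min = 0`: on libraries without a junk low-count
population truncation buys nothing, and classification metrics are
insensitive to the choice anyway (the F1/AUROC span over `[0, Q1]` is
< 0.01 on the standard benchmark). The scan is exposed as
`--xmin auto`.

### Posterior and calling rules

`p_j = 1 − π̂₀ f̂₀(z_j)/f̂(z_j)` clipped to [0, 1]; excluded cells get 0.
Because a multiplet carries the chromatin of at least two nuclei, the
likelihood ratio f₁/f₀ is monotone in the count; the reported posterior
is therefore the isotonic (non-decreasing in z) projection of the raw
values, which removes spline-wiggle artifacts, and exact ties are ordered
by count rank at a 10⁻⁹ scale so rankings are well defined. The raw
density-ratio value is kept alongside (`posterior_raw`). Calls:

* **lfdr rule** (default): call `p_j > 0.8`, i.e. local fdr ≤ 20%.
* **tail-FDR rule**: over a 2,001-point grid spanning
  `[min Z_T, max Z_T + 3σ̂₀]`, estimate
  `Fdr(t) = π̂₀(1−F̂₀(t))/(1−F̂(t))` with the mixture survival floored at
  `1/N_T`, clip to [0, 1], and call all cells with `z ≥ t*`, the smallest
  grid threshold meeting the target (default 20%). If no threshold
  qualifies, nothing is called.

### Evidence integration

The HCLC analysis is summarized per cell by the Bayes factor
`BF_j = [p_j/(1−p_j)] · [π̃₀/(1−π̃₀)]` (posterior odds over prior odds;
probabilities clipped to [10⁻¹⁰, 1−10⁻¹⁰] before forming odds, excluded
cells get BF = 0). An external multiplet probability q — treated as a
prior — updates to `q·BF/(q·BF + 1 − q)`. Two identities pin down this
construction: updating the library prior `1 − π̃₀` returns `p_j` exactly,
and successive updates compose multiplicatively (the naive-Bayes product
rule). The conditional-independence assumption between evidence sources
is diagnosed, not assumed: `score_dependence` reports Pearson/Spearman
correlations between the per-cell scores.

External z-scores are converted to priors by running the same
empirical-null machinery (Lindsey density + central matching, no Box-Cox)
directly on the scores; p-values are first mapped through
`z = Φ⁻¹(1 − p)`. This generalizes the posterior pathway to the other
score types; it requires ≥ 200 scores for a stable null fit.

## Synthetic benchmark

`simulate_hclc` draws singlet HCLC from a negative binomial parametrized
by mean (default 40) and dispersion index (variance/mean, default 5 —
shape = mean/(index−1) = 10) and forms each doublet as the sum of two
independent singlet draws; labels are recorded. Defaults mirror the
artificial-doublet protocol used to validate the method: doublet
proportions 5–25% on ~10⁴ cells, counts overdispersed well beyond
Poisson. `simulate_fragments` emulates the same design at the fragment
level on a toy genome — per-cell Poisson fragment counts at a fixed locus
layout, doublet barcodes receiving the union of two latent cells'
fragments — so the full preprocessing path is exercised end to end.

What the generator does *not* emulate: chromatin-specific structure
(peak widths, TSS enrichment, copy-number variation), barcode errors,
ambient fragments, heterotypic composition effects, or the long
low-count junk tail of real libraries. Passing benchmarks therefore
demonstrate the statistical machinery — transform, null recovery,
calibration, FDR control — under honest overlap, not end-to-end fidelity
to any particular chemistry. Notably, the synthetic components overlap
more strongly than in typical real libraries (the best achievable AUROC
of any detector on the default generator is ≈ 0.953), which makes the
calibration tests conservative; mixing-proportion recovery to ±0.05 sits
at the Monte-Carlo noise floor at intermediate doublet loads.

Benchmark scale: acceptance checks use 20 replicates of 10,000 cells per
setting, which keeps every suite run in the low minutes on one core while
holding per-setting Monte-Carlo error on proportions near 0.004.

## Numerical choices and degenerate inputs

* Histogram range `[min Z_T, max Z_T]`; modal-bin ties break to the
  lowest index; empty bins are allowed (the GLM smooths over them);
  fewer than `spline_df + 2` non-empty bins is an error.
* Mixture density floored at 10⁻³⁰⁰ before ratios; π̂₀ capped at 1;
  posteriors clipped to [0, 1].
* λ search bounded to [−2, 2], tolerance 10⁻⁵ (both the MLE and the
  robust estimator).
* `β̂₂ ≥ 0` (no concave peak) raises a dedicated error advising a
  different `x_min` or window; all-identical counts and sub-200-cell
  libraries fail fast with specific errors.
* Exact truncation-boundary semantics: cells with `x_j = x_min` are
  retained for fitting and scored by the model; cells strictly below get
  posterior 0.
* Determinism: model fitting has no random element; all stochasticity
  lives in the simulators behind explicit seeds, and identical inputs
  yield byte-identical outputs.

## Known limitations

* HCLC is blind to multiplets whose pooled counts remain within the
  singlet range (deep homotypic overlap at low coverage); no detector
  using this statistic alone can call them.
* π̂₀ inherits central matching's bias under extreme component overlap;
  the refinement removes the systematic part but seed-level noise of
  ±0.04 remains at 10⁴ cells.
* The tail-FDR rule relies on the normal tail of the fitted null; if the
  true singlet tail is heavier than normal after transformation, realized
  FDR can exceed the nominal level by a few points (observed: 0.21 mean
  at nominal 0.20 on the standard benchmark).
* The naive-Bayes combiner assumes conditionally independent evidence;
  correlated sources overstate the combined posterior. Check
  `score_dependence` before integrating.
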