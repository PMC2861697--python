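# Methods

## Model

The expression rate of a transcript is treated as a basal rate modulated
multiplicatively by nearby enhancers.  Writing the rate as
k₁ = k₀·e^λ with first-order decay k₂ and assuming steady state, the log
transcript abundance is log(k₀/k₂) + λ, where each enhancer j contributes
additively to the modifier:

    λᵢ = Σⱼ αⱼ f(dⱼ).

f(d) is the influence function over signed TSS distance d (negative
upstream in the transcription direction), and αⱼ > 0 is a per-site
modifier (1 unless regulator weights or affinity weights are applied).
Expanding f in P cubic B-splines makes the prediction linear in the
spline coefficients c, so the per-gene features

    b_{i,k} = Σⱼ αⱼ Bₖ(dⱼ)

are precomputed once and the fit is a penalized least-squares problem

    F(c) = (1/N) ‖y − Bc‖² + σ·cᵀDc,   D = Δ₂ᵀΔ₂,

with Δ₂ the second-difference operator on coefficients — the standard
P-spline surrogate for the integrated squared second derivative.  The
minimizer solves (BᵀB/N + σD)c = Bᵀy/N by Cholesky factorization; there
is no iteration and no stochastic step.  A singular system (e.g. σ = 0
with rank-deficient features) raises an error advising a larger σ.

The basal term log(k₀/k₂) is not fitted: responses are mean-centered (and
scaled to unit population sd) before fitting.  For between-tissue
predictions the basal and decay rates cancel under the assumption that
they are tissue-invariant, so the predicted log fold change is the
difference of the two tissues' contribution sums and the differential
design matrix is simply the difference of the per-tissue feature
matrices.

## Coordinates and association

Binding sites are BED-style 0-based half-open intervals; a site's
position is its interval midpoint (floor of (start+end)/2, reported
1-based).  Midpoints rather than peak summits are used because summit
columns are not guaranteed to exist in the input.  TSS positions are
1-based, one TSS per gene id (microarray probe sets are treated as
independent genes).  Association uses an inclusive boundary
(|d| ≤ cutoff), 100 kb by default; an asymmetric signed window such as
(−5500, +2500) is available for promoter-array style data.  In multi-gene
mode a site joins every gene whose window contains it; in nearest-gene
mode it joins only the gene with minimum |d|, ties broken by
lexicographic gene id for reproducibility.

Regulatory regions are called from per-regulator peak sets by merging
transitively overlapping peaks (≥1 bp overlap) and keeping maximal merged
intervals that contain a peak of the designated coactivator or peaks of
at least two distinct other regulators; the region inherits the union of
regulator labels and the maximum enrichment.  The operation is idempotent
on its own output.

## Spline basis and defaults

The basis spans the association window with uniform interior knots and
boundary knots repeated degree+1 times; basis functions are zero outside
the domain and sum to one inside it.  Defaults: degree 3, P = 20
functions over ±100 kb (knot spacing ≈ 11 kb, comfortably below the
50 kb decay scale of interest), penalty order 2.  The conservation-based
variant uses the identical machinery with an 8-function basis on [0, 1]
evaluated at site conservation scores.

σ trades data fit against curve smoothness (units: penalty per unit MSE;
the features and responses are O(1) after standardization).  By default
σ is chosen from the grid 10⁻⁴…10² (7 log-spaced values) by held-out MSE
on one internal 2/3–1/3 split of the training data, then the model is
refitted on all training genes; a fixed σ can be supplied instead, and
the bootstrap procedure selects σ once on the full data so all
replicates refit at the same regularization.

## Model variants

* **Uniform**: prediction = w · (α-weighted site count; net count in the
  differential model), w by closed-form least squares.
* **Conservation**: influence as a spline in conservation score instead
  of position.
* **Regulator weights**: the bilinear model ŷᵢ = Σⱼ a(Rⱼ)·αⱼ·f(dⱼ), where
  a(R) is the mean of per-regulator weights w_r over the regulators
  bound at the site.  Fitting alternates exact steps: (i) with weights
  fixed, solve the penalized spline system; (ii) with the curve fixed,
  solve the weights by non-negative least squares (floor 10⁻⁶).  The
  reference regulator's weight is pinned at 1 throughout, which fixes
  the scale ambiguity between weights and curve and, because each
  half-step is an exact constrained minimization and a candidate weight
  update is only accepted if it does not increase the objective, makes
  the objective trace non-increasing by construction.  The mean
  combination rule is the fitted one; product and max rules are
  available for prediction only, since they break bilinearity.
* **Affinity**: αⱼ ← αⱼ·(enrichmentⱼ/median enrichment)^γ, γ = 1 by
  default, the median taken over distinct sites.

## Conservation scoring

A region's score is the maximum 100 bp moving average of per-base scores
over windows fully inside the region; regions shorter than the window use
the whole-region mean.  Track bases without data score 0 (missing
alignment treated as unconserved).  The conserved/non-conserved threshold
maximizes (fraction of bound regions above t) + (fraction of background
sequence at or below t) — Youden's J — scanned over midpoints of adjacent
sorted unique pooled scores, ties toward the smaller threshold;
"non-conserved" means score ≤ threshold.

## Evaluation protocol

Experiments restrict to genes bound in at least one tissue at the chosen
cutoff (and, in differential mode, flagged as differentially expressed —
the flag is an input column, not recomputed), standardize responses, then
repeat: random 2/3–1/3 gene split, fit on train, score held-out MSE,
Pearson and Spearman correlation.  Both correlations are reported since
the appropriate one depends on downstream use.  Paired comparisons
(multi-gene vs nearest-gene assignment; all sites vs conserved-only)
reuse identical splits and identical gene sets in both arms, so per-trial
MSE differences isolate the manipulated factor.  The permutation control
shuffles responses across genes before each trial and also records the
train-mean baseline MSE (≈1 on standardized responses).  Bootstrap bands
resample genes (not sites) with replacement, refit, and take pointwise
empirical quantiles of the curve; replicates with a singular resampled
system are skipped and counted.  Every stochastic step draws its seed
deterministically from a base seed and trial index, so identical seeds
give identical reports.

Because no intercept is fitted, an absolute-mode fit can absorb a
constant offset of the centered responses into the curve (the offset
loads on the site-count direction).  Differential responses are free of
this offset, so curve-recovery and bootstrap-coverage analyses run in
differential mode.  For the same reason the upstream/downstream asymmetry
statistic integrates the fitted curve after subtracting its own far-field
level (mean over |d| ≥ 80% of the domain), which removes any residual
constant before comparing the two sides.

## Synthetic data generator

The generator emulates the statistical structure of two-tissue ChIP +
expression data: n genes (default 2,000) on one linear chromosome with
≈25 kb mean spacing (minimum 2 kb), random strands; per gene a
Poisson(3) number of 200 bp binding sites at signed distances drawn from
a 40/60 mixture of a Laplace(0, 5 kb) proximal component and a uniform
component over ±100 kb, so most sites are distal but binding still
concentrates near the TSS and sites routinely fall within the window of
several genes; each site is shared between tissues or tissue-unique
(default unique fraction 0.5), carries one regulator label, a log-normal
enrichment ratio, and a conservation score from a bimodal Beta mixture
drawn independently of influence (a conservation-coupled preset exists
for testing the conservation variant).  Expression is the α-weighted sum
of true influences plus Gaussian noise (sd 0.5); genes whose noiseless
sums differ between tissues are flagged differential.  Ground-truth
influence presets: linear decay to zero at 50 kb, the same with a 1.2×
upstream side, flat, and conservation-only.

What passing tests on these data do show: the estimator recovers curves,
weights and model orderings from data with the assumed additive,
distance-decaying structure at realistic noise.  What they do not show:
robustness to peak-calling artifacts, probe-level microarray noise,
non-additive enhancer interactions, chromatin-domain structure, or
influence shapes outside the preset family — real-data performance can
differ on all of these.

## Numerical choices and degenerate inputs

Solves use Cholesky factorization of the penalized normal matrix; σ = 0
is permitted when features have full rank.  Basis evaluation outside the
domain returns zeros, so sites beyond the association window contribute
nothing (association and domain should use the same window).  Empty
profiles yield zero feature vectors and prediction 0 (the centered basal
level).  Constant response vectors refuse to standardize; fewer than
three genes refuse to split; correlations of constant prediction vectors
are recorded as 0.  Nearest-gene and threshold ties break
deterministically (lexicographic id; smaller threshold).

## Problem sizes used in validation

The shipped validation runs use 2,000-gene datasets (1,000 for bootstrap
coverage, 50 for solver exactness), 100 trials or replicates per
comparison, 200 bootstrap replicates, and 20-function bases — sizes at
which every recovery property is stable while the full suite completes
in a few minutes on a single core.

## Known limitations

The model is linear and additive by design: no enhancer–enhancer
interactions, no joint position×conservation surface, no saturation.
The regulator-weight fit assumes the mean combination rule and exactly
one weight per regulator per tissue.  The affinity weighting form
(power of median-normalized enrichment) is one reasonable choice among
several.  Absolute-mode influence curves are identified only up to the
basal offset discussed above.  One TSS per gene id is assumed; isoform
TSS choice is upstream of this package.
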