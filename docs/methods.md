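# Methods

## The model

`expsup` implements a forward model of expectation suppression: the
attenuation of visual responses to expected compared with unexpected
stimuli. The question the machinery addresses is which *neural-level*
modulation underlies the attenuation observed at the *voxel* level —
dampening (suppression of neurons tuned toward the expected stimulus),
sharpening (suppression of neurons tuned away from it), an unspecific gain
reduction, or a narrowing of tuning curves.

### Neural response spaces

Each region of interest is modeled as a 1-D feature space carrying eight
feature-tuned neural populations:

* **Circular space** (orientation, early visual cortex): the space is
  [0, π) with wrap-around distance d = min(|Δ|, π − |Δ|), maximum π/2.
  Population i responds with a circular normal (von Mises) on the doubled
  angle,

      g(x; μ_i, σ) = exp[(cos 2d(x, μ_i) − 1) / σ],

  i.e. concentration κ = 1/σ. The grid's width parameter σ therefore plays
  the role of a *squared* width (small-angle expansion: g ≈ exp(−2d²/σ)).
  This convention — rather than the textbook κ = 1/σ² — is deliberate: it is
  the convention under which the full parameter grid reproduces the
  plausibility-rejection rates the package validates against (see *Response
  requirements* below and the acceptance tests), which are extremely sensitive to the effective
  tuning width at both ends of the σ range. Under κ = 1/σ² every σ ≥ 3
  fails the selectivity requirement and every σ ≤ 0.2 fails the coverage
  requirement, which is incompatible with those per-family rates.
* **Linear spaces** (shape complexity, semantic similarity): Gaussians with
  standard deviation σ, eight means spanning [0, π] inclusive. Because
  summed responses sag at the boundaries, the space is clipped to the
  region where the summed response is ≥ 95% of its maximum; stimuli are
  only placed inside the clip. The clip bounds are the *outermost*
  threshold crossings; for very narrow tuning the interior of that interval
  can still dip between the means, which is exactly what the coverage
  requirement (below) is meant to reject.

Every population's peak is normalized to 1; the summed response is
normalized by its maximum over the clipped region.

### Expectation modulation

Six models = {gain, tuning} × {local, remote, global}. The suppression
factor at feature distance d from the expected stimulus is

    local:  c = min(1, a + |d/b| (1 − a))
    remote: c = max(a, 1 − |d/b| (1 − a))
    global: c = a

with a ∈ (0, 1] the suppression magnitude (a = 1: no modulation) and b > 0
the distance scale. Gain models multiply each population's response by c;
tuning models recompute the response with width c·σ, leaving the peak
untouched. The modulation is applied only when the expected stimulus
actually appears (a top-down modulation conditional on the expectation
being fulfilled); unexpected trials always use the unmodulated bank.

Note an asymmetry in these formulas: as b → ∞ the local factor
converges uniformly to the global factor a (sup-norm gap ≤ d_max/b·(1−a)),
but the remote factor converges to 1 (no modulation), not to a. The
formulas are implemented exactly as written.

### Parameter grid

Defaults: a from 0.05 to 1.00 in steps of 0.05 (20 values); b from 0.1 to
2.3 in steps of 0.1 (23 values, dropped for global models); σ in
{0.1 … 1.0 step 0.1, 1.5 … 4.0 step 0.5, 5.0} (17 values), for 17·20·23 =
7820 combinations per local/remote family. The uneven σ list realizes
exactly that grid size while spanning 0.1-5. All three lists are
configurable.

### Response requirements (biological plausibility)

Three criteria reject implausible parameterizations; all are evaluated on
the discretized feature grid (resolution round(180π) = 565 points):

1. **Coverage** — the unmodulated summed response must stay ≥ 75% of its
   maximum everywhere a stimulus can be placed (no blind spots).
2. **Modulated minimum** — for every candidate expected position on the
   *full* grid (including outside the clip: an expectation is a state, not
   a placed stimulus), the modulated summed response must stay ≥ 10% of the
   unmodulated maximum at every placeable probe position.
3. **Selectivity** — no population may respond above 75% of its peak at
   distance π/2 from its mean.

The bulk sweep exploits that the minimum modulated response is
nondecreasing in a (both suppression branches increase with a, and response
curves increase pointwise with width), so the criterion-2 failure set is a
prefix of the sorted a values, found by bisection per (σ, b). A test
cross-checks the fast path against exhaustive per-point evaluation.

## From neurons to voxels

Each voxel pools eight population indices drawn uniformly with replacement
(biased sampling); its response is the mean of the sampled populations'
responses, keeping the scale independent of the pool size. Responses are
multiplied by a gain of 100 so that the noise calibration's "SD step of 1"
is meaningful (≈1% of the maximal clean response).

Noise is iid Gaussian per trial × voxel, calibrated separately per
(ROI, σ): starting from SD 0, localizer-style data are simulated and
decoded with a stratified 4-fold cross-validated linear classifier
(closed-form LDA by default; multinomial logistic regression and linear SVM
are config options), the SD advancing in steps of 1 until accuracy falls
below the target; the SD whose accuracy was closest to the target wins.
The default target accuracy is 0.5 for a 6-way problem — a mid-range fMRI
object-decoding level, far above chance (0.167) and far below ceiling.
Localizer runs receive half the calibrated SD, mirroring their higher SNR.
Modulation parameters a, b never enter the calibration.

## Study designs and synthetic data

Two probabilistic-association designs are built in: 6 leading × 6 trailing
images at 50% reliability over 240 trials (expected image five times more
likely than each unexpected one), and 8 × 8 at 9/16 = 56.25% reliability
over the 456 analyzed non-oddball trials (oddballs are not simulated).
Leading images are balanced exactly by round-robin before shuffling;
trailing images are drawn from the leading image's transition-matrix row.
Localizer runs present each trailing stimulus 12 times, expectation-free;
the repetition count is a package default, not a derived quantity.

Synthetic stimuli are stratified-uniform positions on the unit interval,
mapped into the stimulus-placeable range of each response bank (linear
feature axes are only meaningful up to affine rescaling, so placement
inside the σ-dependent clip is a rescaling, not a distortion). Optional toy
images accompany the positions: oriented gratings for the circular space,
star-like silhouettes with increasing protrusion count for linear spaces,
so the feature-extraction path can be tested end to end against its own
generator.

Ground-truth datasets (the recovery oracle) simulate a known modulation
model for a cohort of participants. Seeding is counter-based
(SeedSequence over [master, participant, repetition, stream]), so any
single participant or repetition is reproducible in isolation.

What the generator does *not* emulate: spatially correlated noise,
hemodynamics, attention or adaptation confounds, oddball trials, and
behavioral responses. Passing tests therefore demonstrate the internal
consistency and identifiability of the analysis pipeline under
well-behaved noise, not its robustness to those real-data complications.

## Outcome metrics

Seven metrics, identical for simulated and empirical data (trials ×
voxels + localizer):

* **MAM** — mean amplitude modulation, mean(unexpected) − mean(expected).
  Condition means are stimulus-balanced (average per trailing stimulus
  first): the two conditions sample trailing stimuli unequally by design,
  and without balancing that composition difference masquerades as an
  amplitude effect even for a null model.
* **WC/BC** — within-/between-class correlations between z-scored
  localizer patterns and z-scored condition-mean task patterns (the
  localizer anchor avoids the bias that leading-image bleed-over would
  induce in within-task correlations).
* **CP** — classification performance, literally BC − WC (the `cp_sign`
  flag flips it for comparison with accuracy-style conventions where
  higher = more discriminable).
* **AMA / AMS** — voxel-wise suppression binned (10 equal-count bins,
  remainders to the lower bins) by localizer amplitude / selectivity;
  summarized by the OLS slope over bin rank. Selectivity is the OLS slope
  of a voxel's localizer response on the within-voxel amplitude rank of the
  images; flat voxels get selectivity 0 and are retained.
* **IP** — within-voxel suppression per localizer preference rank,
  averaged over voxels; slope oriented so positive = more suppression for
  more preferred images.

Slope conventions for sign matching: two-condition metrics use expected −
unexpected (MAM uses unexpected − expected so that suppression is
positive). Sign matching operates on these raw slopes; the weighted MSE on
normalized slopes (see below). The split is deliberate: normalizing CP by
its (typically negative) unmodulated value flips its sign, which would make
"sign of the slope" convention-dependent.

## Model comparison

Normalization: MAM/WC/BC/CP slopes divide by the metric's unmodulated
(unexpected) value; ranked-metric slopes divide by the mean unmodulated
amplitude. Normalized slopes are scale-invariant.

For each (family, grid point): the simulated cohort-mean normalized slope
is compared to the empirical group mean per metric; squared errors are
scaled by their grand median across all families and plausible grid points
(so every metric contributes comparably); the weighted mean uses weights ∝
|mean|/SD of the empirical metric across participants (discounting
unreliable metrics), normalized to sum 1. Bootstrap CIs resample simulated
participants before the cohort mean. Comparing cohort means (rather than
averaging per-participant squared errors) removes a variance floor that
would otherwise be shared by all grid points and blur family differences.

Sign matching: a simulated metric matches if its slope distribution across
simulated participants is significantly nonzero (two-sided one-sample
t-test, α = 0.05) and its mean's sign equals the empirical sign.

Fidelity requirement learned the hard way: the fitting simulations must
present the *same stimuli on the same trial sequences* as the
(pseudo-)empirical data; only voxel compositions and noise draws are
resampled. Re-drawing stimuli or sequences adds cross-cohort variance that
visibly breaks recovery of near-degenerate families (remote gain vs
global gain, global tuning vs remote tuning).

## Problem sizes and presets

The `desk_grid` preset (3 σ × 4 a × 4 b = 216 family-points) with 10–20
participants × 1–2 repetitions and 200 voxels runs a full fit in tens of
seconds and is what the test suite and the recovery control use; the
`full_grid` preset is the full 7820-point grid. The recovery control uses
truth (a = 0.6, b = 0.5, σ = 0.5) with calibrated noise, a 20 × 2 cohort on
both the generating and fitting side, and five fixed seeds per family.
Larger cohorts shrink the MSE margins' noise roughly as 1/√n and only make
the control stricter.

## Numerical choices and edge cases

* Ties in the Gabor energy argmax, voxel-amplitude orderings and MSE
  rankings break deterministically (smallest angle / stable sort / family
  name then lexicographic parameters).
* A stimulus missing one expectation condition is skipped in WC/BC/IP for
  that condition; MAM/AMA/AMS balance over stimuli present in both.
* Zero-variance patterns raise errors naming the stimulus; constant rank
  vectors yield selectivity 0 rather than NaN.
* Metrics with a zero grand median are dropped from the MSE with a warning
  and the remaining weights renormalized.
* The a = 1 truth is reported as unidentifiable (all families coincide);
  a global-gain truth won by local gain at the grid's largest b is flagged
  as the large-b equivalence.
* End-to-end determinism: all randomness is pre-drawn from counter-derived
  seeds before the (optionally joblib-parallel) grid loop, so results are
  bit-identical for any worker count.

## Feature-space construction

* **Orientation**: quadrature-pair Gabor energy, orientations in 20° steps,
  eight spatial scales geometric between wavelength 4/√2 px and the image
  diagonal (reading the scale endpoints as wavelengths keeps the whole
  ladder below Nyquist; the cycles-per-image reading aliases), summed over
  the image, averaged over scales; argmax orientation. 0 = horizontal,
  counter-clockwise, period π.
* **Shape complexity**: six silhouette metrics (concavity count ≥ 5 px
  area, concavity area, convex-hull area and perimeter, minimum enclosing
  circle area, silhouette/circle ratio), column-standardized, first
  principal component, sign fixed so more concavities = higher score.
* **Similarity axis**: classical (Torgerson) MDS, first coordinate, via
  eigendecomposition — deterministic, unlike SMACOF-style iterative MDS.
* **RSA**: neural RDM = 1 − Pearson r of z-scored patterns; partial
  Spearman = Pearson on rank-transformed, control-residualized lower
  triangles; group inference by t-test on Fisher-z values. Feature spaces
  are compared with Spearman ρ, a joint bootstrap over stimuli (10 000
  resamples) and a Mantel row/column permutation test (10 000 permutations;
  the permutation count is a package default).

## Known limitations

* The plausibility-criterion reading (expected positions on the full grid,
  probes within the clip) was selected as the unique reading consistent
  with the validated rejection rates; other readings differ by a few
  percentage points in the remote families.
* The weighted MSE inherits the grid search's limitations: no interpolation
  between grid points and no gradient-based refinement.
* Identifiability degrades as a → 1 and, in linear spaces, between local
  gain and local tuning; the recovery control quantifies but does not
  remove this.
* Empirical-data ingestion expects trial-wise pattern CSVs; no GLM fitting
  from BOLD time series is included.
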