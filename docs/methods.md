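# Methods

## Scope and model

`dscout` analyzes multiplex real-time digital PCR (dPCR) data for
circulating-tumor-cell (CTC) biomarker panels. A chip partitions each
reaction over ~20,000 microwells; every well is imaged at every thermal
cycle in three dye channels (FAM, VIC, CY5) and two chip regions (protein
via immuno-PCR oligo tags, mRNA via RT-PCR), yielding six markers: EpCAM,
GPC-3 and ASGPR proteins and EpCAM, GPC-3 and PD-L1 mRNAs. The package
covers the computational chain from per-well fluorescence traces to
clinical-style scores:

1. per-well amplification-curve fitting and positive/negative calling;
2. Poisson absolute quantification from partition counts;
3. assay analytics (LOB, probit LOD, %CV, standard curves, efficiency);
4. a six-marker composite Z-score with AHP weighting and ROC diagnostics;
5. 2D protein-mRNA profiling (ASGPR calibration, P1/P2 regions, efficacy
   vectors).

A synthetic-data module generates plates, dilution series and cohorts with
known ground truth; every downstream claim in the test suite is checked
against that truth or a closed form.

## Trace model and well calling

Each well x channel trace is modeled as a four-parameter logistic on a
drifting baseline:

    F(c) = F0 + drift*c + A / (1 + exp(-k (c - c50))) + eps,   eps ~ N(0, sigma)

Closed forms used throughout: the threshold-crossing cycle at fraction f of
the amplitude is `Ct = c50 - ln(1/f - 1)/k` (default f = 0.1), and the
maximum slope of the amplitude-normalized logistic is `k/4`, which we take
as the *normalized fluorescence growth rate*. These two identities connect
the simulator (which draws Ct and growth rate per channel and back-solves
c50 and k) with the caller (which fits the curve and recovers them), so
each is the other's oracle.

A well is called positive only if **all** of the following hold
(inclusive comparisons; every failed criterion is named in the output):

| criterion | default | rationale |
| --- | --- | --- |
| fit converged | — | non-convergent fits are negatives, never errors |
| r^2 of fit | >= 0.98 | curve must look like amplification, not noise |
| amplitude A | >= 5 x baseline noise sd | signal must clear the well's own noise |
| Ct window | [10, 38] cycles | rejects immediate jumps and end-of-run creep |
| normalized growth rate | >= mean/4 per channel (0.0975 / 0.165 / 0.0625) | rejects slow nonspecific drift-up |

The per-well baseline noise sd comes from the residuals of a linear fit to
the first 8 cycles. The growth-rate floor is deliberately set at a quarter
of each channel's nominal mean rate (channel means 0.39, 0.66, 0.25 per
cycle): with the observed channel spreads (sd 0.07-0.15) a floor at half
the mean would reject 1-4% of genuine positives on the rate criterion
alone, which is incompatible with the >= 99% per-well sensitivity the
caller is designed to (and in tests does) deliver. All thresholds are
configurable in `CallCriteria`.

**Fitting operates on the raw trace.** The centered moving-average
smoother (window 5, symmetric shrinking windows at the edges, so linear
signals are exact fixed points) is used for candidate screening,
initialization and display only: least-squares fitting a logistic to a
boxcar-smoothed logistic biases k low (the boxcar flattens the sigmoid;
for k ~ 1.6 and window 5 the max slope roughly halves), which would shift
every Ct late by over a cycle. The least-squares fit itself is the
noise-handling step.

**Candidate pre-screen.** Fitting all ~10^5 wells of a plate would be
wasteful; wells that cannot pass the amplitude criterion are classified
negative (reason `amplitude`) from a vectorized screen: the peak of the
smoothed trace above a full-trace linear fit must reach 1/4 of the
amplitude floor *and* the first-to-last-cycles rise must reach 1/2 of the
floor (or the peak the full floor, admitting late risers). Screen
thresholds use the plate-median noise sd — the per-well estimate has ~6
degrees of freedom and its low tail would leak thousands of noise wells
into the fit. For baseline-only wells the joint chance of passing is
< 1e-4; a sigmoid at the amplitude floor leaves a residual peak of ~0.4 A
and a rise of ~A, far above both screens. Wells within ~2x of the
amplitude floor are the only regime where the screen and the criterion
could disagree, and such wells receive the full fit whenever their
residual peak clears the screen.

## Poisson quantification

With M positive of N wells, copies per reaction are `X = -N ln(1 - M/N)`
(the occupancy inversion; for saturated plates M = N the transform
diverges and X is reported at M - 0.5 with a `saturated` flag). The 95%
interval is the Wilson score interval on p = M/N mapped through the same
monotone transform. Copies are reported per reaction; conversion to
copies per mL of blood depends on the lysate dilution scheme and is left
to the caller as a multiplier.

## Assay analytics

* **LOB** — nonparametric percentile of blank replicates: rank
  r = 0.5 + p*n with linear interpolation between order statistics,
  clipped to the observed range (the CLSI-style convention; blanks 1..12
  at p = 0.95 give rank 11.9 and LOB 11.9).
* **LOD** — binomial GLM with probit link on log10(concentration)
  (statsmodels); LOD = 10^((Phi^-1(0.95) - a)/b). All-detected tables
  have no information about the slope: the lowest tested concentration is
  returned flagged non-converged, as is any non-positive slope.
* **%CV** — 100 x sample sd (n-1) / mean.
* **Efficiency** — from the Ct vs log10(conc) slope,
  (10^(-1/slope) - 1) x 100; the series must span >= 2 logs.
* **2^-ddCt** — included only as a comparison utility for relative
  quantification against the absolute digital counts.

## Scoring

Copies are transformed log2(x+1), standardized per marker against a
reference population (default: the whole analyzed batch, matching how
heatmaps are standardized; a healthy-only reference is available for
diagnostic scoring and is recorded in the output metadata), and combined
as `score = sum_j w_j z_j`. Weights come from the Analytic Hierarchy
Process: principal right eigenvector of a reciprocal pairwise-comparison
matrix (power iteration, tolerance 1e-10), consistency index
(lambda_max - n)/(n - 1), consistency ratio against Saaty's random
indices, with CR > 0.1 rejected unless explicitly allowed. The package
ships no opinion about the six markers' relative importance: the default
comparison matrix is all ones (equal weights); user matrices are supplied
as JSON.

ROC analysis uses the rank (Mann-Whitney) AUC with half-credit for ties;
the operating point maximizes Youden's J with ties broken toward higher
specificity (a deliberate convention, tested). Logistic combination of
markers uses a small L2 ridge (1e-6) so maximum likelihood stays finite
under perfect separation, which is flagged.

## 2D profiling

Since the number of captured CTCs varies per sample, each marker's copies
are divided by (ASGPR protein copies + 1): ASGPR is a liver-lineage
surface marker carried by the captured cells, so the ratio approximates a
per-cell expression level. The pseudocount keeps blank samples finite and
reduces to the raw copies when ASGPR is absent. This ratio form is our
interpretation of the calibration (configurable); classification and
efficacy vectors operate in calibrated *linear* space — display may log
the axes but analysis never does, keeping displacement vectors
interpretable.

The P1/P2 boundary is a standardized-feature SVC (poly kernel, degree 3,
C = 1, coef0 = 1 so the kernel keeps its lower-order terms — unstated
upstream, fixed here and exposed in config) or a
Gaussian naive Bayes baseline ("GSNB"); P1 is defined as the side of the
boundary containing the healthy-cohort centroid. The classifier sees
symlog-compressed coordinates, `sign(v) log1p(|v|)`: copy ratios are
heavy-tailed, and on the raw linear scale the tail dominates the feature
standardization, compressing the healthy cluster until margin-based
classifiers collapse to the majority class. The transform is monotone
per axis, so the induced P1/P2 regions remain contiguous in the original
plane; it applies to classification only — efficacy vectors stay in
calibrated linear space — and can be disabled (`symlog=False`). Accuracy, precision,
recall and F1 are reported from stratified 5-fold cross-validation
(k reduced with a warning for tiny classes). Efficacy vectors are
post-minus-pre displacements with Euclidean magnitude and angle in
[0, 360); the zero vector's angle is undefined (NaN). Spearman
correlation is the Pearson correlation of midranks with a seeded
permutation p-value (9999 permutations by default).

## Synthetic data: what it emulates, and what it does not

The plate generator places `round(lambda)` molecules into N wells by a
multinomial throw (exact template conservation, per-well occupancy
approximately Poisson(lambda/N)); occupied wells get logistic traces with
channel-drawn Ct ~ N(26.83, 0.88), N(26.46, 0.86), N(25.73, 1.21) cycles
and normalized growth rates ~ N(0.39, 0.07), N(0.66, 0.15), N(0.25, 0.07)
per cycle for FAM/VIC/CY5 — the channel statistics reported for this
assay class — with amplitude 1.0 +/- 0.05 (normalized units), baseline
0.1, drift 0.001/cycle and i.i.d. Gaussian noise sd 0.02 (chosen as a
clean-instrument regime; all configurable). Cohorts draw per-marker
copies from log-normals with zero-inflation to blank-level Poisson
backgrounds (protein blanks ~100-190 copies, mRNA blanks ~5-9 copies,
mirroring typical no-template levels of the two analyte classes); the
default cohort sizes (24 healthy / 31 early / 22 intermediate-advanced)
mirror the clinical arms this pipeline targets. A separate binormal
cohort generator produces data whose equal-weight composite score has an
analytically known AUC, used to validate the scoring chain.

Not modeled (hence not demonstrated by passing tests): partition-volume
variability, cross-channel spectral bleed-through, amplification
competition between targets in a well, optical/image artifacts, and any
biological covariance structure between the six markers beyond the
latent-severity construction. Real instrument data will stress exactly
these; the calling criteria are configurable for that reason.

## Numerical choices and degenerate inputs

* Fit initialization is data-driven (F0 = min, A = range, c50 = steepest
  smoothed rise, k from the observed max slope via k = 4 slope/A, clamped
  to [0.2, 8]); Levenberg-Marquardt with analytic Jacobian, maxfev 400.
  Failures and A < 0 or k <= 0 are reported as non-converged with A = 0
  and classify as negative.
* Ties at any calling threshold count as positive (>= comparisons).
* Z-scoring a marker that is constant in the reference returns zeros plus
  a recorded warning rather than NaNs.
* Every generator and every pipeline stage is a pure function of
  (parameters, seed); the run manifest hashes config and outputs and
  carries no wall-clock timestamps, so a rerun is byte-identical.
* Problem sizes in the acceptance checks — 200 simulations per occupancy
  level, one full 20,000-well three-channel plate, 50 plates for template
  recovery, 10,000-replicate dilution rows, 500 samples per class for the
  AUC check — were chosen to make each statistical tolerance a >= 3-sigma
  margin under the generator's own variability.

## Known limitations

* The calling thresholds are declared defaults, not instrument-calibrated
  values; on real data they should be tuned against control wells.
* The Wilson-propagated interval ignores the (slightly sub-binomial)
  dependence of multinomial occupancy counts; coverage is conservative in
  that direction.
* The probit LOD treats replicates as independent Bernoulli trials;
  day/operator effects are out of scope.
* AHP weighting reproduces whatever judgment matrix it is given; with the
  neutral default it reduces to equal weights.
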