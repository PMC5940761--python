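# Methods

This note records the models, conventions and design decisions behind
`texturesurv`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Lesion images and the exclusion rule

A lesion is a 2-D integer image of stored CT intensities (`stored = HU +
1024`, so the clinically relevant range is non-negative and fits 16-bit PNG)
with a boolean polygonal ROI mask. Air and fat have negative attenuation;
pixels below 0 HU (stored < 1024) are removed from the ROI *once*, on the
unfiltered image, and the refined mask is reused at every filter scale. We
treat the exclusion as an ROI-drawing correction rather than a per-filter
step: the anatomical identity of a pixel (fat/air vs tumor) does not depend
on the band-pass scale. An ROI left empty by the rule raises
`NoAnalyzablePixelsError`.

## Laplacian-of-Gaussian filtering

The LoG kernel is the closed-form expression

∇²G(x, y) = (x² + y² − 2σ²)/(2πσ⁶) · exp(−(x² + y²)/2σ²)

sampled on the integer grid and truncated at 4σ (configurable). Truncation
leaves a small negative DC sum (≈ −1.4×10⁻⁴ at σ = 1; relative to the L1
norm, well under 10⁻³ at every standard scale); we subtract `sum/size`
uniformly so the applied kernel has *exactly* zero DC gain. Consequences:
a constant image has identically zero response, and total intensity is
conserved away from borders. Border handling is reflect padding.

Two output modes exist because the filtered-histogram convention is
genuinely ambiguous in this literature:

* `response` — the pure zero-mean LoG response (fine-scale structure at
  small σ);
* `band-plus-dc` (default) — `input + response`, which retains the DC level
  so the in-ROI "average" stays near its unfiltered value at every scale.
  This matches reported filtered averages that remain on the ~1085 stored
  scale, impossible for a zero-mean response.

Filter scales are restricted to σ ∈ {0, 1, 1.5, 2, 2.5} px (σ = 0 = identity)
unless explicitly overridden; the descriptive "filter width in pixels" labels
sometimes attached to these σ values are not exactly proportional to σ and
are treated as labels only.

## Texture features

Histogram features use population (biased) moments; kurtosis is *excess*
kurtosis (Gaussian ⇒ 0, matching the near-zero values typical of CT lesion
histograms). A constant sample returns SD = 0 and skewness = kurtosis = 0 by
convention. Moments are computed on standardized residuals to avoid
overflow/underflow at extreme scales.

The GLCM pools ordered pixel pairs over four distance-1 offsets
{E, S, SE, SW}, symmetrized by adding transposed counts, and normalizes to
probabilities — standard Haralick practice when no convention is stated.
Quantization default is `raw-integer` (rounded stored values used directly as
gray levels, the matrix stored densely over *observed* levels only);
`fixed-bins(k)` rescaling is available. Raw-integer was chosen because
reported contrast magnitudes (hundreds, on averages ≈ 1088 with SDs of
10–30) are consistent with un-rebinned 12-bit-scale values rather than
coarse binning. Contrast and correlation weight cells by actual gray-level
values; ASM and entropy are level-free. Entropy is log₂ (bits) by default
with a natural-log option; σxσy = 0 ⇒ correlation = 0 by convention.
Absolute GLCM feature scales are *not* comparable across software packages
(binning and normalization conventions differ); the package asserts
internal-consistency properties, oracle equivalence and qualitative
patterns, not literature table values.

## Synthetic cohort generator

What it emulates: a resected pancreatic-head-cancer cohort in which texture
carries prognostic signal. Defaults (all configurable through
`SyntheticConfig`):

| parameter | default | rationale |
|---|---|---|
| n_patients | 88 | reference cohort size |
| mean_hu / mean_hu_sd | 64 / 10 HU | stored averages ≈ 1088, between-group separations ~15 on that scale |
| sd_hu_range | (10, 30) HU | reported per-lesion SD scale |
| correlation_length | 1.5 px | CT-like spatial smoothness; free knob |
| roi_pixel_range, median | (164, 1685), 433 | reported ROI pixel statistics; log-normal, truncated |
| event_fraction_target | 0.795 | 70/88 recurrences |
| censoring_time_range | (3, 89) months | reported follow-up span; the censoring *mechanism* is unreported, so independent uniform is assumed |
| nodal_positive_prob | 49/88 | baseline-table prevalence |
| hazard_coefficients | average −0.5, sd −0.5, nodal log 2 | signs encode the low-attenuation/homogeneous → higher-hazard direction; magnitudes sized so dichotomized texture HRs land near the reported 0.5–0.6 and nodal near 2 |

The lesion substrate is white noise smoothed by a Gaussian kernel of width
`correlation_length`, z-scored over the whole image, scaled to the patient's
true heterogeneity and shifted to their true mean — so in-ROI sample moments
fluctuate around the truth as real measurements would. ROI masks are
rasterized random polygons (ellipse × radial wobble, iteratively rescaled to
the drawn pixel count, morphologically nudged into range). Survival times
come from an exponential (optionally Weibull) proportional-hazards model on
standardized true covariates; the baseline hazard is solved by root-finding
(Gauss–Legendre integration over the uniform censoring law) so the
*expected* event fraction equals the target. Identical config + seed
reproduces the cohort bit for bit; per-lesion seeds are spawned
deterministically from the cohort seed.

What it does **not** emulate: anatomy, contrast-phase enhancement, scanner
effects, 3-D structure, informative censoring, or correlation between
texture and the other clinical covariates. Passing tests therefore show the
*machinery* is correct and the effect directions are recoverable — not that
the effect sizes transfer to real patients.

## Cutoff dichotomization

Candidate thresholds are the observed feature values (not midpoints); the
boundary value belongs to the "≤" side. Both directions are scanned and ties
in the Youden index break toward higher specificity, then the larger cutoff,
then "≤" — purely so reporting is deterministic. LOOCV refits the cutoff on
each n−1 subset, assigns the held-out patient with that fold's cutoff, and
reports the modal cutoff (ties toward the cutoff closest to the full-data
one). Continuous cutoffs rarely repeat exactly; `round_decimals` optionally
coarsens before taking the mode. Folds whose training half is single-class
are skipped and logged.

No multiple-testing correction is applied across the many feature × scale
combinations — deliberately mirroring common practice in this literature —
so the univariate p-values are exploratory. See *Limitations*.

## Survival analysis

* 2×2 tables: Fisher's exact test (two-sided, point-probability rule) is the
  default — the variant whose p-values reproduce typical clinical baseline
  tables (it is the one consistent with the reference values we checked);
  Pearson and Yates chi-square are available, and error on zero margins.
* Mann–Whitney U: exact p when min(n) ≤ 8 without ties, tie-corrected normal
  approximation otherwise.
* Kaplan–Meier: lifelines' product-limit estimator. The restricted mean
  (area under the curve up to the largest observed time) is integrated
  exactly as a step function; its CI uses the standard Greenwood-based
  estimator variance Σᵢ Aᵢ² dᵢ/(nᵢ(nᵢ−dᵢ)) with a normal approximation.
  (The generic library routine returns the population variance of the
  restricted lifetime — a different quantity — via adaptive quadrature, so
  this small standard formula is implemented here and cross-checked against
  the library's point estimate.)
* Log-rank: standard two-group observed-minus-expected chi-square, 1 df.
* Cox: Newton–Raphson with step halving on the partial likelihood; Breslow
  tie handling by default (the behaviour of the classic clinical packages),
  Efron selectable. Convergence requires max |gradient| < 10⁻⁶; diverging
  coefficients (|β| > 20) raise a separation error, and stepwise selection
  flags and skips such variables. Wald CIs and p-values are reported.
* Stepwise: pure forward, no removal. Candidates must pass a univariate
  log-rank screen at the entry level (a Mann–Whitney screen on the
  continuous feature is selectable, since the reported methodology is
  ambiguous about which univariate test gates entry); each step adds the
  smallest likelihood-ratio p below `entry_p` (0.05). Texture covariates in
  the per-filter models are coded as the indicator of the *above-cutoff*
  group regardless of which side is high-risk, so hazard ratios are
  comparable across features (protective features then show HR < 1).

Months are days/30.4375 when dates are supplied. DFS = time from resection
to recurrence or death from any cause, censored at last follow-up.

## Problem sizes used by the test suite

Simulation-based checks use sizes chosen to make the asserted properties
statistically stable: Cox calibration uses 200 cohorts of n = 300 (bias
tolerance ±0.05 on a true log-HR of 0.7, coverage band 90–98%); the
direction-of-effect study uses 100 pipeline replicates of n = 300 at the
unfiltered scale; oracle-equivalence suites use hundreds of small random
instances with tolerances of 10⁻⁹ (exact arithmetic identities) or 10⁻⁶
(iterative fits).

## Limitations

* **Cutoff circularity.** The Youden cutoff is optimized against the
  recurrence label and the dichotomized variable is then tested against
  recurrence-driven survival. Under a null cohort this inflates the
  univariate log-rank and stepwise-entry type-I error far above nominal (the
  suite's optimism test quantifies the mechanism: mean J ≈ 0.12 for pure
  noise at n = 200). The outcome-blind LOOCV assignments reduce, and median
  splits avoid, this optimism; the pipeline reports both. Conclusions from
  the full-data cutoffs should be treated as exploratory.
* **Proxy competition among homogeneity features.** For a Gaussian random
  field, GLCM contrast is an almost deterministic function of the field SD
  and neighbor correlation, so `standard_deviation`, `contrast`, `asm` and
  `entropy` are strongly collinear proxies of the same generating
  heterogeneity. Forward selection then picks *one* of them first and the
  rest add little; which proxy is named in the final model fluctuates
  between replicates even when the underlying effect is fixed. Qualitative
  claims should therefore be read at the level of "a homogeneity feature",
  not a specific proxy.
* No proportional-hazards diagnostics, competing risks, overall-survival
  endpoint, 3-D texture, or multi-reader ROI variability.
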