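# Methods

This note documents the statistical model, the image-processing chain, the
synthetic-data generator and the numerical choices behind `nanomix`, in the
spirit of a model-description appendix.

## Mixture model and EM fitting

Particle sizes (area in nm² or width in nm) are modeled as i.i.d. draws
from a univariate K-component Gaussian mixture with weights wₖ ∈ (0,1]
summing to one, means μₖ and standard deviations σₖ > 0 (3K − 1 free
parameters). Fitting maximizes the log-likelihood by
Expectation-Maximization:

* **E-step** — posterior membership probabilities (responsibilities)
  γᵢₖ, computed in log space with log-sum-exp normalization. This matters
  at nm² magnitudes (values of order 10³, densities of order 10⁻³ per
  component) and for observations far from every component, where naive
  density ratios underflow.
* **M-step** — weighted-moment updates. The variance update uses the
  freshly updated component mean (the standard EM update); the weight
  update wₖ = Σᵢγᵢₖ/N sums to one by construction.
* **Convergence** — successive log-likelihoods agreeing to six decimal
  places, implemented as |ℓₜ − ℓₜ₋₁| < 10⁻⁶ (absolute), capped at 1000
  iterations. The per-iteration log-likelihood trace is retained; its
  monotone non-decrease (within 10⁻⁸) is the algorithm's central invariant
  and is asserted across the test suite.
* **Initialization and restarts** — the deterministic start places means on
  the (j − ½)/K data quantiles, sigmas at the pooled standard deviation and
  weights uniform; nine additional seeded restarts perturb that start
  (means jittered by a fraction of the pooled sd, sigmas log-jittered,
  weights Dirichlet-resampled) and the best final log-likelihood is kept.
  Restarts are run as one vectorized batch; the updates are algebraically
  identical to the single-start path.
* **Degeneracy guards** — mixture likelihoods are unbounded when a
  component collapses onto a single observation; sigmas are floored at
  10⁻⁶ × the data range. A responsibility column with numerically zero
  mass raises a component-collapse error; a fit only fails when every
  restart collapses. Components are always reported sorted by ascending
  mean, so permuting the initialization never changes the reported model.

## QQ diagnostics and model selection

The goodness-of-fit diagnostic plots the sorted observations against the
mixture quantiles at midpoint plotting positions pᵢ = (i − ½)/N (this
matches the "fraction of observations below a given value" definition of a
quantile evaluated at half-counts; the choice is conventional and
documented rather than derived). The mixture CDF is Σₖ wₖΦ((x−μₖ)/σₖ);
quantiles are obtained by bracketed root finding (Brent) to 10⁻⁹ of the
mixture scale. A least-squares line through the QQ pairs summarizes
linearity; a correctly specified model gives slope → 1, intercept → 0,
R² → 1, with the identity line as the perfect-fit reference.

Model complexity is chosen sequentially: fit K = 1, 2, … and accept K + 1
over the current choice only if it improves the log-likelihood by at least
2.0 **and** the QQ R² by at least 0.005; the first rejection stops the
walk. The thresholds operationalize a judgment call ("no longer
significantly improves"); they were calibrated once on the synthetic
presets — a log-likelihood gain of 2.0 is roughly what three superfluous
parameters gain by chance, and 0.005 in R² separates visible QQ curvature
from noise at N of a few hundred — and are exposed as parameters. Raising
either threshold can only decrease the selected K. A `force_K` override
exists for cases judged by eye (the published analyses contain one such
case); forced choices are flagged in the selection report.

Component-mean confidence intervals use ±t·σₖ/√n with n = N/K rounded half
up and t the two-sided Student quantile with n − 1 degrees of freedom.
This convention (each component credited with an equal share of the
observations) reproduces the published half-widths from the published
sigmas, e.g. n = 18 for N = 36, K = 2; n = 11 for N = 33, K = 3; n = 10
for N = 19, K = 2. It deliberately ignores the actual mixing fractions;
the alternative (n = wₖN) is not what the source analyses used.

Between-condition comparisons hard-assign each observation to its
maximum-responsibility component (ties to the smaller mean), build a
conditions × components count table (components aligned across conditions
by mean order; a fixed-bin histogram mode is provided as the model-free
alternative) and apply Pearson's chi-squared test of independence without
continuity correction. On null simulations the test rejects at the nominal
5% level within sampling error; p-values are reported at full precision.

## Image morphometry

The measurement chain mirrors the ImageJ/FIJI workflow for particle
fields: luminance grayscale conversion (ITU-R 601 weights) → FFT bandpass
→ Sobel gradient magnitude ("Find Edges" semantics) → threshold → 8-connected
component labeling with hole filling → per-particle measurement.

* **FFT bandpass** — Gaussian transfer functions attenuate structure
  smaller than 3 px and larger than 40 px (the defaults of the GUI tool
  this chain reimplements). The image mean is restored after filtering and
  the result clipped to the input range; a constant image passes through
  unchanged.
* **Thresholding the edge map** — a particle is a *closed* gradient
  contour; thresholding an edge map yields annular bands, whose enclosed
  holes are filled before labeling. The threshold is swept over 10–45
  intensity units and the level maximizing the number of valid particles
  is chosen. Validity requires: area ≥ 100 px (the smallest real particles
  in this domain, ~50 nm wide, are several hundred px² at typical
  calibrations), a closed contour with an enclosed interior of at least a
  quarter of the region (a thinner interior means the contour has merged
  with neighbouring structure), roundness 4πA/P² ≥ 0.5 (a digitized disk
  measures ≈ 0.65 under an 8-neighbourhood perimeter; ragged noise webs
  fall far below), and no border contact. Among levels attaining the
  maximal count the **median** level is chosen: the low end of the plateau
  sits at the gradient noise floor where noise structure attaches to
  contours and corrupts areas, the high end is about to break contours
  open, and the plateau middle is the stable operating point the manual
  "balance closing vs merging" procedure effectively targets.
* **Contour-midline areas** — a filled contour region extends to the
  *outer* edge of the gradient band, which systematically overestimates
  particle area. For roughly circular particles the package reports the
  area of the circle at the band midline, π((r_in + r_out)/2)², with
  r_in/r_out the equivalent radii of the enclosed interior and the filled
  region; mask pixels above threshold strictly inside the contour are
  counted as interior, not band. Widths are the maximal x-extent of the
  filled region minus the mean band thickness. On synthetic fields this
  keeps area errors within a few percent; the midline convention assumes
  approximately isotropic particles.
* **Calibration** — instrument scale is expressed as pixels per 200 nm;
  area_nm² = area_px·(200/c)², width_nm = width_px·(200/c). Values outside
  the instrument's typical 103–125 range are accepted with a warning.
* **Exclusions** — border-touching and open-contour regions are retained
  with flags but excluded from statistics, matching the requirement that a
  measurable particle have a complete, isolated circumference.

## Synthetic data generator

The generator defines the study conditions for every statistical test:

* **Measurement sets** — seeded draws from explicit component
  specifications; the published fitted mixtures for every condition
  (particle areas per aging time, widths after single and double
  nano-indentation passes, and the pooled ensembles, with their original
  sample sizes of 19–129) are built in as named presets. Latent component
  labels are returned with every sample, and draw i always comes from the
  component named by label i. Degenerate σ = 0 point masses are allowed
  (and flagged) in the generator only.
* **Images** — particles are rendered as radially symmetric domes: a flat
  top with a sigmoidal shoulder (scale 1 px) crossing half-maximum exactly
  at the nominal radius, so the analytic particle area is πr². Defaults
  emulate the instrument's stated geometry: 512 px fields, calibration 115
  px per 200 nm (midpoint of the printed 103–125 range), radii 17–30 px
  (≈ 60–105 nm widths), peak 180 on background 30, additive Gaussian
  intensity noise of sd 6 clipped to [0, 255] (the source describes no
  noise model; sd 6 gives a visibly noisy but workable field). Centers are
  rejection-sampled to at least three radii separation; deliberately
  overlapping placements are allowed but flagged, emulating the
  contiguous-particle failure mode.

What the generator does **not** emulate: AFM tip–sample convolution,
nano-indentation mechanics, height information, spatially correlated scan
noise, streak artifacts, or JPEG compression. Tests passing on synthetic
fields therefore demonstrate the correctness of the measurement chain's
geometry and statistics, not robustness to every instrument artifact.

## Problem sizes and known limitations

The validation suites use sample sizes matching the published conditions
where they exist (N = 19–129 for the presets; N = 500–5000 for recovery,
selection and QQ-discrimination checks; 50 fitting fixtures for the
monotonicity suite; 10 images for the round trip; brute-force grid
comparison on ≤ 10-point datasets where exhaustive search is tractable).

Known limitations:

* Parameter recovery for *strongly overlapping* components is limited by
  information, not by the optimizer: for the four-component ensemble
  preset (components at 1479 ± 194 and 1617 ± 54 overlap heavily) the
  maximum-likelihood weights at N = 5000 scatter by more than ±0.03 in a
  substantial fraction of replicates even though the fitted likelihood
  exceeds the generating parameters' likelihood. Tight recovery tolerances
  are only meaningful for well-separated mixtures.
* The selection thresholds are calibrated heuristics, not formal tests;
  likelihood-ratio asymptotics do not apply at mixture boundaries.
* Width measurement follows the thresholded mask; the original manual
  procedure (reading the widest lateral point off the image by eye) cannot
  be reproduced literally.
* The chi-squared construction from hard assignments discards assignment
  uncertainty; for heavily overlapping components the counts understate
  the variance.
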