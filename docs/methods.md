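# Methods

This note documents the models implemented in `morphomech`, the assumptions
behind the synthetic-data generators, and the numerical choices that were
genuinely open. Every number quoted here is recomputed by the test suite or
by `scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## Morphometry

Fourteen descriptors are measured per cell from a cell mask and a nucleus
mask (one connected foreground component each; ≥ 95% of nucleus pixels must
lie inside the cell):

| descriptor | definition | units |
|---|---|---|
| cell/nuclear area | pixel count × pixel_size² | µm² |
| cell perimeter | Crofton-formula boundary length | µm |
| cell major/minor axis | best-fit ellipse via second central moments (full axes = 4√λ) | µm |
| bounding length/width | axis-aligned box extents after rotating so the reference axis is horizontal | µm |
| aspect ratio | major/minor | – |
| solidity | area / convex-hull area | – |
| roundness | 4A/(π·major²) | – |
| circularity | 4πA/P², clipped to 1 | – |
| cell/nuclear angle | moment orientation relative to `reference_axis`, wrapped to [−90, 90), CCW positive | deg |

Choices worth flagging:

- **Perimeter.** The Crofton (4-direction) estimator is used because the
  chain-code perimeter runs ~5% high on smooth digital boundaries, which
  would bias circularity of round cells well below 1. Crofton slightly
  underestimates the perimeter of axis-aligned rectangles; tests use
  tolerances rather than bit-exact equality with any particular software's
  boundary weighting.
- **Reference frame.** Angles and bounding extents are defined relative to
  an explicit `reference_axis` (the scaffold fiber/stretch axis), because
  orientation *relative to the fibers* is the biologically meaningful frame.
  Whether source measurements used the image axis or the fiber axis is
  ambiguous; the parameter makes the choice explicit.
- **YAP/TAZ ratio.** Mean nuclear intensity over mean cytoplasmic intensity
  (cell minus nucleus), with an optional constant background subtraction
  (default 0, since background handling is otherwise unspecified).
- Orientation is ill-defined as aspect ratio → 1; round-trip tests only
  check angles for aspect ≥ 1.3.

## Synthetic populations

Real deposited imaging data do not exist for this pipeline, so the
generators define the study conditions.

**Archetypes.** Four default morphologic archetypes mirror the qualitative
shape groups observed on strained fiber networks: (1) off-axis spreading,
low solidity, low aspect; (2) very large, low circularity; (3) round,
compact, round nuclei; (4) small, strongly elongated, on-axis. Ranges
(areas 500–7000 µm², aspect 1–6, solidity 0.45–0.97) are generator defaults
chosen once as plausible for fibroblast-like cells on fibers; no per-group
descriptor distributions were available to validate against, so only the
qualitative cluster structure is meaningful. Sampled descriptors (area,
aspect, solidity, angle) are uniform within ranges; the remaining
descriptors are deterministic ellipse-geometry consequences, so pairwise
archetype centroid separation in z-scored space is ≥ 3 by construction (a
full pooled covariance is singular because of those deterministic columns,
hence the diagonal-covariance definition of this separation).

**Masks.** Cells are rasterized as rotated ellipses with optional sinusoidal
boundary lobes, m(t) = 1 + a·cos(kt), with a = 0.9(1 − solidity) capped at
0.45; axes are rescaled by 1/√(1 + a²/2) so the enclosed area is exact.
Round-trip tolerances (measured vs generating record): area 3%, aspect 5%,
angle 2°. Rendered solidity is only approximate — the lobe amplitude is a
heuristic, and no tolerance is claimed for it. The nucleus is a concentric
ellipse shrunk (×0.97 steps) until strictly inside the cell.

**YAP coupling.** yap = baseline + Σ c_j·tanh((x_j − m_j)/s_j) + cue shift +
decoupling offset + N(0, σ_noise), floored at 0.1 (a nuclear/cytoplasmic
ratio is positive). The coupled descriptors are cell aspect ratio, cell
area, and nuclear area — the most predictive morphology parameters — with
tanh saturation so the target is smooth, bounded, and representable by a
4-neuron network. Default cue shifts are −0.60 (contractility inhibitor)
and +0.69 (agonist), the measured group displacements of a cue-blind model;
the default decoupling offset is N(1.52, 0.88²), the invasive-cell
calibration. `noise_sd_for_explainable_variance` sets σ_noise so that
var(deterministic)/var(total) hits a target (0.65 in the headline study);
the floor can truncate the left tail, so the reported explainable variance
is computed before clipping.

What the generator does *not* emulate: intensity images with realistic
texture/noise, segmentation error, correlated per-descriptor measurement
noise, batch effects, or cell–cell interactions. Passing tests therefore
demonstrate that the analysis chain recovers planted structure, not that it
would perform identically on real micrographs.

## Fiber-network constitutive model

R(θ,ε) is Gaussian in θ about θ₀ with spread σ(ε) = σ₀e^(−αε) + σ∞
(degrees). The literal prefactor 1/(2πσ²) of the Gaussian form is not a
normalized one-dimensional density and contradicts the unit-integral
definition of R; we therefore keep the Gaussian *shape* and renormalize
analytically over [−π/2, π/2) (truncated normal via erf). Only the shape
affects fitted spreads.

Axial stress is the double integral of R·cos²θ·A·B·e^{Bε} over angle and
strain plus a linear matrix term k_matrix·ε. Numerically: trapezoid in θ on
a 3° grid and cumulative trapezoid in ε with 1.6×10⁻⁴ steps (both
overridable); against a fine-grid oracle (0.1°, 10⁻⁵) the default-step
integral agrees to < 1% at ε = 0.09.

Fitting is two-stage: (1) each angle histogram is fit to the truncated
Gaussian (θ₀, σ) by least squares; σ(ε) parameters (σ₀, σ∞, α) are then fit
to the per-strain spreads — at least three distinct strains are required for
identifiability. (2) (A, B, k_matrix) are fit to the stress–strain curve
restricted to the toe region (default cap 0.06 strain; the source analysis
fit "low strain" without a number) by bounded least squares with 5
Latin-hypercube multi-starts (seeded internally, so fits are
deterministic). In the simulate-and-refit study (2% multiplicative noise,
histograms at ε ∈ {0, 0.03, 0.06, 0.09}, 181-point curve), median R² ≥ 0.9
and all six scale parameters recover within 15% over 20 seeds; θ₀ is
checked absolutely (degrees) since its true value is 0. The curve is
sampled densely (181 points) because A and B trade off through the
amplitude A·B·e^{Bε}; sparse noisy curves leave A weakly identified.

`orientation_from_image` Hann-windows the image, bins 2-D FFT power by the
direction perpendicular to each spatial frequency (annulus r ∈ [3, 0.45·min
dim]), and normalizes to unit integral. Isotropy is asserted on the average
histogram over seeds, since a single noise image has large per-bin variance.

## Self-organizing map

2×2 grid (four units — the "2 neurons" phrasing in the source is read as
grid dimensions, matching the four observed shape groups) over z-scored
descriptors (they span four orders of magnitude in units). Batch training:
each epoch assigns every cell to its best-matching unit and moves prototypes
to the Gaussian-neighborhood-weighted mean; the radius decays linearly 1 → 0
over the first half of training, after which updates are k-means-like.
Prototypes initialize from data points (seeded). The recorded quantization
error is the RMS distance to the assigned prototype — the energy the
zero-radius batch update minimizes — and is non-increasing per epoch on the
default population. Ties in assignment break to the lowest unit index.
Exact hyperparameters of the original toolbox run are unknown, so cluster
identity is validated structurally (4 non-empty units, archetype purity
≥ 0.8), not numerically.

## Bayesian-regularized regression

14 (or 15) inputs → 4 logistic-sigmoid hidden units → linear output.
Training minimizes F = λ_d·E_D + λ_w·E_W (E_D = Σ residual², E_W = Σ w²)
by Levenberg–Marquardt with the Gauss–Newton Hessian; after each accepted
step the evidence approximation re-estimates γ = N_w − 2λ_w·tr(H⁻¹),
λ_w = γ/2E_W, λ_d = (n − γ)/2E_D. Because these updates rescale F to n/2
identically, convergence is judged on the relative decrease achieved by the
LM step itself (< 10⁻⁷), or 300 iterations. Weights initialize
Nguyen–Widrow-style (seeded). Inputs and target are z-scored; the
biochemical-cue input passes through unstandardized so its {−1, 0, +1}
coding is preserved. No validation split is held out — regularization
replaces early stopping — matching the 75/25 train/test protocol; training
targets are screened by a single two-sided Grubbs test (α = 0.05) before
fitting. On pure-noise targets γ collapses far below N_w (asserted
< 0.3·N_w), the over-fitting guard that motivates this estimator for
n-of-hundreds datasets. A constant target is flagged degenerate (the net
returns the constant; R² reported as 0).

Error convention throughout: **error = measured − predicted**, so a group
mean μ < 0 means the model over-predicts (e.g. after contractility
inhibition) and μ > 0 under-predicts (agonist, invasive cells).

In the cue study, group biases of the cue-blind and cue-aware models are
estimated on an independent 300-cell-per-group evaluation population rather
than the small held-out split: a group-mean over ~25 cells has SEM ≈ 0.07,
which would swamp the |μ| < 0.1 question being asked.

## Aberrance statistics

Grubbs: G = max|x − x̄|/s against the t-based critical value, two-sided,
single pass by default ("a Grubbs test", singular); iterative mode repeats
until no rejection. Symmetric extreme pairs in tiny samples can mask each
other — this is a property of the test, and a unit test documents it.
Kruskal–Wallis (tie-corrected, via scipy) is the omnibus; Dunn's rank-based
z statistics with the Σ(t³−t)/12(N−1) tie correction and Bonferroni
adjustment form the post-hoc table (the named graphing software's
convention; the exact multiplicity correction was unstated). If all values
are identical the omnibus is reported as H = 0, p = 1. Per-cell decoupling
flags use |error| > z·σ_ref with z = 2 by default — a documented package
default, as no numeric single-cell rule was stated — where σ_ref is the
training-set error SD (0.42 in the calibrated studies, the measured
test-set precision of the original model).

## Invasiveness classifier

10 sigmoid hidden units, two-unit softmax output (scores sum to 1 exactly),
cross-entropy plus a small (10⁻⁴) L2 term, trained by Møller's scaled
conjugate gradient with a seeded 50/15/35 train/validation/test split and
early stopping after 6 consecutive validation increases (best weights
restored). 50/15/35 of an odd n is ambiguous; the rule is floor for train
and validation, remainder to test (292 → 146/43/103). Class imbalance is
left as-is.

The two-class study condition makes the invasive class a morphologic
*mixture*: half its cells are drawn from the same epithelial archetypes as
the non-invasive class and half from an elongated mesenchymal archetype,
while *every* invasive cell carries the YAP decoupling offset. Morphology
alone therefore cannot exceed ~75% accuracy (the shared-shape half is
unidentifiable), YAP alone does better, and the combination is best —
median test accuracies over 20 seeds are asserted in that order — and
removing the offset (the "stiff 2D" condition, where fibrous-environment
mechanosensing differences collapse) drops the YAP-only classifier below
0.7. These are qualitative-pattern checks; the printed accuracies of the
original cell-line experiment depend on unavailable imaging data and are
not reproduction targets.

## Pipeline

`run_pipeline` fans the global seed out to per-stage seeds by hashing
`"{seed}:{stage}"` (SHA-256, reduced mod 2³¹), so toggling one stage never
perturbs another and re-running a config reproduces every artifact hash
bit-identically (single-threaded numerics, fixed seeds). A stage failure is
recorded in the manifest (status `failed`, later stages `skipped`) before
the error propagates. Prediction cards map the measured cytoplasmic level
to the cytoplasm and ratio × cytoplasm (clipped to [0, 255]) to the nucleus,
side by side for measured and predicted ratios.

## Problem sizes

Default study sizes are chosen to mirror the scale of the motivating
experiments: ~1000 cells for clustering, 400 for the predictability study
(75/25 split), 650 for the cue study plus a 900-cell evaluation population,
1000 + 300 for decoupling detection, 300 per classifier dataset, 20-seed
medians for all stochastic recovery claims.

## Known limitations

- The morphometry is not bit-compatible with any specific image-analysis
  software's boundary weighting; descriptor contracts are tolerance-based.
- The SOM and both networks are deliberately small, matching the described
  architectures; no hyperparameter search is provided.
- Fitted constitutive parameters are validated only against synthetic data;
  no reference values for A, B, k_matrix were available.
- The generators produce feature tables with some deterministic column
  dependencies (e.g. roundness = 1/aspect exactly), which real segmentation
  noise would break.
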