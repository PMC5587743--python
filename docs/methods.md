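# Methods

This note documents the models and procedures implemented in `cartinirs`,
the assumptions they make, and the design choices taken where the
underlying methodology is genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## OCT scoring

**Catheter detection and scale.** The imaging catheter (diameter 0.9 mm)
appears as a bright ring near the top of the B-scan. The detector
thresholds the top third of the image at `median + 6·1.4826·MAD` (with a
single retry at the background/maximum midpoint when the noise floor is
degenerate, e.g. on synthetic noiseless renders), takes the largest
connected bright component, and fits a circle to it: the centroid gives
the centre and the mean radial pixel distance the radius. The component
must be ring-like — relative radial spread ≤ 0.12 and angular coverage
≥ 24/36 bins — otherwise scoring aborts; a silently assumed scale would
corrupt every micrometre quantity downstream. The radius is then refined
to sub-pixel precision as the intensity-weighted centroid of the
baseline-corrected radial brightness profile (±6 px window); without this
refinement the thresholded radius is biased ~0.5 % low because the dim
outer edge of the blurred ring is eroded first, which propagates into a
~10 µm depth bias at typical surface depths. The scale is
`px_per_mm = 2·radius / 0.9 mm`.

**ROI.** A 2 mm-wide column window (the footprint of the NIRS fibre
probe), centred on the configured measurement position (image centre by
default). Catheter pixels are masked and the per-column surface search
starts below the catheter mask; in the supported geometry the catheter
sits above the tissue, so ROI columns themselves are never dropped.

**Surface detection.** Each A-line is smoothed along depth (Gaussian,
σ = 1 px). The noise floor is estimated from a background window below
the catheter; the surface candidate is the first sample above
`median + 6·MAD` sustained for 3 consecutive samples. The depth is then
refined to the half-rise point between the background median and a local
plateau estimate taken as the 75th percentile of the 8 samples at the
onset — an upper quantile because a plain maximum is biased high under
multiplicative speckle (pushing the crossing deep) while a plain mean
dilutes the ~12 µm echo with tissue (pushing it shallow). Columns without
an echo are interpolated from neighbours; if more than 20 % of ROI
columns fail, the image is rejected as fully eroded/off-tissue. The
resulting line is median-filtered (5 columns) and adaptively smoothed:
per-column Gaussian kernels whose σ (0.5–2 px) shrinks where the local
gradient energy is high, preserving lesion rims while suppressing
speckle jitter.

**Interface detection.** The calcified-cartilage/bone onset is searched
strictly below the surface (≥ 24 µm) as the maximum positive depth
gradient of a strongly smoothed A-line (σ = 4 px), validated by requiring
the band beyond the candidate to be ≥ 2× brighter than the tissue before
it (windows placed outside the ±2.5σ blur zone of the step, so the
half-rise level is symmetric about the true edge). The candidate is
refined to the half-rise crossing; the gradient argmax alone is ~5 px
deep because speckle fluctuations scale with intensity inside the bright
band. Columns failing validation — including bone-exposed columns, where
there is no tissue/bone step — are bridged by lateral interpolation, and
the final line receives strong lateral smoothing (σ = 25 px): the
subchondral interface is laterally continuous and smooth, and this
dilutes any residual spurious detections. If fewer than half of the
columns validate, the interface is reported unknown and grading falls
back to surface criteria with a warning.

**ORI.** Root-mean-square residual of the detected surface about its
least-squares straight line over the ROI, in µm via the catheter scale.
The exact definition behind the published roughness index is not spelled
out in the scoring literature we follow; the straight-line detrend is
chosen so flat and uniformly tilted surfaces score exactly zero, and it
is what makes the index invariant to probe orientation. A higher-order
detrend is a one-line change flagged for sensitivity analysis.

**Thickness and loss.** Thickness is interface − surface per column.
The reference thickness is the mean over the flanking quartiles of the
ROI (the least lesion-affected columns); the baseline for the published
8 % loss threshold is not specified, and a local intact reference is the
interpretation that works for an isolated measurement. The loss
statistic is computed on a profile processed by an 11-column median
filter, a 31-column grey closing and an 8-column Gaussian: roughness is a
zero-mean narrow-scale modulation whereas a lesion is a wide one-sided
dip, and the closing removes dips narrower than its window so roughness
does not masquerade as focal loss. `loss_fraction` and
`max_defect_fraction` are both `(reference − min thickness)/reference`;
they are kept as two fields so the decision tree reads exactly as the
threshold rules it implements. Bone exposure is judged on the
median-only profile (the closing and Gaussian would smear the narrow
zero-thickness valley of a penetrating defect) at a 20 µm threshold, the
instrument-class axial resolution.

**Grading.** Most-severe-first: bone exposed → 4; defect > 50 % → 3;
loss > 8 % → 2; ORI > 8 µm → 1; else 0. Evaluating in this order
resolves multi-threshold conflicts deterministically, and makes the grade
monotone non-decreasing in each input.

## Spectral preprocessing

Pipeline order: average the three repetitions → Savitzky–Golay (order 3,
window 39 points ≈ 25 nm; derivative orders 1/2 scaled to per-nm units by
the grid step) → scatter normalization (SNV or MSC) → restriction to
700–1100 nm. The source methodology lists the operations but not a
strict order; normalizing smoothed spectra and restricting the band last
keeps filter edge effects outside the retained wavelengths. Edges are
handled by refitting the polynomial on the truncated terminal windows
(`scipy` `mode="interp"`). SNV uses the sample SD (n−1). The MSC
reference is the mean spectrum of the *training* subset only, reused for
validation/test — the unspecified alternative (all-set mean) would leak
held-out spectra into the correction. The repetition CV is the mean over
wavelengths of SD/mean × 100.

## Reference analysis

FTIR contents are trapezoidal band integrals (amide I 1584–1720 cm⁻¹ for
collagen, carbohydrate 984–1140 cm⁻¹ for PG) with linear interpolation
at the band edges. The superficial/deep zone boundary is the interior
minimum of the birefringence depth profile after a light 3-sample moving
average (noise-driven minima otherwise dominate), ties breaking toward
the surface; monotone profiles are flagged and floored (default: one
depth step; severe defects in the source cohort bottom out at 12.5 µm).
Zone means are trapezoid-weighted over the samples above/below the
boundary — depth-weighted rather than per-pixel means, the natural
choice when a profile is the primary object — and converge under
depth-grid refinement. Profiles are consumed already truncated at the
uncalcified/calcified boundary and pre-averaged across sections (the
single-section FTIR case is the general case).

## Network regression

**Split.** 60/30/10 train/validation/test, stratified by ICRS grade with
per-stratum rounding. The reference ranges of validation and test are
required to lie inside the training range; violating extremes are swapped
into training within their stratum (the methodology states the
containment property but not the mechanism).

**Forward IVS.** The "most reliable wavelength" criterion is the
canonical residual-correlation filter: step 1 maximizes |Pearson r| with
the target, step k+1 maximizes |Pearson r| with the OLS residual on the
selected set; ties break toward the lower wavelength, zero-variance
columns are skipped, and selection stops at 200 variables (or the column
count). Selection uses training + validation rows only; the test group
never influences which wavelengths enter the model.

**Architecture and training.** One hidden tanh layer (1–10 neurons),
linear output, inputs and target standardized to training z-scores
(required for a stable Levenberg–Marquardt on absorbance-scale data).
LM damping starts at 1e-3, ×10 on a rejected step, ÷10 on an accepted
one (floor 1e-12, abort diagnostics above 1e10); an accepted step never
increases the training SSE. Two accelerations are layered on the basic
step: (i) the accepted Gauss–Newton direction is extrapolated by doubling
while the error keeps falling, and (ii) a line search along the tanh
scaling family (W1, b1 → /2 with the linear output layer re-solved in
closed form) — the conditional optimum of a linear output layer is
ordinary least squares, and for targets in the filter's near-linear
regime the residual is dominated by the cubic tanh term and shrinks ~4×
per halving, which is what lets affine maps be realized to machine
precision. Early stopping: training ends after six successive epochs
without validation improvement (or 1000 epochs), returning the weights of
the validation minimum. Initialization is Nguyen–Widrow-style and fully
seed-determined; identical seeds give bitwise-identical models.

**Selection.** A grid over hidden sizes × weight restarts (default 5;
how many restarts the original protocol used is not stated), keeping the
model with minimal test-group RMSE — reproduced verbatim even though it
is optimistically biased; the audit grid also records validation RMSEs so
a validation-based selection remains inspectable.

## Evaluation protocols

Protocol 1 (generalized) fits one model per zonal target on all points.
Protocol 2 (condition-specific) fits per-grade models on per-grade
subgroups of the protocol-1 split (exact set inclusion, assertable), and
pools the per-grade test predictions before computing pooled metrics.
NRMSE is RMSE ÷ (max − min of the target over all samples) in percent;
the "average NRMSE" pools the eight target rows (4 parameters × 2
zones). Small strata receive proportionally fewer selected variables
(≤ n_train/4) and hidden neurons (≤ n_train/12), and strata under 10
points are excluded with a warning — an unconstrained network on a
30-point stratum would be meaningless. Pearson p-values are raw
two-tailed with no multiple-testing correction (a deliberate match to the
source methodology; a limitation, since eight correlated targets are
tested).

## Synthetic data generator

The generator emulates the structure the analysis assumes; its defaults
are the study conditions (530 points; grade mix 318/159/53 over ICRS
0/1/2; repetition CV calibrated to ≈ 0.82 %; composition means, SDs and
ranges per the published reference table, clipped 0.5 % inside the range
bounds so profile round-trips stay strictly within them).

**Composition.** Per-grade means shift linearly with grade (superficial
orientation up ≈ 8°/grade; superficial collagen, PG content and PG OD
down), with a shared within-point severity factor (ρ = 0.4) so degraded
points are degraded across parameters. Grades 3–4 are generated even
though the emulated cohort contained none, so the full decision tree is
exercisable.

**Depth profiles.** Each parameter is constant at its superficial value
above the zone boundary and rises smoothly (cubic smoothstep over ≤ 50 µm)
to a deep plateau chosen so the continuum deep-zone mean equals the truth
exactly; birefringence is a parabola with its unique interior minimum at
the boundary (default 11 % of thickness, ≥ 12.5 µm). These functional
forms are the simplest with a unique, configurable minimum and exact
zonal means.

**Spectra.** No physical light-transport model exists for cartilage, so
the forward model is deliberately phenomenological: a smooth baseline
plus Gaussian bands at the overtone assignments (NH 3rd overtone
775–850 nm, CH 3rd 850–950 nm, the 970 nm water OH peak, NH/OH 2nd
950–1100 nm) with one distinct signature (band or slope/curvature term)
per composition field, amplitudes affine plus a mild quadratic in the
standardized field values. Grade enters twice: an additive offset
(+0.035 AU/grade, making healthy ICRS0 ensemble spectra lowest) and a
structural dependence — band centres drift ±18 nm per grade step and the
composition gain scales by 1 + 0.18·(g−1). The structural part is what
makes per-grade wavelength selections differ and condition-specific
models genuinely better than a single generalized map; a gain alone is
absorbed by one network and does not reproduce that ordering. Effect
sizes are free parameters chosen once for solvability and positivity;
they are not calibrated to reproduce published correlation magnitudes,
which is also why absolute synthetic errors (NRMSE ≈ 1–3 %) are far
below real-tissue errors. Repetitions apply multiplicative
(σ = 0.0077) and additive (σ = 0.0017 AU) scatter plus white noise
(σ = 0.0017 AU), jointly calibrated to the ≈ 0.82 % repetition CV.

**B-scans.** 1024×1024 px at 4 µm/px (scaled down from the instrument's
2048×2048 to keep fixtures fast; the full geometry is a config change).
Piecewise-constant reflectivity template (background, bright 12 µm
surface echo, tissue, hyperreflective calcified band, bone) times
exponential multiplicative speckle, lightly blurred, plus a Gaussian
noise floor — adequate to exercise segmentation without optical
simulation, and deliberately not a physically accurate speckle model.
Surface roughness is correlation-filtered Gaussian noise scaled to a
target RMS; lesions are cos² depressions with grade-dependent depth
margins kept clear of the decision thresholds (e.g. grade-1 roughness
14–26 µm vs the 8 µm threshold) so truth grades are well defined;
grade-4 defects overshoot the bone line by 20 % and are clipped there,
giving the flat exposed-bone floor such defects actually have. Ground
truth surface/interface lines are returned at sub-pixel precision.

**What passing tests do and do not show.** The generator shares the
real data's structure (grade-dependent geometry and spectra, repetition
noise, zonal organisation) but none of its hard parts: real speckle
statistics, catheter artefacts (shadowing, non-uniform rotation), probe
coupling variation, biological covariance between composition fields, or
the unknown true spectrum–composition map. Passing tests therefore
validate the algorithms' contracts and internal consistency — not
clinical performance.

## Problem sizes and numerics

The test suite and acceptance script use reduced-but-representative
sizes chosen as sensible defaults for a desk-scale reproduction: 120–300
phantoms for grading/statistics, one 530-point cohort per modelling run,
30–40 selected wavelengths, hidden sizes {2,3,4,6}, 2–3 restarts,
100–150 epochs. The full protocol (200 variables, hidden 1–10, 5
restarts, 1000 epochs) is the library default (`EvalConfig()`).
Degenerate inputs are handled explicitly: constant spectra are rejected
by SNV, zero-variance columns skipped by IVS with a warning, monotone
birefringence floors the boundary with a warning, all-identical samples
give Kruskal–Wallis H = 0/p = 1, and every random quantity is a pure
function of an explicit seed.
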