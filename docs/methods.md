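# Methods

## Scope and data model

`pibquant` quantifies reversible-tracer dynamic brain PET (the intended
tracer is [¹¹C]PiB) from three inputs: a 4-D activity volume in kBq/mL,
decay-corrected to scan start; a contiguous frame schedule (seconds on
disk, minutes internally); and an integer label volume naming the
internal-carotid search region, the cerebellar reference, eight
cortical lobe regions (frontal/temporal/parietal/occipital, left and
right), the posterior cingulate and white matter. Frame midpoints are
the nominal sample times of every TAC; all voxel coordinates are
0-based and "slice" means an index along the third (z) axis.

The default schedule is 12×5 s, 6×10 s, 3×20 s, 4×30 s, 5×60 s,
4×5 min, 4×10 min — 38 contiguous frames totalling exactly 70 min.

## Input function

**VOI selection.** The early-phase image is the overlap-weighted mean of
frames intersecting a 10–40 s window; fractional overlap receives
fractional weight, so the operation is exact for constant TACs under
any schedule. Within the carotid search region the n = 30 most intense
early voxels form the VOI; ties break by ascending flattened C-order
index so the selection is deterministic and invariant to positive
affine intensity rescaling.

**Two-phase TAC.** During the bolus (frame midpoint ≤ 45 s, the middle
of the plausible 40–50 s switch range; configurable) the IDIF value is
the mean over the 4 VOI slices holding the most VOI voxels (a 3–5 slice
choice; ties by ascending slice index) of each slice's maximum — a
max-based statistic that resists partial-volume dilution while the
bolus transits. Afterwards it is the maximum over VOI slices of the
per-slice mean, a lower-variance statistic for the tail. A VOI spanning
fewer than 3 slices is rejected.

**Metabolite correction.** The unmetabolized (parent) fraction follows
the Hill form R(t) = α·t^β/(t^β + γ) with t in minutes; shipped
constants α = 1.62, β = −0.92, γ = 0.47. For β < 0 the t→0⁺ limit is α;
since α > 1 the raw curve exceeds 1 at early times and is clipped to
[0, 1] (a parent fraction cannot exceed unity); clipping events are
counted in the QC report. The plasma input is
C_p(t) = clip(R(t))·IDIF(t)/BP with the whole-blood-to-plasma partition
BP defaulting to 1 — scanner cross-calibration is assumed to absorb the
scaling, and BP is exposed as a single scalar for tracers where it is
not. `fit_hill` estimates (α, β, γ) from observed parent fractions by
bounded nonlinear least squares on the *unclipped* model over a 64-point
multi-start grid; with nearly constant data only the level α/(1+γ) is
identified, which the fit reports faithfully rather than failing.

## Graphical analysis

Running integrals are trapezoidal from an implied (0, 0) sample with
frame midpoints as abscissae — exact for piecewise-linear TACs, which
is the natural model for decay-corrected frame averages. The
plasma-input Logan slope over frames with midpoint ≥ t* = 50 min
estimates V_T; on the default schedule this uses the two 10-min frames
centred at 55 and 65 min, matching a 50–70 min linear phase. The
reference-tissue Logan slope uses the cerebellar TAC in the abscissa
integral and estimates DVR directly; the population-k2′ correction term
is omitted by default (the common two-integral graphical-reference
variant) and available as an optional argument.

Per-voxel fits are plain OLS (unweighted, as is conventional for Logan
images). A voxel is masked invalid — value 0, counted in QC — if any
late-frame activity is nonpositive, the design is degenerate, or the
slope falls outside a plausibility window (default (0, 20]); with only
two late points the slope estimator is heavy-tailed under noise, and a
physiological range cap is the standard parametric-imaging safeguard
against single voxels dominating regional means. Noise-free values are
far inside the window, so the cap never binds in clean data.

SUV divides the duration-weighted 50–70 min static mean by injected
dose over body weight (MBq/kg); SUVR and DVR_L divide by the mean of
valid voxels in the cerebellar reference region. The known systematic
property — SUVR overestimates DVR progressively with binding, because a
high-DVR region clears roughly DVR-fold slower than the reference and
is still above equilibrium late in the scan — emerges in the phantom
with realistic magnitude (~10–30%).

## Statistics

Regional values are arithmetic means over valid voxels. Group
comparisons use Welch's two-sample t-test; region-versus-PCC contrasts
use a paired t-test within subjects. Metric agreement uses OLS
regression with Pearson r², and Bland–Altman limits (mean ± 1.96 SD of
differences) computed after mapping the second metric onto the first's
scale through the inverse of the fitted line, so limits reflect
residual scatter rather than linear offset. Difference variances of two
method pairs observed on the same items are compared with the
Pitman–Morgan test (correlation of paired sums and differences) — the
appropriate correlated-variance test here, and implemented in-package
since no installed library provides it. ROC analysis reports the
empirical trapezoid AUC (scikit-learn), equal by construction to the
all-pairs concordance probability; the operating threshold maximizes
Youden's J over midpoints between consecutive sorted unique values
("value ≥ threshold" calls disease), ties resolving to the lower
threshold, so for separated groups the threshold lies strictly between
the class extremes.

## Synthetic phantom

The generator produces the statistical structure the analysis assumes
and nothing downstream could trivially invert.

*Arterial input.* Whole blood rises linearly from 0 to a bolus peak at
0.75 min (peak 22.5 kBq/mL) and decays as three exponentials
(amplitudes 14/5/3.5 kBq/mL; rates 4/0.3/0.004 min⁻¹). The nearly flat
slow component keeps the late input from collapsing, sustaining the
quasi-equilibrium that the 50–70 min Logan window and SUVR presuppose —
absent it, late tissue activity is washout-dominated and SUVR inflates
unphysiologically.

*Tissue.* Each region follows the two-tissue-compartment model; the
impulse response is the standard bi-exponential in the eigen-rates of
(k₂, k₃, k₄), convolved exactly against the piecewise-linear plasma
input on a 0.5 s grid (closed-form per-segment update; IIR filter on
uniform grids). Ground truth DV = (K₁/k₂)(1 + k₃/k₄); DVR is DV over
the cerebellar DV. Defaults: cerebellum one-tissue with K₁ = 0.45
mL/min/g, k₂ = 0.3 min⁻¹ (DV 1.5 mL/g); target regions share K₁/k₂ and
carry binding k₃ = k₄(DVR − 1) with k₄ = 0.3 min⁻¹, chosen so the
slowest tissue eigen-rate stays near 0.1 min⁻¹ and regions approach
equilibrium within the scan, the regime the graphical methods assume.
DVR < 1 is realized by raising k₂ with no specific binding.

*Image formation.* Voxels carry frame-duration averages of their
region's analytic TAC (not midpoint samples — matching how
reconstructed frames behave); carotid voxels carry the frame-averaged
whole-blood curve, optionally with a linear intensity taper along the
vessel. Zero-mean Gaussian noise with SD = s·sqrt(TAC/Δt) mimics count
statistics; the single scale s defaults to 0.2, i.e. ≈10% relative
noise in late 10-min cortical frames and ≈15% in early bolus frames,
in the range of post-filtered OSEM reconstructions. The geometry is a
crude block layout (disjoint boxes scaled to any grid ≥ ~16³, default
32³ at 5 mm); one seed fixes the entire study bit-for-bit.

*Cohorts.* Per subject, regional ground-truth DVR is drawn from group
(mean, SD) targets — defaults are a control-like and an early-AD-like
contrast (e.g. PCC 1.30 ± 0.16 vs 2.43 ± 0.42) with white matter at
1.45 ± 0.10 in both groups. Regions are drawn independently within a
subject; between-subject coupling enters instead through shared
log-normal variation of delivery (K₁, CV 15%), release (k₄, CV 10%),
reference DV (CV 10%) and the arterial amplitude (CV 15%) plus peak
time — the variability that makes transiently-equilibrated metrics
(SUVR) scatter across subjects while true-equilibrium ratios (both
DVRs) stay tight, reproducing the observed agreement ordering.
Injected dose is uniform in 700–750 MBq, weight normal 60 ± 8 kg.
Per-subject seeds derive deterministically from the cohort seed.

**What the phantom does not emulate** — and hence what passing tests do
not demonstrate about real data: tomographic reconstruction and its
correlated, non-Gaussian noise; attenuation, scatter, partial volume
and spillover (in particular, real carotid IDIFs need the calibration
the VOI rules approximate); dispersion; head motion; anatomical
realism of the parcellation. Recovery results here validate the
numerics and logic of the estimators, not their robustness to those
physical effects.

## Numerical choices and degenerate inputs

- Trapezoid integration everywhere, with an explicit (0, 0) anchor for
  Logan integrals.
- Coincident 2TC eigen-rates are split by 1e-8 rather than switching to
  the t·e^(−at) limit form; the perturbation error is far below
  simulation noise.
- Early-window and static averages use fractional frame-overlap
  weights.
- Hottest-voxel and slice-count ties break by ascending index; the
  Youden threshold tie breaks low.
- Voxels failing Logan validity carry 0 and are excluded from regional
  means; regions with no valid voxels are omitted from tables rather
  than reported as NaN.
- Problem sizes in the test-suite and acceptance runs (32³ grids,
  20-subject groups, 0.5 s simulation step) were chosen as the smallest
  sizes at which regional statistics are stable; all scale linearly if
  enlarged.

## Known limitations

- The two-point late-phase Logan fit has no within-voxel redundancy on
  the default schedule; r² diagnostics are informative only for
  regional TACs or finer late sampling.
- The noise-induced negative bias of Logan DV (underestimation when
  late activity is noisy) largely cancels in DVR but is present in raw
  DV images.
- The Hill α/γ pair is unidentifiable from flat parent-fraction data;
  the fit returns one representative of the level set.
- `simulate_cohort` assumes group SDs are achievable with DVR > 0.2;
  draws are floored there.
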