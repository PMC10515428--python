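# Methods

## The voxel kinetic model

After an intravenous gadolinium bolus, tissue behind an intact
blood–brain barrier shows essentially flat T1 signal over tens of
minutes, while tissue behind a subtly opened barrier accumulates tracer
slowly. Each voxel's intensity curve, normalized to the first
post-contrast frame, is modeled as

    f(t) = x1 · t · e^(−t/x2) + x3 · e^(−t/x4) + x5

with t in minutes post injection. The first term is a slow
accumulation-then-washout lobe (amplitude x1 in 1/min, time constant x2 in
min, peak at t = x2), the second a simple exponential decay component
(amplitude x3, time constant x4), and x5 the asymptotic offset; all
amplitudes are in units of the normalized baseline. The functional form
follows the two-compartment exchange picture of tracer kinetics; a
"saturating" reading of the second term, x3·(1 − e^(−t/x4)), is
selectable via `FitConfig(variant="saturating")` for sensitivity checks.
No arterial input function, T1 mapping, or signal-to-concentration
conversion is attempted — the model describes the normalized signal
directly.

Assumptions: injection defines t = 0; the first frame is acquired at
t_first > 0 and normalization makes f(t_first) ≈ 1; at least 7 frames
within ~30 min; intensities stationary apart from tracer effects (motion
is handled by rigid registration).

### Derived summaries

All three summaries are evaluated on the *fitted* curve, on a dense grid
of `grid_points` (default 1000) samples over the scan window
[t_first, t_last], never by extrapolation beyond the last frame:

- **Dyn** (%) = 100 · (max f − f(t_first)). Nonnegative by construction
  since the grid includes t_first.
- **TT** (min): the measure of {t : f(t) ≥ 1 + threshold}, estimated as
  the grid fraction × window length (resolution ≈ 0.03 min at defaults).
  TT is window-limited by design: it measures opening duration within the
  scan, not the total duration of the opening.
- **AOT** (min × normalized units): trapezoidal quadrature of
  max(f − (1 + threshold), 0).

The threshold default is 0.05 (a 5 % signal increase).

### Fitting

`fit_voxel` (per-curve reference path) runs bounded trust-region nonlinear
least squares from a data-driven initial guess (x1 from the early slope,
x2 = 10 min, x3 = peak − last, x4 = 20 min, x5 = last value) plus 5 seeded
random restarts, keeping the lowest SSE — two-exponential objectives are
multimodal. r² = 1 − SSE/SST with SST about the mean of the observed
values; a flat observed curve (SST ≈ 0) gets r² = 1 iff the fit is also
exact, else 0.

`fit_brain` (whole-brain path) exploits the model's conditional
linearity: for fixed (x2, x4) the optimal (x1, x3, x5) is a linear
least-squares solve, identical for every voxel. A variable-projection
sweep over a log-spaced 16 × 12 (x2, x4) grid therefore fits all voxels
simultaneously; the best node per voxel seeds a batched
Levenberg–Marquardt refinement of all five parameters (per-voxel damping,
40 iterations, bound clipping). On noiseless curves this reaches machine
precision; the two routes (scipy per-curve vs batched LM) are compared
against phantom ground truth independently in the tests.

Bounds: x2, x4 ∈ [2.5, 200] min and x1 ≥ 0 by default. The lower time
constant bound reflects identifiability — components faster than the
early inter-frame spacing (~2.5 min on the default schedule) cannot be
resolved by the sampling and act purely as noise-chasing degrees of
freedom, inflating Dyn through sub-sampling-scale transients. The x1 ≥ 0
bound encodes that the accumulation lobe models tracer influx, whose
amplitude is nonnegative (curves may still decay below baseline through
x3 < 0 … x3 is unconstrained). Both are configurable.

Voxels whose first-frame intensity is at or below a noise floor ε
(default 10⁻⁶ of the dtype's positive range for integer data, 10⁻⁶ of the
first-frame maximum for float data) are flagged unfittable and excluded,
which keeps air voxels from blowing up the normalization.

## BBBo classification

A voxel is classified BBBo iff r² > 0.6 AND Dyn > 5 %, and it belongs to
a 3D-connected component of at least 30 such voxels. Filters are applied
in the order r² → Dyn → cluster size (order does not change the result;
it is fixed for reproducible logs). Components are labeled with
face connectivity (6-neighborhood) by default, selectable among 6/18/26.
This default is deliberate: at realistic noise levels a few percent of
pure-noise voxels pass the r² and Dyn thresholds, and with
26-connectivity those isolated voxels chain through diagonal contacts
into components that exceed the 30-voxel minimum — the cluster filter
then no longer separates signal from noise. Face connectivity keeps the
filter meaningful while leaving compact real clusters (which are
face-connected) intact; with noise-free input the two choices give
identical masks on such clusters.

BBBo volume is n_voxels × voxel volume. The printed minimal-cluster
volume is taken as the voxel-count rule (30 voxels ≈ 1.83 mm³ at
0.39 × 0.39 × 0.4 mm). Group comparison uses the fold ratio of group-mean
voxel counts (rounded to the nearest integer) and the pooled-variance
Student's t-test.

Registration: each frame is rigidly (6-DOF) aligned to the first
post-contrast frame with a correlation metric and linear interpolation
(SimpleITK). The stage is pluggable and bypassed by default
(`registration="identity"`) for synthetic inputs, which are generated
aligned; a diverging frame is passed through unaligned and flagged in the
transform log rather than aborting the run.

## Distributions

Histograms of Dyn/TT/AOT are built over BBBo voxels only (default bin
widths 2.5 %, 2.5 min, 0.2 — configurable; counts always sum to the BBBo
voxel count, with top-edge values assigned to the last bin). The AOT
histogram is summarized by unweighted least squares of A·e^(−x/τ) on raw
counts at bin centers through the last nonempty bin (≥ 3 nonempty bins
required). Raw counts rather than log-counts: the log transform is
undefined for empty bins and over-weights the sparse tail.
Group-average histograms are bin-wise means with SEM across subjects.
`calibrate_exponential_rate` / `exponential_fraction_below` provide the
closed-form exponential-CDF arithmetic used for tail predictions (e.g.
calibrating the rate to one quantile and evaluating another).

## Pharmacology

Tissue concentration converts as nM = (µg/g) · density(g/mL) · 10⁶ /
MW(g/mol); defaults are doxorubicin's MW 579.98 g/mol and brain density
1.046 g/mL (0.3 µg/g → ≈ 541 nM by this dimensional analysis; the fold
arithmetic in `analysis/04` uses the separately reported molarity of
690 nM, and the discrepancy is recorded in the results table it writes).
Fold-over-IC50 is the rounded ratio of achieved concentration to IC50.

IC50 estimation fits the variable-slope four-parameter logistic
y = bottom + (top − bottom)/(1 + (c/IC50)^hill) to mean endpoint
confluence per concentration, on the log10 concentration axis for
conditioning, with hill > 0 encoding inhibition. Vehicle (zero
concentration) wells anchor the top plateau at a pseudo-log position two
decades below the lowest dose. The IC50 standard error comes from the
log-space covariance by the delta method. Flat plates raise a
non-convergence error rather than returning a spurious estimate.

## Efficacy

Tumor volume is the enhancing-ROI voxel count × voxel volume; growth rate
is the dimensionless fold change v_followup/v_baseline (the only
definition consistent with rates near 1–3 for mm³-scale volumes over a
few days). Extratumoral BBBo re-runs the classification on brain AND NOT
tumor voxels, re-applying the minimum-cluster filter after subtraction —
the filter defines what counts as BBBo, so a cluster straddling the tumor
border only survives if its remainder still reaches 30 voxels.

## Synthetic data

The phantom generator emulates the imaging experiment's statistics, not
MR physics. An ellipsoidal brain (semi-axes 0.42 × grid) in a 64³ grid of
0.39 × 0.39 × 0.4 mm voxels is scanned at 8 frames at
1, 2.5, 5, 8, 12, 17, 23, 30 min. Treated phantoms implant 3 spherical
enhancing clusters (radius 2–3.2 voxels, ≥ 30 voxels each) in the outer
cortical shell of the ellipsoid (normalized radius 0.78–0.88, shrunk on
small grids so the cluster fits inside the brain), echoing the cortical
localization of field-induced opening; each cluster shares one kinetic
parameter set drawn so Dyn lands uniformly in 6–30 % (x2 ∈ [6, 20] min,
x4 ∈ [10, 40] min, |x3| ≤ 0.03, x1 rescaled by fixed-point iteration, x5
solved so f(t_first) = 1 exactly). Both phantom types also carry isolated
enhancing components of 1–5 voxels — always below the 30-voxel minimum —
which model the sparse non-specific enhancement seen in controls; sham
phantoms carry only those, so their true BBBo mask is empty. Ground-truth
Dyn/TT/AOT maps are computed analytically from the generating parameters
with the same dense-grid definitions the pipeline uses.

Noise is Gaussian on the signal with sd = 0.02 × the local baseline
(brain 1000, background 60 intensity units), clipped at zero; a Rician
magnitude option exists but the Gaussian default keeps the truth
analytic. Note that normalizing by the noisy first frame makes the
effective per-point noise on normalized curves ≈ √2 × 0.02 ≈ 2.8 %.

What the phantoms do *not* model — and hence what passing tests cannot
show about real data: motion between frames (generated aligned),
spatially correlated or non-Gaussian scanner noise, partial-volume and
susceptibility effects, anatomically realistic brain geometry, vascular
input variability, and within-cluster kinetic heterogeneity (one
parameter set per cluster). The last point means the phantom AOT
population is a handful of discrete values, not the smooth exponential
decay seen across thousands of in vivo voxels — the exponential-fit
machinery is therefore validated against seeded exponential samples in
the tests, while on phantoms it is merely exercised (its r² there is low
and the analysis drivers report it as such).

Dose-response plates simulate 6 wells per concentration on a 3-fold
serial dilution (0.3–656 nM) from a 4PL truth (defaults: top 90 %, bottom
5 %, hill 1) with 5-percentage-point Gaussian well noise clipped to
[0, 100]. Efficacy cohorts draw per-animal baseline volumes
(normal, means 8.09/5.76 mm³, sd 3.47/3.26, floored at 0.5 mm³) and
growth rates (normal, means 1.18/2.6 with sds 0.313/0.984 — the reported
SEMs × √5 — floored at 0.05).

All generators are pure functions of spec + seed (byte-identical reruns).

## Numerical choices and degenerate inputs

- Dense-grid resolution 1000 points: TT quantization error ≤ one grid
  step (~0.03 min); AOT trapezoid error ≪ 10⁻³ for these smooth curves.
- Optimizer tolerances: scipy defaults for the per-curve path; the
  batched LM runs a fixed 40 iterations with per-voxel damping
  (accept/reject, λ × 0.3 on success, × 5 on failure, ridge 10⁻¹²).
- Ties/edges: histogram top-edge values counted in the last bin; voxels
  exactly at a filter threshold are excluded (strict inequalities, as
  published); cluster labels are ordered by decreasing size.
- Degenerate inputs: empty brain masks give empty maps (no error); a
  zero/noise-floor baseline flags the voxel unfittable; empty BBBo masks
  give all-zero histograms; < 3 nonempty bins, flat plates, empty value
  lists and zero denominators raise typed errors.

## Problem sizes

The analysis drivers and tests run phantoms at 64³ (the acceptance-scale
grid, ~80 k brain voxels, ~15–20 s per phantom on one core thanks to the
batched fitting) and 24–32³ for unit-scale checks; the Monte-Carlo
studies use 100 plate replicates, 200 cohort replicates and 100
round-trip parameter sets.

## Known limitations

- The accumulation-lobe and decay terms can trade off against each other
  on short schedules; individual parameters (especially x3, x4) are far
  less identifiable than the Dyn/TT/AOT summaries, which is why only the
  summaries are thresholded and reported.
- With 8 frames and 5 parameters, r² is an optimistic goodness measure;
  the classification relies on the Dyn and cluster filters to reject
  noise, and ~8 % of detected voxels on noisy phantoms are halo voxels
  adjacent to true clusters.
- The exponential AOT fit is a summary, not a generative claim: bins
  beyond the last nonempty bin are ignored, and the fitted τ depends
  mildly on bin width.
- Growth-rate and plate generators draw independent normals; real
  cohorts/plates have correlated errors (shared scanner/passage effects)
  that the power estimates ignore.
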