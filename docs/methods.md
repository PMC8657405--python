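# Methods

This note documents the models, numerical choices and limitations of
`ventriflow`'s LV flow-component analysis and its synthetic verification
phantoms.

## Velocity fields and geometry

A `VelocityField4D` holds one cardiac cycle as a
`(frames, nx, ny, nz, 3)` array in cm/s with voxel spacing (mm), frame
duration (ms) and the velocity-encoding limit VENC (cm/s). World
coordinates are RAS mm; the voxel `(i, j, k)` has its centre at
`((i,j,k)+0.5)·spacing`; frames tile the R-R interval cyclically. Velocity
sampling is trilinear in space and linear in time with cyclic wrap — the
single interpolation contract shared by the tracer, the flux integrator
and the phantom oracles, so all stages see the same continuous field.
Positions outside the grid hull sample zero by default ("hold" clamps to
the edge instead); the defaults reflect that blood outside the imaged
volume is simply unknown, and a particle that leaves the hull is flagged
aberrant rather than silently advected.

## Pathline tracing

Fixed-step classical RK4 with `substeps_per_frame = 8` (≈4 ms steps at
typical 25–35 ms frames). A fixed step keeps runs bit-reproducible and
makes the convergence order directly testable: on the solid-body rotation
phantom — whose linear-in-space velocity is represented *exactly* by
trilinear interpolation — halving the step shrinks the endpoint error by
2⁴ (measured order 4.0), and one full revolution at 32 substeps/frame
returns every particle to its seed within 1.2e-8 voxels.

After every step each valve plane (geometry of the nearest integer frame)
is tested for a segment–orifice intersection: a crossing requires strictly
opposite signed distances (an endpoint exactly on the plane counts toward
the moving side) and an intersection point inside the disc or polygonal
orifice. A particle freezes at its first crossing of either valve, which
prevents re-entrant double counting; simultaneous candidates resolve by
the earlier interpolated crossing time. Aberrance: leaving the grid hull,
sampled speed above `1.5 × VENC`, or non-finite positions. Aberrant seeds
are excluded from the component ratios by default; the alternative policy
folds them into residual volume (blood that never demonstrably crossed a
valve), both are exposed because vendor behaviour is not observable.

## Component classification

Seeds are emitted from every LV-mask voxel centre at end-diastole, traced
backward to the IVR frame and forward to end-systole. *Entered* = the
backward trace crossed the mitral plane; *ejected* = the forward trace
crossed the aortic plane; the four combinations give DF / RI / DE / RV.
Seeding at end-diastole is the only frame from which a single seed set
identifies all four components with one backward and one forward trace.
Ratios are expressed relative to the total classified (mapped) volume
rather than the cine-derived EDV — the mapped volume is what the tracer
actually accounts for, and the inflow/outflow QC gap
`|DF+RI − (DF+DE)| / max(...)` (default threshold 0.15, aberrant-fraction
threshold 0.10; both package choices) is meaningful on that denominator.
Volumes in ml are also reported, so an EDV-denominated ratio can be formed
externally when a cine EDV is available.

## Phase detection

The IVR (diastole-onset) frame minimises `|Q_mitral| + |Q_aortic|` after
the aortic systolic peak, searching cyclically up to *renewed* mitral
inflow — the mitral flow must first dip below 10% of its peak before a
rise ends the window, so geometries with late-systolic mitral-plane flux
do not truncate the search; ties break toward the earlier frame.
End-diastole comes from the LV-volume maximum when per-frame masks exist;
the fallback (the frame where the contiguous mitral inflow wave falls back
below 10% of peak) is a heuristic meant for single-wave inflow patterns
and can end early on strongly biphasic E/A waves — masks are preferred.
End-systole equals the IVR frame under cyclicity.

Transvalvular flux integrates `v·n` on a 1 mm in-plane lattice (below
acquisition resolution) over the orifice and multiplies the mean normal
velocity by the exact orifice area, making the uniform-flow case exact.

## Preprocessing

*Phase offset.* Eddy-current background offsets are fitted per velocity
component as a spatial polynomial (default degree 1, configurable 0–3) to
the time-averaged velocity of static-tissue voxels by least squares, and
subtracted everywhere. Concomitant-field (Maxwell) residuals cannot be
separated without the sequence's gradient waveforms and are deliberately
folded into the same polynomial. The fit demands ≥10 static voxels per
coefficient and raises on rank-deficient mask geometry.

*Anti-aliasing.* A voxel moves by ±2·VENC when that brings it closer to
the median of its six face neighbours, iterated up to five sweeps. This
single-wrap local vote needs an unwrapped anchor adjacent to every aliased
region: isolated wraps and wrapped filaments/sheets bordered by unwrapped
flow recover exactly (the phantom round trip restores a corrupted field to
1e-14 cm/s RMS), but a region that wraps uniformly together with all its
neighbours is unrecoverable by *any* local criterion — such data need
global unwrapping and are out of scope.

## Synthetic phantoms

*Tube* — uniform axial flow through a straight segment between entry
(mitral) and exit (aortic) planes. A seed at depth z₀ enters iff
z₀ < n_diastole·speed and ejects iff z₀ > length − n_systole·speed, giving
closed-form fractions (60/20/20/0 at the 8/8-frame, speed-1 configuration;
0/50/50/0 at 5/5). By default the speed carries a per-phase raised-sine
time profile that vanishes at the phase boundaries and the flow is gated so
the mitral plane carries flux only in diastole and the aortic plane only in
systole; per-phase displacement integrals are preserved exactly and the
piecewise-linear-in-time field is integrated *exactly* by RK4, so the
closed form survives to machine precision through the whole pipeline.

*Rotation* — solid-body rotation, closed streamlines, never crosses a
valve: 100% residual volume, plus analytic circular orbits for integrator
accuracy checks.

*LV* — a half-ellipsoid chamber (base up, apex down, long-axis/short-axis
ratio 2.6) whose volume follows a raised-cosine filling/ejection curve
between ESV and EDV; defaults EDV 160 ml, ESV 62 ml, 20 frames over a
900 ms cycle at 2 mm spacing match healthy-adult chamber volumetrics. Per
frame the interior velocity solves a discrete pure-Neumann Poisson problem
(conjugate gradients on the chamber voxels) whose divergence equals the
uniform volume-rate compensation plus a concentrated source/sink on
mitral/aortic orifice voxels at the base — a potential-flow construction
chosen for simplicity, *not* for physiological realism: its ground truth is
therefore computed by an independent dense forward-Euler advection oracle
(100 substeps/frame) with separate crossing bookkeeping, at build time,
before the main tracer ever runs. The default tracer reproduces the
oracle's fractions within 0.1 percentage points (acceptance bound: 2).
Because the potential flow decays away from the orifices, apical blood is
nearly stagnant and the phantom's residual-volume fraction (~62%) is far
above in-vivo values (~8%) — the phantom validates *tracing and
classification*, not hemodynamic realism. Likewise none of the phantoms
contain measurement noise textures, turbulence, wall motion artifacts or
segmentation error, so green tests demonstrate algorithmic correctness on
idealized fields, not robustness to all properties of patient data.

*Corruption model* — polynomial phase offset (cm/s per mm^k), seeded
Gaussian velocity noise, and a single phase wrap
`v ↦ ((v+VENC) mod 2·VENC) − VENC`, with inputs restricted to |v| < 3·VENC
to match the single-unwrap correction scope.

*Cohorts* — per-subject DF/RI/DE/RV fractions drawn from an independent
multivariate normal at the two groups' published means ± SDs (controls
n=30: 50.0/23.5/18.6/8.0 ± 12.2/5.8/5.7/3.8; PAF n=50:
44.5/25.3/21.6/8.7 ± 11.2/5.5/5.6/4.1), truncated at zero and renormalised
to sum to 100 — chosen over a Dirichlet/logistic-normal because it matches
reported means and SDs directly; the truncation bias is <0.2 points at
these moments. Demographics use normal draws with median/IQR summaries
converted via IQR/1.349; BSA is computed from the drawn height and weight
with the Du Bois formula (0.007184·W^0.425·H_cm^0.725), which reproduces
the cohort's median BSA of 1.99 m² from its median height (1.77 m) and
weight (81.5 kg).

## Cohort statistics

Continuous two-group comparisons are gated per variable by Shapiro–Wilk at
α = 0.05 in *both* groups: t-test with mean ± SD reporting when normal,
Mann–Whitney U (normal approximation with tie correction; exact for
n ≤ 12 without ties) with median [Q1–Q3] otherwise. The t-test is pooled
by default with a Welch option — the published age comparison matches the
Welch variant while the flow-fraction comparisons match the pooled one, so
both are exposed. Chi-square omits the Yates correction (which reproduces
the published sex-ratio p of 0.902 exactly). No multiple-testing
correction is applied, mirroring the source analysis. The full gated
pipeline's type-I error, measured over 1000 seeded null replicates at
n = 30/50, is 0.05–0.06.

Propensity matching fits a logistic model of group membership on
standardized covariates (constant columns dropped), then greedily pairs
treated subjects in seed-randomized order with the nearest unclaimed
comparison subject within a caliper of 0.2·SD(logit) — the standard
convention. Balance is summarised as standardized mean differences with
the pooled-variance denominator. At the study's group sizes (~18–28 pairs)
a one-dimensional score cannot pin down three covariates individually, so
single-draw post-match SMDs scatter to ~0.1–0.3 from sampling noise alone;
the *balance property* of the implementation is therefore assessed on a
cohort with the same Table-1-like covariate shift at ten times the group
sizes (300/500, ~280 pairs), where every post-match |SMD| falls below 0.1.
The matched-pair count at study scale (≈18–28 depending on the draw) is
reported alongside.

OLS regression (with intercept) reports the overall F, degrees of freedom,
R² and p in the conventional `F (k, n−k−1)` format; rank-deficient designs
raise an error naming the collinear columns. CHA₂DS₂-VASc follows the
standard additive rule (CHF/LV dysfunction 1, hypertension 1, age ≥75 2,
diabetes 1, stroke/TIA 2, vascular disease 1, age 65–74 1, female 1).

## Problem sizes and determinism

The acceptance script and test suite run the tube phantoms at
10×4×4-voxel LV segments (160 seeds), the rotation phantom at radius 10
voxels (1264 seeds), and the LV phantom at 2 mm / 20 frames
(~20 000 seeds, dense oracle at 100 substeps/frame, ≈70 s total); unit
tests use a coarser 3 mm / 12-frame LV build. Monte-Carlo sizes: 1000
replicates for test calibration, 10 000 subjects for cohort moment
recovery, 300/500 for matching balance. All stochastic stages accept an
explicit seed, phantom construction is fully deterministic, and repeated
pipeline runs with the same configuration produce byte-identical outputs
(the embedded configuration hash excludes output paths).

## Known limitations

- Valve planes are inputs (static or per-frame); automatic valve
  recognition from cine images is out of scope.
- Crossing tests use the plane geometry of the nearest integer frame; no
  sub-frame plane interpolation.
- Single-wrap anti-aliasing only; uniformly aliased regions are
  unrecoverable locally (see above).
- Maxwell terms are not separately corrected (no gradient-waveform
  access).
- The LV phantom is a continuity-consistent flow construction, not a
  hemodynamic simulation; no turbulence, non-Newtonian rheology or
  fluid–structure interaction anywhere.
- The regression and matched-cohort outputs of a real study are not
  numerically reproducible without the underlying per-subject data; the
  procedures are implemented and simulation-tested instead.
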