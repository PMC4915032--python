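# Methods

This note documents the models behind spinemetry: what the synthetic
data emulate, how each measurement operator works, the numerical choices
involved, and where the approximations break down.

## Synthetic spine populations

A spine is modelled as a neck tube (cylinder of diameter w, arclength L,
optionally curved as a circular arc with configurable sagitta) attached
to the surface of a dendritic shaft (cylinder, default radius 0.35 μm),
carrying a spherical head (diameter d). The path from the dendrite base
through the head centre to the distal head edge has length L + d, which
is the operational spine length.

Per-group parameters (`GroupMorphParams`) give means and standard
deviations of neck length, neck width and head width plus the spine
density. Two presets are built in, for wild-type and APP/PS1-like
populations (all μm):

| group | spine length | head width | neck length | neck width | density /10 μm |
|---|---|---|---|---|---|
| wt | 0.82 | 0.44 | 0.38 | 0.160 | 11.5 |
| APP/PS1 | 0.81 | 0.49 | 0.32 | 0.165 | 8.7 |

Spine length is derived (neck + head), so its mean follows from the neck
and head means. Head-width and spine-length dispersions are set to
s.e.m.·√n reconstructions of published group summaries (sd ≈ 0.17 and
0.35 at n ≈ 300); the neck-length sd is chosen so the derived
spine-length sd matches (≈ 0.30 by quadrature); the neck-width sd
(0.04 μm, CV ≈ 25%) is a realistic choice, as no dispersion is published
for it. The APP/PS1 neck width (0.165) is calibrated once, by a 2-million
draw run of the sampler, so that the APP/PS1 group-mean
compartmentalization factor equals the wt mean: the larger heads and the
shorter, wider necks cancel. This is the defining property of the
preset pair, and group-level analyses on synthetic data reproduce it.

Features are drawn from *moment-matched* left-truncated normals: the
truncated distribution itself has the requested mean and sd (underlying
parameters solved from the standardized truncated-moment identities),
with a physical floor of 0.05 μm. Two consequences worth knowing:

- a left-truncated normal requires (mean − floor)/sd > 1; dispersions
  violating that are rejected (`ParameterError`) rather than silently
  clipped. The APP/PS1 neck-length sd is capped at the wt shape ratio
  (0.243) for this reason.
- `head_width > neck_width` is enforced by resampling the neck width
  only, so the head-width marginal — the quantity whose distribution is
  compared across groups — is exactly the requested one.

Attachment points are uniform along the dendrite (so branch-level counts
are binomial at the requested density); spines alternate sides and tilt
by ±15° around perpendicular by default.

## Rendering model

A voxel reads the binary occupancy of the geometry convolved with an
anisotropic Gaussian PSF (lateral FWHM 0.050 μm, axial 0.600 μm —
super-resolution laterally, conventional axially), scaled so the peak
equals `photons_per_peak`, offset by a background, and noised (Poisson,
optionally plus Gaussian read noise). Acquisition geometry defaults to
40 nm × 40 nm pixels and 10 z-sections at 192 nm.

Occupancy is rasterized at 4× sub-voxel resolution in all axes before
convolution; at the default settings a 0.10 μm neck spans ten lateral
sub-voxels and structures thinner than ~25 nm axially may rasterize to
nothing. Rendering is deterministic with noise disabled and seeded
otherwise; intensity is linear in `photons_per_peak`.

There is no STED photophysics (depletion profile, bleaching) in the
model: the image formation is "fluorophore density ⊗ Gaussian PSF",
which is the level of realism the measurement operators are sensitive
to. Real tissue adds background structure, out-of-focus contamination
and anisotropic labelling that this generator does not emulate, so
passing recovery tests here demonstrate correctness of the measurement
chain, not field performance.

## Measurement operators

All measurements run on the lateral maximum-intensity projection; the
axial direction (192 nm sampling, 0.6 μm PSF) carries no usable width
information.

**Tracing.** The centerline is traced on a Gaussian-smoothed copy
(σ = 1 px) by a guided 8-connected walk from the annotated base seed to
the head hint: each step moves to the brightest above-threshold
neighbour that does not increase the distance to the hint, with
backtracking out of dead ends. The connectivity threshold is 10% of the
background-subtracted head peak — thin necks can dip below 15% of the
head's brightness, so a single half-maximum threshold would disconnect
them. Beyond the hint, the distal head edge is found by casting a ray
along the spine axis and interpolating the half-maximum crossing
(`edge_threshold_rel` = 0.5): a pixel walk would quantize the edge and
zigzag across the flat head plateau. The pixel path is smoothed by two
passes of a 9-point moving average (~0.36 μm support) before arclengths
are taken; without this the staircase of an 8-connected walk inflates
arclength by up to ~8%.

**Spine length** is the polyline arclength from base to the distal
half-maximum edge.

**Neck/head boundary.** Model-free local widths (half-maximum spans of
profiles orthogonal to the path) are scanned along the path. The default
estimator (`boundary_method="sphere_end"`) places the junction
(1 + √3/2)·r before the distal end, where r = w_max/√3 and w_max is the
median of the three widest profiles: for a spherical head the projected
half-maximum span through the centre is √3·r and the distal half-maximum
cap extends (√3/2)·r past the centre. The published-style threshold rule
— first position whose width exceeds 1.5× the running neck estimate — is
available as `boundary_method="width_threshold"` (with interpolated
crossing and a sphere-chord pullback), but it is blur-delayed at the
junction by 0.05–0.12 μm, a +10–30% bias on typical necks, which is why
it is not the default.

**Widths.** Neck width is the mean FWHM of least-squares Gaussian fits
(offset + amplitude·exp(−(x−c)²/2σ²); FWHM = 2√(2 ln 2)·σ) to three
profiles at evenly spaced neck arclengths, each orthogonal to the local
tangent, sampled by bilinear interpolation at half-pixel spacing;
non-converged fits (solver failure, relative residual > 0.2, edge peaks)
are excluded and counted. Head width is the FWHM through the head
intensity maximum, orthogonal to the neck axis.

**Apparent vs physical widths.** Because the structures are much thinner
than the axial PSF, the lateral profile of a filled tube or sphere takes
the z-projected chord shape (a half-ellipse, saturated by the finite
axial PSF), not a top-hat. A Gaussian fit to that shape convolved with
the lateral PSF returns only ~70–85% of the physical diameter. The
default (`width_correction="none"`) reports this apparent width — the
convention of the imaging literature the package follows. When physical
diameters are wanted (e.g. parameter-recovery validation, volume
estimates), `width_correction="projection"` inverts the full forward
model: erf-saturated chord ⊗ lateral PSF ⊗ pixel integration ⊗ bilinear
kernel → Gaussian-fit FWHM, tabulated and inverted by interpolation. A
quadrature correction (√(w² − w_psf²)) is also available but assumes
Gaussian-on-Gaussian blur and does not address the projection effect.

On 50 rendered wt-preset spines with Poisson noise (peak SNR ≈ 30),
median absolute relative errors are typically 3–5% (spine length), 5–9%
(neck length), 5–12% (neck width, corrected) and 2–4% (head width,
corrected). Individual spines with necks shorter than the base-exclusion
zone (~0.12 μm) or thinner than ~0.07 μm may be unmeasurable or carry
large errors; they are flagged, not silently dropped.

## Compartmentalization

cf = V·L/A with, by default, V = π/6·d³ (spherical head from head width)
and A = π/4·w² (circular neck cross-section). Both estimators are
explicit model choices; absolute cf values therefore carry this model's
scale and should be compared within the pipeline, not against published
cf numbers whose volume/area estimators are unstated. The invariances do
not depend on the scale: cf is preserved under compensating morphology
changes (the cancellation property, exact to machine precision) and
scales as length² under uniform geometric scaling.

The mapping cf = τ·D is verified against a 1D finite-difference oracle:
a neck column (≥ 50 cells, half-spacing end couplings so the total
diffusive resistance is exactly L/(D·A)) couples a well-mixed head of
volume V to a reservoir fixed at concentration 1. The explicit update is
run under the stability bound dt ≤ 0.2·dx²/D (enforced); the repeated
step is composed by binary exponentiation between recorded samples, so
long runs cost milliseconds while remaining the same explicit scheme to
rounding. Fitting 1 − e^(−t/τ) to the recovery gives τ within 10% of
VL/(AD) whenever the neck holds little volume (A·L/V ≤ 0.1; the
acceptance grid shows ≤ 5%). For A·L/V ≳ 1 the single-exponential
reduction fails by design (> 10% deviation) — the regime limit is
asserted in the tests rather than hidden.

## Statistics

The two-group workflow mirrors common practice in the field: both
samples are screened with the D'Agostino & Pearson omnibus test (K² =
Z²_skew + Z²_kurt against χ²(2); requires n ≥ 8, smaller samples route
to the nonparametric branch); if both pass, a two-sided unpaired
Student's t-test (classic equal-variance; Welch by flag), otherwise a
two-sided Mann–Whitney test (exact enumeration for tie-free samples up
to n = 20, normal approximation with tie correction beyond). The
two-sample KS test reports D = sup|ECDF_ref − ECDF_sample| with the
asymptotic Kolmogorov p at effective size n₁n₂/(n₁+n₂), or the exact
permutation null for pooled sizes ≤ 16. A Wilcoxon matched-pairs test on
raw values completes the workflow. Sidedness is two-sided throughout.
Under the null the gated comparison rejects at 5.0 ± 0.5% over 10⁴
simulations. Multi-factor ANOVA with post-hoc corrections is out of
scope; the pipeline exports tidy group tables for any stats environment.

## End-to-end experiment

`run_full_synthetic_experiment` samples both preset groups (default 250
spines each), renders each spine as a small patch stack (Poisson noise),
measures blind to ground truth, computes per-spine cf from the measured
widths, and compares the groups feature-by-feature (gated test + KS with
the first group as reference; density at branch level over 8 branches).
A single seed fans out to per-stage child seeds via
`numpy.random.SeedSequence` spawning; reruns are byte-identical and all
output tables carry the configuration hash.

At these settings the run reproduces the qualitative pattern the presets
encode: the head-width distributions separate (KS p < 0.05 in ~3 of 4
seeded runs; the effect is a 0.05 μm shift against a 0.17 μm sd, so
power at n = 250 is ~77%) while the cf distributions do not (p > 0.05 in
~94% of runs). Measured neck-width group differences of ~0.005 μm are
below what the measurement chain resolves and may even invert sign —
a known limitation, documented rather than tuned away.

## Quantification indices

All electrophysiology indices use magnitudes (raw EPSCs are inward).
LTP magnitude is the post-window (30–40 min after induction) mean of
amplitudes normalized to the 8-min pre-induction baseline, ×100; the
sweep at the induction time belongs to the post epoch (half-open
baseline window). PPR = amp2/amp1 of averaged paired responses;
NMDAR/AMPAR ratio = |I_NMDAR|/|I_AMPAR|·100; the tonic shift is the
difference between the last minute of baseline and the last minute of a
6-min antagonist application. Displacement index =
T_novel·100/(T_novel + T_familiar); novel-arm fraction = novel-arm
time/total·100. Specific binding = (total − nonspecific)/mg protein,
with negative duplicate-noise differences clipped to zero and flagged;
duplicates are averaged. The behaviour generator draws total exploration
from a gamma and splits it by a Beta with mean equal to the group
preference, so expected indices equal the preset percentages exactly.

## Problem sizes

Defaults were chosen so a full validation is quick on one CPU: 50 spines
for recovery studies (~10 s), 250 spines/group for the two-group
experiment (~25 s), 27 geometries for the diffusion-oracle grid
(< 1 s), 10⁴ simulations for the type-I-error check (~20 s).
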