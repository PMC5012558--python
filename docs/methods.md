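# Methods

This note documents the phantom model, the measurement algorithms, the
default parameter choices and the known limitations of `aosoct`.

## Coordinate and unit conventions

Volumes are indexed `(y, x, z)`: `y` is the circumferential axis (one
B-scan per position, along Schlemm's canal), `x` the lateral axis within a
B-scan (one A-line per position), `z` depth. MB-mode series are indexed
`(t, x, z)` at one fixed `y`. Lengths are µm, pressures mmHg, volumes nL
(1 nL = 10⁶ µm³), times ms, velocities µm/ms. Voxel pitch is
field-of-view / sample-count per axis.

The default scan protocol is 512 B-scans × 360 A-lines × 1024 depth samples
over a 2000 × 3000 × 2200 µm field (pitches 3.91 / 8.33 / 2.15 µm), MB-mode
at 200 B-scans/s for 7 s (1400 frames, 5 ms interval). The theoretical
axial resolution of a Gaussian-spectrum source is
(2 ln 2/π)·λ₀²/Δλ; the default source (1340 nm / 110 nm) gives 7.20 µm in
air.

## Phantom model

Each noiseless B-scan is a layered reflectivity map: a dark fluid layer
above the tissue, a bright trabecular-meshwork (TM) band with a sinusoidal
lamellar texture, and sclera whose intensity decays exponentially with
depth. Three dark lumens are carved into it:

* **SC** — an ellipse (default aspect 8:1, width:height) pressed against
  the TM's outer wall. Its cross-sectional area varies sinusoidally along
  the circumference (integer number of periods, so it integrates exactly to
  the target volume).
* **CCE** — a rectangular channel breaching SC's outer wall over a limited
  circumferential span, partly covered by a thin bright collagen flap. The
  uncovered part of the ostium leaves SC and CCE as one connected fluid
  space — deliberately, since that is the hard case for segmentation.
* **ISCC** — a circular intrascleral channel at fixed depth.

**Pressure–volume law.** SC volume follows a saturating exponential
`V(P) = v_min + (v_max − v_min)(1 − exp(−P/p_eff))`, with
`p_eff = p_half` on the ascending limb and `p_half/hysteresis_factor` on
the descending limb, so at equal pressure the descending volume is larger
(hysteresis) whenever the factor exceeds 1. CCE channel length and ISCC
area scale with the normalized opening fraction `1 − exp(−P/p_eff)`.
Defaults: `v_min 0.5`, `v_max 15` nL, `p_half 20` mmHg, factor 1.5. At
0 mmHg SC is a near-closed potential space (≈6 µm high, below what the
segmentation can resolve) — intended behavior, not a bug.

**Dynamics.** After a step pressure change at `switch_time`, the lumen
height (and opening fraction) follows a first-order response with time
constant `tau` (default 15 ms). The ground-truth onset frame is the first
frame whose height differs from baseline.

**Noise.** Multiplicative gamma speckle with `L` looks (shape `L`, mean 1;
default `L = 4`, i.e. 50 % relative std) plus a small additive Gaussian
floor, clipped at zero; `noiseless=True` disables both. All randomness
comes from `rng_seed`; truth masks are noise-free and identical across
seeds.

**Deliberate non-emulations.** No depth-dependent speckle decorrelation,
no shadowing/signal dropout below strong reflectors (the default
attenuation coefficient, 2×10⁻⁴ /µm, is chosen so that deep sclera stays
distinguishable from lumen — with realistic stronger attenuation, deep
tissue falls below any lumen threshold and intensity-based segmentation
alone cannot separate them), no lateral PSF blur, no refraction, no motion
artifacts, no hinged-flap mechanics beyond a static partial cover.

## Segmentation

Semi-automatic: one user seed per structure (`SC`, `CCE`, `ISCC`) on a
reference plane; the tests and pipeline derive seeds from the truth-mask
centroids, playing the role of the operator click.

Per plane: (1) Gaussian pre-smoothing (σ = 1 voxel); (2) TM-top surface
detection per A-line (first sample above the midpoint of the robust 5–95 %
intensity range, invalid columns interpolated, running-median smoothing) —
every mask is clipped strictly below this surface because the mounting
fluid is as dark as the lumens; (3) a local threshold from the
(2·12+1)² window around the seed — by default an **Otsu** bimodal split,
which tracks the lumen/tissue boundary regardless of how much of the
window the lumen fills (a fixed-quantile alternative,
`threshold_method="percentile"`, is retained but lands inside one class
whenever the window is lumen-dominated or lumen-free); (4) region growing
over the connected sub-threshold component at the seed; (5) morphological
opening + closing (radius 1); (6) guards: the seed must itself be dark
relative to the window's bright class (an Otsu split of a lumen-free
window merely bisects speckle noise and must not seed growth), regions
larger than 25 % of the plane are treated as threshold leaks, and regions
under `min_region` (25 voxels) are reported empty — an empty mask is a
legitimate result for a closed lumen.

**Connected lumens.** When two seeds grow into the same component (SC and
CCE through the uncovered ostium), a marker-based watershed on the
smoothed intensity splits the union along the bright ridge between them.
Seeding every visible structure is therefore recommended; with only an SC
seed the measured SC mask will include the connected channel.

**Propagation.** From the reference plane outward (both directions for a
spatial sweep; forward from frame 0 for MB-mode), each lumen is re-seeded
on the next plane at the *darkest voxel of that plane inside the previous
plane's mask footprint*. A raw centroid is not used because the centroid
of a non-convex mask (e.g. SC + channel) can fall on bright tissue between
lumens, which poisons all subsequent planes. In a spatial sweep, a run of
more than `max_gap` (20) consecutive empty planes stops that structure's
propagation (with a warning for SC). In MB-mode the scan position is
fixed, so by default no gap limit applies: a lumen closed for hundreds of
baseline frames is recovered at the same position once the pressure step
opens it, and an empty reference frame falls back to the original seed
position.

## Geometry

Area = voxel count × pitch_x × pitch_z. Height = the tallest per-column
count of lumen voxels × pitch_z (counting voxels, not the bounding box,
for robustness to oblique walls). Area profiles resample per-B-scan areas
by linear interpolation onto a uniform 10 µm grid over the 2000 µm
circumference (201 points; grid points beyond the last B-scan hold the
nearest value). Volume is the trapezoidal integral of the profile,
converted at 1 nL = 10⁶ µm³.

## Elastance

Pressure is regressed on volume with a low-order polynomial (default
degree 2) because dP/dV is the quantity of interest; the fitted
polynomial's analytic derivative is the local elastance. On noiseless
samples of the truth law over 0–30 mmHg, a degree-3 fit reproduces the
analytic elastance `p_half/(v_max − V)` within 10 % over the central 80 %
of the sampled volume range; over wider sweeps (to 50 mmHg the analytic
elastance rises ~12-fold) no single low-order polynomial tracks it to that
tolerance, so fits should be interpreted over the sampled range only.
Hysteresis between ascending and descending limbs is summarized by the
trapezoidal loop area between the two V(P) branches over their shared
pressure interval and by the mean volume excess of the descending limb;
both are positive iff the truth law is hysteretic.

## Dynamics

Height traces are uniformly sampled at the frame interval. Onset is the
first frame whose height departs from the pre-switch baseline mean by more
than k·σ (k = 3, baseline ≥ 20 frames) sustained for 3 consecutive frames.
Response time runs from the reference frame (onset − 1) to the first frame
at ≥ 95 % of the plateau change, the plateau being the mean over the final
1000 ms of the record; for a τ = 15 ms first-order response this is ≈ 45 ms
(3τ) plus frame quantization. Maximum velocity is the largest magnitude of
a Savitzky–Golay derivative (window 5, order 2) after onset; note that for
responses fast relative to the window (τ ≈ 3 frame intervals) the smoothed
peak underestimates the analytic peak (h₁−h₀)/τ by roughly half, while for
τ ≫ frame interval it is within ~10 %. Synchrony reports pairwise onset
lags across structures.

## Statistics

ANOVA F and Tukey(-Kramer) q are computed from their definitional sums of
squares in-module; tail probabilities come from scipy's F and
studentized-range distributions (numerical integration, no table lookup).
The suite cross-checks both against `scipy.stats.f_oneway` and
`scipy.stats.tukey_hsd` as independent oracles. Conventions: α = 0.01 for
ANOVA and regression, α = 0.05 for pairwise comparisons. Polynomial r²
comes with an overall-regression F-test; boxplot summaries use 1 %/99 %
whiskers and numpy's linear-interpolation quantiles.

## Validation studies and problem sizes

`aosoct.validation` derives every random draw from one root seed through
`numpy.random.SeedSequence.spawn` (children reduced below 2³¹), so a
single integer reproduces each study. The studies reduce only the
circumferential B-scan count (128 instead of 512) and, for the step
response, the record length (4 s instead of 7 s, keeping the 200 B-scans/s
rate and the full 360 × 1024 B-scan size the segmentation works in); these
are runtime choices, and the default protocol remains available
end-to-end. Representative results (root seed 1): replicate SC-volume
deviation 0.21 % across 10 noisy replicates at 30 mmHg; measured step
response 50 ms on a τ = 15 ms phantom (other seeds: 5–35 ms); minimum
quadrant r² 0.988 across 14 simulated quadrants.

## File formats

Images are multi-page TIFF (one page per B-scan/frame) with a JSON sidecar
holding pitches, pressure/timing, protocol, parameters and seed; label
masks are 8-bit TIFF with codes 0/1/2/3 = background/SC/CCE/ISCC; tables
(area profiles, pressure–volume curves, height traces) are CSV. The
pipeline manifest records the merged config, seed, package version and
SHA-256 of every output.
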