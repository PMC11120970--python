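# Methods

This note describes the models, conventions and design choices behind
axoplast, in the spirit of a methods appendix: what each procedure assumes,
which parameters matter, what the synthetic generator does and does not
emulate, and where the numerical edges are.

## Coordinate and sampling conventions

All profiles and scenes live on the camera grid: physical position = pixel
index × `pixel_size_nm` (default 40 nm, the SIM camera pixel), with
position 0 at the path origin — the soma end of an axon path. Profiles are
uniformly sampled, positions in µm, intensities in arbitrary units.
Because peak positions are reported on the grid, *every* distance the
periodicity module emits is an exact multiple of the pixel size; this
quantization is a property of the measurement, not an artifact to be
smoothed away, and several closed-form expectations below are stated on
the grid rather than in the continuum.

## AIS boundary detection

The ankyrinG profile is smoothed with a centered rolling average
(`window_um = 3`, converted to an odd pixel count). At the edges the
window shrinks **symmetrically** (half-width `min(h, i, n−1−i)`): a
symmetric mean preserves linear trends exactly, so a ramp is a fixed point
of the smoother everywhere, including its endpoints. The smoothed trace is
min–max normalized and the boundary rule applied: the maximum is the
leftmost global maximum (a plateau reports its proximal edge); scanning
outward, the boundary is the first sample with normalized value ≤ 0.33
(closed inequality, no sub-pixel interpolation — detection is quantized to
the grid exactly like the reported distances). A side that never reaches
the cutoff is truncated at the profile end and flagged; truncated AISes
should be excluded from length statistics. The procedure is invariant to
affine intensity transforms a·I + b (a > 0).

Axon width uses the raw (unsmoothed) transverse profile and a threshold of
0.33 × max — max only, no baseline subtraction — because its job is to
separate axon from background. The closed ≤ rule lands ~half a pixel
inside the true crossing on each side, a ≤ 1-pixel inward bias that is
visible in the synthetic width benchmark.

## Synthetic ankyrinG profiles

The generator must produce profiles whose *detected* boundaries equal the
requested truth. A logistic-edge shape cannot do this: a centered moving
average of width W shifts a logistic's 0.33-crossing by ≈ (W²/24)(1−2c)/k,
which for W = 3 µm exceeds one 40 nm pixel for any edge scale steep enough
to form a plateau. The shape used instead is piecewise linear — baseline,
linear rise, shoulder at 0.98, symmetric apex tent at the maximum
position, shoulder, linear fall, baseline — with the rise and fall
arranged to cross the normalized 0.33 level exactly at the requested
start/end and to remain linear for ≥ 1.6 µm on both sides of each
crossing. Since the symmetric smoother preserves linear segments and the
near-apex shoulder (0.98) keeps the smoothed maximum within 0.5 % of the
apex, the smoothed-and-normalized crossing stays at the construction
position to well under one pixel. The apex tent makes the maximum unique
and centered. Baseline is 5 % of the amplitude; Gaussian noise (optionally
Poisson) is added on top and clipped at zero. Signal-to-noise ratio is
defined as (peak − baseline)/σ.

Control-condition defaults are start 4.5, max 13.6, end 26.9 µm (length
22.4 µm); profiles carrying them must extend past the AIS end, so the AIS
ordering is validated against the profile length at generation time rather
than at parameter construction (ring profiles and 20 µm scenes legitimately
use shorter rasters).

## Ring profiles and periodicity analysis

Ring profiles are sums of unit Gaussian bumps (σ = 40 nm) at integer
multiples of the ring spacing (default 190 nm, optional phase), on a
constant background (0.5) with amplitude 1; spacing must exceed twice the
pixel size. Local normalization subtracts a centered moving mean
(window 480 nm ≈ 2–3 periods; the window is a package choice) and scales
the residual to unit SD; residuals at float-rounding magnitude (constant or
linear inputs) are returned as zeros with a `constant` flag instead of
being amplified. Autocorrelation uses the biased estimator
r(k) = Σᵢ xᵢxᵢ₊ₖ / Σᵢ xᵢ², so r(0) = 1 and |r| ≤ 1; the significance bound
is the white-noise band 1.96/√n (for averaged curves, conservatively at
the per-profile n). The first local maximum above the bound is the
reported period; for 190 nm rings on the 40 nm grid this is the 200 nm lag
(5 pixels), matching the grid lag that maximizes overlap with the true
period.

Amplitude: highest acf local maximum with lag in 120–280 nm (symmetric
about 200 nm, excluding the short-lag noise region), minus the mean of the
nearest local minima on each side; no maximum in the band ⇒ the curve is
omitted; a missing right valley (band at the curve end) falls back to the
end value with a flag. On the grid the amplitude of an ideal 200 nm
cosine converges to 1 − cos(2π·2/5) ≈ 1.81, not 2, because the continuous
valleys at ±100 nm are not grid lags; a 160 nm period (valley on-grid)
attains 2. Peak detection uses prominence ≥ 0.3 in locally-normalized
units with ≥ 2 px separation (the prominence value is a package choice).
Spatial analysis assigns each ~2 µm segment to one of four half-open 5 µm
bins [0,5), [5,10), [10,15), [15,20) by its midpoint; midpoints outside
are excluded and counted.

## Scenes and the fiber detector

Scenes are 2D rasters (default 20 × 3 µm) with channels actin, ankyrinG,
puncta. The shaft has a Gaussian cross-section whose 33 %-of-max width is
`shaft_width_um` (default 0.95 µm); rings modulate the shaft axially;
fibers are straight segments with Gaussian cross-section (FWHM 120 nm,
SIM-like); puncta (σ 80 nm) are placed independently at each fiber end
with probability `puncta_end_prob`; an optional oblique 0.4 µm sinusoidal
stripe term emulates reconstruction artifacts. Fibers reaching outside the
raster are clipped, with a flag in the ground truth. All randomness
derives from a single integer seed; outputs are bit-identical across runs.

The random fiber placement enforces two physical constraints. First, a
fiber's entire transverse excursion stays within ±0.3 µm of the shaft
center — a fiber inside a ~1 µm axon that is long must be near-parallel
(steeper apparent angles in the source imagery generally indicated
extracellular structures). Second, fibers that overlap axially are placed
in lateral lanes ≥ 0.16 µm apart: two parallel fibers closer than the
~120 nm optical resolution are a single visible structure, so a generator
claiming N countable fibers must make N resolvable ones. Within these
constraints lengths are Gaussian (clipped to the countable 1–6 µm range;
default mean 3.0 µm, the control AIS value) and angles uniform.

Detection replaces the study's manual tracking with an automated
surrogate, validated only against synthetic truth: the image is convolved
with oriented difference-of-Gaussians line kernels (σ∥ = 6 px;
σ⊥ = 1.3 px matched to the fiber width, minus a σ⊥ = 4 px background
term) at seven orientations within ±45° of the shaft axis; at orientation
0 the kernel gives exactly zero response to any pattern uniform across the
shaft, which cancels the much brighter ring bands. The maximal response is
thresholded at median + 6 robust SDs (MAD-based, hence invariant to global
intensity scaling; the MAD is computed over the shaft rows), small objects
removed, and the mask skeletonized. Skeletons are broken at junction
pixels so touching fibers separate; each branch is vectorized by principal
axis into a straight two-point trace, extended by 1.5 px per tip to undo
skeleton end erosion (calibrated against generator truth). Traces whose
centroid leaves the shaft rows are dropped — the 2D stand-in for checking
intracellularity through the z-stack. Collinear traces with end gap
≤ 0.3 µm, orientation difference ≤ 15° and lateral offset ≤ 0.06 µm are
merged to a fixed point (the continuity rule: aligned segments with a
small gap are one fiber), then the counting rules filter survivors
(length ≥ 1 µm inclusive, angle ≤ 45° inclusive) and bin them into the
5 µm zones their axial extent overlaps.

On this generator the detector counts 0–6-fiber scenes within ±1 in ~92 %
of cases at SNR 5, with failures concentrated in 6-fiber scenes where
fibers still fuse; false positives on fiber-free scenes are ≪ 0.1 per
20 µm; mean fiber length is recovered within 0.1 µm on scenes sparse
enough (≤ 2 long fibers) that fusion does not truncate traces. These
numbers quantify the surrogate on synthetic data only — they say nothing
about agreement with a human tracker on real images, which is explicitly
out of scope.

## ADR and puncta scoring

ADR = mean marker intensity over AIS samples (positions in
[start, end], closed) divided by the pooled mean over the first 50 µm of
every dendrite; dendrites shorter than the extent are rejected rather than
silently included. The synthetic ADR phantom is deliberately minimal —
piecewise-constant marker levels whose true ratio is the configured
contrast (default 0.44, the control-like value; uniform ⇒ exactly 1).
A fiber is puncta-positive when any punctum lies within 160 nm (4 px) of
either end; the radius is a package choice.

## Statistics

`two_prop_test` implements the pooled-proportion chi-squared with Yates
correction, |p̂₁−p̂₂| reduced by (1/n₁+1/n₂)/2 and floored at zero, squared
over p̄(1−p̄)(1/n₁+1/n₂), with a two-sided p from χ²₁ — algebraically
identical to the Yates-corrected 2×2 contingency chi-squared and to R's
`prop.test`. Degenerate tables (pooled proportion 0 or 1) return p = 1
with a flag. KS is two-sided with asymptotic p. Mann–Whitney uses
mid-rank ties and the normal approximation **without** continuity
correction, so identical samples give p = 1 exactly. The chi-squared
family for count data tests pooled per-group totals against equal
expectation (the construction of the original per-cell test is not
specified; this reading is documented and swappable for a rank test).
Shapiro–Wilk per group and Levene across groups are reported alongside
every family; no multiple-testing correction is applied beyond
Tukey–Kramer within the ANOVA family. Under 1000-replicate null
simulations every implemented test rejects at 3–7 % at α = 0.05.

## Pipeline

A synthetic run maps condition labels to generator parameter sets,
analyzes `n_cells` per condition (AIS profile → boundaries; scene → fiber
counts/lengths/puncta; four ring segments, one per 5 µm zone → acf,
amplitude, inter-peak distances; marker profiles → ADR), and writes tidy
CSVs plus cross-condition comparisons (Kruskal–Wallis on AIS metrics and
ADR, chi-squared on fiber totals, KS and two-proportion tests on
inter-peak distributions). Every row carries the cell seed and a parameter
hash. The manifest's `content_hash` covers the scientific configuration
and summary (not the output directory or timings), so identical
config+seed ⇒ identical hash. Condition labels can be masked
(`group_A`, …) in all intermediate tables for blind analysis, with the
mapping stored in the manifest. Non-empty output directories are never
overwritten unless forced.

Per-cell seeds are derived deterministically from the run seed; all
library randomness flows through `numpy.random.default_rng`.

## Occlusion and noise-trend experiments

Two qualitative directions are checked end to end. (1) Fibers degrade
ring-periodicity readout: since a fiber running parallel to the profile
adds a slowly-varying term that local normalization removes, occlusion is
emulated through photon statistics — scenes are rendered photon-limited
(Poisson at 25 counts per intensity unit plus weak read noise), so rings
under a bright fiber (intensity 2.5) are shot-noisier and their peaks
register off-grid more often; clean scenes then show a higher proportion
of exactly-200 nm inter-peak distances than fiber-occluded ones.
(2) The acf amplitude of averaged ring profiles decreases strictly with
added Gaussian noise across σ = 0.05…0.8 (signal amplitude 1).

## Problem sizes

The validation experiments use 30–50 profiles for periodicity, 100
profiles for boundary recovery, 100 scenes for fiber counting, 40
fiber-free scenes for false positives, 15 scenes per arm for the occlusion
comparison, and 1000 replicates per null calibration; these sizes give
comfortable Monte-Carlo margins for every asserted bound while keeping a
full run in the low minutes on one core.

## Known limitations

* The fiber surrogate is validated on synthetic truth only; no claim is
  made about equivalence to expert tracking on real SIM images, and the
  subjective "clear at original brightness" inclusion rule is approximated
  by a prominence threshold.
* The generator does not model the optical PSF or SIM reconstruction
  beyond a stripe term; sub-resolution ring substructure, actin patches
  and trails, curved fibers, and 3D geometry are not emulated. Passing
  recovery tests therefore demonstrates correctness of the measurement
  procedures under the stated image model, not robustness to every real
  imaging condition.
* Real SNR and background statistics of the source data are unknown; the
  defaults (SNR 5, background 0.5) are tunable, not calibrated.
* Noise-free profile SNR is defined relative to signal amplitude; Poisson
  rendering changes the effective SNR with brightness, which is exactly
  the property the occlusion experiment exploits.
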