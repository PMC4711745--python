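# Methods

## Scope and model

`ivcyto` quantifies intratumoral nanoparticle pharmacokinetics and
pharmacodynamics from multi-channel 3-D (or 3-D + time) fluorescence
volumes with five possible channel roles: the particle **vehicle**, its
**payload** (a quenched pro-drug reporter that brightens on
activation), a nuclear DNA-**damage** reporter forming discrete puncta
at double-strand breaks, a **macrophage** label, and a **vascular**
tracer. All physical quantities are micrometres and minutes; axis order
is `(t,) c, z, y, x`, voxel positions are index × voxel size, and
anisotropic voxels are respected everywhere a distance is computed.

## Synthetic tissue generator

The generator is first-class, tested code: it defines the conditions
under which every estimator is validated.

**Geometry.** Nuclei are spheres with radius ~ Normal(4, 0.5) μm
truncated at 2 μm, placed by rejection sampling with minimum centre
separation 1.5× the mean diameter (12 μm) — this guarantees
watershed-separable ground truth and bounds the packing density;
placement failure after bounded retries is an explicit error, reached
at roughly 40 % of random-sequential-addition saturation. A Bernoulli
draw (default fraction 0.04) marks macrophages, whose bodies form
depot spheres of 7 μm diameter.

**Channels.** The payload field is `bg + c·exp(−d/λ)` with `d` the
Euclidean distance from the depot mask and `λ = 15 μm`; the exponential
kernel is chosen for a single interpretable length scale, the
enrichment itself having no published functional form. The scale `c`
is solved so that the mean over 0 < d < 15 μm is exactly
`depot_fold_amplitude` (default 3) times the mean beyond 30 μm, using
the same bin conventions as the proximity-profile estimator, so the
noise-free fold is 3 by construction. A de-quenching gain
`1 + (F−1)(1 − 2^(−t/t½,release))` (F = 7, t½ = 15 h, snapshot at
24 h) multiplies the payload in snapshot mode. The vehicle channel is a
diffuse background plus per-cell uptake bodies with lognormal
amplitudes (median 50 a.u., log-SD 0.8) and bright depot spheres
(200 a.u.) at macrophages: cell-to-cell uptake heterogeneity is what
makes the vehicle's spatial CV exceed the diffused payload's, the
ordering the analysis is designed to detect. The damage channel fills
each nucleus at 50 a.u. and adds one Gaussian spot (σ = 0.6 μm,
amplitude 150) per punctum, spots kept ≥ 3σ apart — above the
Laplacian-of-Gaussian two-point resolution `2σ√2` — within 0.75 of the
nuclear radius.

**Dose–damage link.** Per-cell puncta counts are Poisson with mean
`0.5 + 4.0 × dose`, where the dose is the clean payload averaged over
the nucleus in units of the near-depot target level (fold ×
background). With the defaults this yields means ≈ 2 in the far field
and ≈ 13 inside depots — discrete, countable foci. The linear-Poisson
link and the dose normalisation are modelling choices; only the
qualitative dose dependence of the damage response is empirically
grounded.

**Time-lapses.** Two straight vessels (4 μm radius cylinders) carry
`I₀ e^(−ln2 (t−t₁)/t½)` per channel from the first post-injection
frame (defaults: 55 min vehicle, 61 min payload; 25 frames, 5 min
apart); frame 0 is a pre-injection background frame, the reference for
background subtraction. At injection, 10 % of the payload's
intravascular integral is deposited uniformly into a 10 μm
perivascular shell (the initial burst); the tracer channel marks the
vessels in every frame.

**Noise.** `I → Poisson(s·I)/s + N(0, σ_read)` with `s = 10` photons
per intensity unit and `σ_read = 1` a.u., clipped at zero — the
standard shot-plus-read camera model. `s = inf` disables shot noise.
One `numpy` Generator seeded by `config.seed` supplies every draw in a
documented order, so identical (config, seed) pairs are bit-identical.

**What the generator does not emulate:** optics (no PSF), vascular
branching morphology, cell motility or division, payload re-uptake
kinetics, autofluorescence structure, or depth-dependent attenuation.
Passing tests therefore demonstrate correctness of the estimators
under a statistically matched model, not performance on real
microscope data.

## Estimators and numerical choices

**Background subtraction** subtracts the per-voxel mean of the
pre-injection frames and clips negatives to zero; pre-injection frames
are retained but flagged.

**Decay fitting** seeds `I₀, λ` from a log-linear regression on the
positive values, then runs unweighted nonlinear least squares on
`I₀ e^(−λt)` (an optional `+C` variant exists because the payload
burst can leave a floor). A fitted `λ ≤ 10⁻⁶ min⁻¹` is reported as
"no decay", not as a half-life. Vessels are averaged with equal
weights regardless of size. Median absolute half-life error over
simulated series with default noise is below 5 %.

**Segmentation** is Gaussian smoothing (σ = 1 μm, physical), a global
Otsu (or fixed) threshold, hole filling, Euclidean distance transform,
and a watershed seeded at distance-transform peaks at least 9 μm apart,
followed by a 50–1500 μm³ volume filter and contiguous relabelling.
Peaks are found with a separable box maximum filter of half-width
`9/√3` μm per axis — the largest box that cannot suppress two peaks
9 μm apart in Euclidean distance — then greedily thinned to the exact
Euclidean spacing, ties broken by peak height then lowest linear
index, making seeding deterministic and anisotropy-correct.

**Puncta counting** runs multiscale LoG blob detection (σ 0.4–1 μm)
on each nucleus' bounding box normalised by the nucleus median; a blob
must lie in the nucleus mask and rise above the median by ≥ 50 % of
the median (a relative criterion, so counts are invariant to uniform
intensity scaling); blobs closer than 1.2 μm are merged keeping the
strongest.

**Local MFI** is the mean channel intensity over the nucleus mask
dilated by the measurement radius in physical units (default 5 μm from
the nucleus *surface*, not the centroid — the surface reading matches
the perinuclear measurement the damage correlation uses); radius 0
measures the nucleus mask alone.

**Outlier rule**: a single pass excluding `|x − mean| > 2·SD` with
sample SD (n−1); zero variance excludes nothing. On standard-normal
data this removes 2Φ(−2) ≈ 4.55 % by construction.

**Damage association**: cells are classed high/low at ≥ 5 puncta
(configurable, always echoed in output); the report gives mean
payload/vehicle MFI per class, their ratio (the raw ratio is reported,
never a "% higher" conversion), and a one-way ANOVA of MFI across
puncta bins (0–1, 2–4, 5–9, ≥10).

**Co-localization**: Pearson over masked voxels (zero variance is
flagged, not crashed). Manders M1/M2 restrict both numerator and
denominator to above-threshold voxels of the reference channel;
default thresholds are the 95th percentile of each channel *outside*
the mask (background-percentile rule — Costes auto-thresholding is
deliberately out of scope).

**Spatial CV** tiles the volume into non-overlapping cubes (default
10 μm — "cell-sized"; a regular tiling is used for determinism since
manual ROI choice is not reproducible), discards ROIs with < 50 % mask
coverage, and reports sample SD / mean of the ROI MFIs.

**Proximity profile** bins intensity by Euclidean distance from the
macrophage mask (mask voxels excluded; physical spacing), and reports
the mean within 15 μm — one cell length — over the mean beyond the
last interior bin edge.

**Uptake accounting**: net MFI is `max(raw − control, 0)`; uptake
shares are prevalence-weighted net MFIs normalised to 1. Caliper
readings are treated as diameters (`r = mean/2`; a flag switches to
radii, the phrasing being ambiguous). Molarity conversion assumes
tissue density 1 g/ml and the Pt standard atomic weight 195.084 g/mol.

## Problem sizes

Defaults are sized for routine desk validation: snapshots of
64 × 128 × 128 μm (1 × 0.5 × 0.5 μm voxels) with 200 cells; time-lapses
of 25 frames over 2 h on a 32 × 96 × 96 μm field; the half-life checks
average 6 replicates; cohort-level checks pool 4 samples × 250 cells.

## Known limitations

* Segmentation assumes convex, non-touching nuclei of roughly uniform
  fill; densely packed or lobed nuclei would need different seeding.
* Puncta counts saturate once foci are closer than the LoG resolution
  limit; very high damage levels are reported as "high class"
  reliably, but their exact counts compress.
* The single-phase decay model deliberately omits multi-exponential
  compartments; series with a strong plateau need the offset variant.
* Manders values depend on the background-percentile threshold choice;
  thresholds are always echoed in the output for that reason.
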