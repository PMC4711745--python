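# ivcyto

Single-cell intravital image cytometry for nanoparticle pharmacokinetics
(PK) and DNA-damage pharmacodynamics (PD).

Therapeutic nanoparticles (TNPs) carrying a platinum pro-drug behave very
differently inside a tumour than bulk PK suggests: the particle vehicle is
taken up avidly by tumour-associated macrophages (TAMs), which then act as
local depots that release the DNA-damaging payload to neighbouring tumour
cells. Quantifying that behaviour from multi-channel intravital microscopy
requires a chain of image-analysis steps — vascular decay fitting, 3-D
nuclear segmentation, 53BP1 puncta counting, perinuclear MFI measurement,
co-localization and spatial-heterogeneity statistics, distance-transform
proximity profiles, and population-weighted uptake accounting. `ivcyto`
implements that chain as a tested, reproducible pipeline, together with a
synthetic tissue/time-lapse generator that reproduces the statistical
structure of the imaging data so every stage can be validated against
ground truth without any microscope.

## The quantities at the core

* **Vascular half-life.** The intravascular intensity after background
  subtraction follows `I(t) = I₀ e^(−λt)`; the circulating half-life is
  `t½ = ln 2 / λ`, fitted by nonlinear least squares
  (`ExponentialDecay(series, times).fit()` → `DecayFit` with `summary()`).
  The generator defaults encode `t½ = 55 min` (vehicle) and `61 min`
  (payload) with a ~10 % payload burst into perivascular tissue.
* **Single-cell dose–damage link.** Per nucleus: 53BP1-like puncta count
  (LoG blob detection) and local MFI of vehicle/payload within a radius
  (default 5 μm) of the nucleus surface; cells are classed high/low damage
  at a puncta threshold (default 5) and compared after the 2-SD outlier
  rule (`|x − mean| > 2 SD` excluded, single pass).
* **Spatial statistics.** Pearson ρ and Manders M1/M2 co-localization;
  coefficient of variation `CV = SD/mean` of MFIs over cell-sized ROIs
  (default 10 μm tiling); payload enrichment versus Euclidean distance
  from the macrophage mask, summarised as the fold within 15 μm relative
  to the far field.
* **Uptake accounting.** For populations with cell fraction `f_k` and
  background-subtracted MFI `m_k`, the share of total uptake is
  `f_k m_k / Σ_j f_j m_j`; plus the spherical tumour volume
  `V = 4/3 πr³` (r averaged from four caliper diameters) and the
  platinum mass-fraction → molarity conversion (1 ng/mg ≡ 5.126 μM).

## Worked example

Run the full simulate → fit → segment → quantify → report pipeline:

```sh
$ ivcyto run --seed 7 --out demo
report written to demo/report.json
  simulate: {"n_cells": 200, "n_macrophages": 5}
  pkfit: {"vehicle": {"t_half_min": 54.93, "r_squared": 0.99993}, "payload": {"t_half_min": 62.32, "r_squared": 0.99950}}
  cytometry: {"n_nuclei": 200, "high_damage_fraction": 0.14, "payload_ratio_high_low": 1.403, "anova_p_payload": 6.3e-10}
  spatial: {"pearson_rho": 0.021, "cv_vehicle": 0.590, "cv_payload": 0.479, "proximity_fold_vs_far": 2.77}
```

Reading the report: the fitted vascular half-lives (54.9 / 62.3 min)
recover the configured 55 / 61 min; all 200 ground-truth nuclei are
segmented; cells classed high-damage (≥5 puncta) carry 1.4× the local
payload of low-damage cells with the MFI separating strongly across
damage bins (ANOVA p ≈ 6×10⁻¹⁰); the payload channel is more spatially
homogeneous than the vehicle (CV 0.48 vs 0.59) while still ~2.8-fold
enriched within 15 μm of macrophage depots.

The decay model is also usable standalone:

```python
>>> from ivcyto import fit_decay
>>> fit = fit_decay(series, times)          # a.u., minutes
>>> print(fit.summary())
Exponential decay fit  I(t) = I0 exp(-lambda t)
  n points     : 25
  I0           : 100.2 (se 0.923) a.u.
  lambda       : 0.012745 (se 0.000216) 1/min
  t_half       : 54.38 (se 0.921) min
  R^2          : 0.9947
  residual s.e.: 1.769 a.u.
```

Other subcommands: `ivcyto simulate`, `pkfit`, `cytometry`, `spatial`,
`account` — each a thin wrapper over the library; see `--help`.

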