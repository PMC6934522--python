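# Methods

## Problem and scope

Clinical proton therapy weights physical dose by a constant relative
biological effectiveness (RBE) of 1.1, although the biological effect of
protons is known to vary with dose, linear energy transfer (LET) and tissue.
`protonrbe` computes RBE-weighted dose maps on co-registered voxel grids of
absorbed dose and LET under six weighting schemes, and derives the standard
plan-evaluation products from them: DVHs, ROI statistics, line profiles and
the distal biological range extension.  Particle transport is out of scope:
the package consumes dose/LET grids (or generates synthetic ones) and models
only the biology applied on top of them.

## LET averaging

For particle steps depositing energy ΔE_i over path Δl_i in a voxel
(per-step LET L_i = ΔE_i/Δl_i):

* dose-averaged LET: `LET_d = Σ (ΔE_i/ΣΔE)·L_i`
* track-averaged LET: `LET_t = Σ (Δl_i/ΣΔl)·L_i = ΣΔE/ΣΔl`

`LET_d ≥ LET_t` always (Cauchy–Schwarz), with equality only for a
single-valued LET spectrum.  Steps with Δl = 0 are rejected rather than
skipped: both averages are undefined for them.

Composite plan LET from per-field voxel values (D_i, L_i) uses the fluence
proxy Φ_i = D_i/L_i for track averaging, `ΣD_i / Σ(D_i/L_i)`, and the plain
dose-weighted mean for dose averaging.  The proxy is exact when each field
contribution is mono-LET and is an explicit, replaceable assumption
otherwise (transport codes combine fields at the step level, which the grid
representation cannot).

## Biological models

With D absorbed dose (Gy), L_d dose-averaged and L_t track-averaged LET
(keV/µm):

* constant: `Dose = 1.1·D`.
* LET-weighted: `Dose_w = D·(1 + κ·L_d)`.  Published κ values differ
  tenfold between sources (0.055 vs 0.0055 µm/keV); the default is
  κ = 0.055 µm/keV and both are supported through the parameter file.
* McNamara (phenomenological, LQ-based):
  `RBE = (√((α/β)² + 4D(α/β)·RBE_max + 4D²·RBE_min²) − α/β) / (2D)` with
  `RBE_max = Z1 + (Z2/(α/β))·L_d`, `RBE_min = Z3 − Z4·√(α/β)`.
  The printed 1/(2D) form is numerically unstable near D = 0, so below
  ε = 1e−6 Gy the analytic limit `RBE_max` is returned.  Voxel α/β comes
  from ROI labels with a most-specific-wins priority
  (spinal_cord/brainstem over ptv over body); defaults α/β = 10 Gy for the
  PTV, 2 Gy for brainstem, spinal cord and everything else.  The body value
  is a configurable choice, not a literature constant.
* Mechanistic DSB-yield correlations (generic cell, LET_t as input,
  parameters a–h, γ_r, γ_m):
  * residual (unrepaired at 24 h): `RBE_r = (d·L_t + e)·c / γ_r`
  * misrepaired: `RBE_m = (d·L_t + e)·(a·(f·L_t² + g·L_t + h) + b)·(1−c) / γ_m`
  * combined: numerators summed over denominator `γ_r + γ_m`, so exactly
    `(γ_r+γ_m)·RBE_r&m = γ_r·RBE_r + γ_m·RBE_m`.
  γ_r and γ_m are the residual and misrepaired DSB yields per Gy of
  Cobalt-60 photons; γ_m ≪ γ_r makes RBE_m large in absolute terms
  (order 10) and keeps RBE_r&m close to RBE_r.  The correlations are
  implemented as published: dose cancels out of the RBE, so these maps
  depend on LET_t alone.  The residual:misrepair yield ratio
  `c / ((a·(f·L_t²+g·L_t+h)+b)·(1−c))` is likewise dose-free, strictly
  decreasing in LET_t, and stays above 1 over the LET range of interest.

LET flavour is enforced per model (L_d for LET-weighted and McNamara, L_t
for the mechanistic correlations); passing the wrong grid raises.

Parameter uncertainties (% standard errors) are stored alongside the
defaults but never propagated; uncertainty bands are a non-goal.

## Grid model and conventions

Grids are (nz, ny, nx) arrays, x-fastest, voxel-center origin, mm spacing;
2 mm isotropic voxels are the default scoring resolution.  All grids in one
analysis must be exactly co-registered; there is no resampling.  RBE and
ratio maps carry NaN in zero-dose voxels (Dose·RBE is defined there — it is
0 — but RBE itself is not); ROI statistics and DVHs skip NaN voxels.  The
portable on-disk format is a JSON header plus a CSV (exact for float64 via
shortest round-trip decimals) or raw little-endian float32 payload.  DICOM
RT-DOSE import is a minimal read-only convenience (scaling factor applied,
geometry from the standard tags); RT-STRUCT handling is a non-goal.

## Plan metrics

* DVH: cumulative, relative volume, `%(value ≥ bin)` by voxel counting,
  bins from 0 to max + one bin, default width 0.01 Gy.  No partial-volume
  weighting.
* D2%: smallest observed value v with ≤ 2% of ROI voxels ≥ v (near-maximum
  metric for serial organs); falls back to the maximum for very small ROIs.
* Line profiles: nearest-voxel sampling at fixed arc-length steps,
  out-of-grid samples dropped; values are never interpolated.
* Distal extension: both profiles are scanned from the distal end for the
  last downward crossing of a dose level; the crossing position is linearly
  interpolated between bracketing samples and the extension is the
  difference weighted − reference (reference: constant-RBE profile).  The
  crossing-depth definition and the default level (80% of prescription) are
  interpretations — the measurement is not uniquely defined by a dose
  distribution — and the level is a parameter everywhere.

## Synthetic phantom

The generator emulates the statistical structure of a three-field SFUD plan
(1.8 Gy per fraction) so the full pipeline is testable without patient data:

* Pristine peak surrogate: plateau `0.3 + 0.7·(z/R)^8`, peak at the range
  R, Gaussian distal falloff (σ = 1.5 mm, baseline-subtracted to reach 0
  continuously at R + 6 mm).  This is a qualitative stand-in chosen for
  smoothness and a realistic peak-to-entrance ratio, not a fitted
  depth-dose model.
* SOBP synthesis: ranges evenly spaced over the modulation, non-negative
  least-squares weights against a flat target, flatness required within
  ±2.5% over the central 80%.
* Per-component LET_t: `L(z) = 0.5 + 4.5·(z/R)³` keV/µm up to the range,
  rising linearly to 9.0 keV/µm at R + 3 mm, constant to R + 6 mm.
  LET_d = 1.3 × LET_t per component (fixed spread factor, configurable —
  no joint distribution is available to emulate).  These values are
  deliberately reverse-engineered so that composite LET_t inside the
  target and organ analogues spans ≈1.5–5.5 keV/µm, the band over which
  the residual correlation gives RBE ≈ 1.1–1.3; the phantom consistency
  checks are therefore consistency checks on this construction, not
  independent validation of the models.
* Geometry: 60×40×40 grid at 2 mm; PTV ellipsoid (semi-axes 15/12/12 mm);
  a brainstem analogue (cylinder along z, radius 10 mm) overlapping the
  PTV's distal-x edge and extending to the end of the +x field's
  modulation; a cord analogue inferior, inside the superior field only.
  The two "lateral" fields enter along +x and +y rather than opposed ±x:
  with opposed laterals the entrance plateau of one field floods the organ
  distal to the other and track-averaged mixing pins composite LET_t near
  the entrance value, destroying the high-LET structure the phantom exists
  to emulate.  Fields carry hard-edged rectangular apertures (no lateral
  penumbra) conformal to the structures they treat; each SOBP is extended
  through every structure its beam doses so that no ROI voxel sits in a
  distal falloff, where LET_t → 9 keV/µm would push the residual RBE to
  ≈1.47, outside the representative map range.
* Dose is normalised to PTV mean = prescription, then multiplied by
  seeded lognormal noise (σ = 0.01) emulating scoring statistics.  All
  randomness flows through the single spec seed; same seed ⇒ bit-identical
  bundle.
* A single-field variant is provided for falloff studies: on the
  three-field phantom every line through the target keeps a multi-field
  dose floor, so a distal crossing at a fixed level only exists against a
  single field's falloff.

## Numerical choices and degenerate inputs

* McNamara D < 1e−6 Gy → analytic limit (above).
* Zero-dose voxels: LET stored as 0 (no track ever crossed), RBE/ratio NaN.
* Mixing with all-zero doses raises; zero-dose contributions are skipped.
* DVH bins always include one bin above the maximum so curves end at 0%.
* D2% ties are resolved by taking the smallest qualifying observed value.
* Profile crossings interpolate position linearly between the bracketing
  samples; profiles that never reach, or never fall below, the level raise.
* SOBP flatness failure raises rather than silently accepting a bumpy field.

## Known limitations

* Single-valued LET per voxel; LET spectra and their differing biological
  effect are not represented.
* The field-mixing rule is exact only for mono-LET contributions.
* The phantom has no beam-model realism (spot sizes, energy spectra,
  heterogeneities, range uncertainty); passing its consistency checks says
  the pipeline reproduces the intended LET→RBE mapping on representative
  inputs, not that the models are validated against measurement.
* Mechanistic correlations are for a generic cell in G1; no tissue
  dependence, no repair pathways beyond non-homologous end joining.
* No treatment-plan optimisation, NTCP/TCP, EQD2, robustness or gamma
  analysis.  Reported doses are per fraction; course scaling is the
  caller's responsibility.
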