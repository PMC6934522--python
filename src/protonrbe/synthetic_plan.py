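"""Synthetic SFUD-like phantom: co-registered dose / LET grids and ROI masks.

This module stands in for Monte Carlo transport.  It produces a
three-field single-field-uniform-dose (SFUD) plan analogue on a water-box
phantom: each field is a spread-out Bragg peak (SOBP) built from an analytic
pristine-peak surrogate, with a track-averaged LET curve that rises slowly
through the plateau, reaches its pristine-peak value at the range, and
climbs further through the distal falloff — the qualitative LET structure of
a proton field.  Composite plan LET grids are produced with the same mixing
rules the scoring module defines, and dose-averaged LET is derived from
track-averaged LET with a fixed spread factor per pristine component.

What this emulates: SOBP depth-dose shape, LET elevation toward distal
edges, field overlap geometry (a serial-organ analogue distal to one lateral
field, a cord analogue inferior, dosed by the superior field only), 2 mm
scoring voxels, 1.8 Gy per fraction prescription, and mild multiplicative
scoring noise.  What it does not emulate: energy spectra, lateral penumbra
and scattering, heterogeneous tissue, nuclear interactions, secondary
particles, LET spectra.

The LET scale (entry 0.5, peak 5.0, distal 9.0 keV/um) is chosen so that
composite track-averaged LET inside the target and serial-organ analogues
spans roughly 1.5-5.5 keV/um — the clinically representative band over
which the residual-DSB RBE correlation yields values of about 1.1-1.3.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from .let_scoring import StepRecord, mix_let_d_arrays, mix_let_t_arrays
from .voxel_model import PlanBundle, Quantity, ROIMask, VoxelGrid, write_grid

#: Distal falloff width of the pristine-peak surrogate (mm).
FALLOFF_SIGMA_MM = 1.5
#: Depth beyond the range at which the pristine dose is exactly zero (mm).
FALLOFF_CUTOFF_MM = 6.0
#: Entrance dose as a fraction of the pristine peak maximum.
ENTRANCE_FRACTION = 0.3

_AXES = {"+z": (0, +1), "-z": (0, -1), "+y": (1, +1), "-y": (1, -1),
         "+x": (2, +1), "-x": (2, -1)}
_AXIS_NAME = {0: "z", 1: "y", 2: "x"}


class SyntheticPlanError(ValueError):
    pass


class SOBPFlatnessError(SyntheticPlanError):
    """Weight optimisation could not reach the required SOBP flatness."""


# ---------------------------------------------------------------------------
# Analytic field surrogates
# ---------------------------------------------------------------------------

def pristine_peak(depth_mm, range_mm: float):
    """Relative depth-dose of one pristine Bragg peak (peak value 1).

    Piecewise analytic: a slowly rising plateau (entrance ~0.3 of the peak),
    maximum at ``range_mm``, Gaussian distal falloff (sigma 1.5 mm,
    baseline-subtracted so the curve reaches 0 continuously at range + 6 mm).
    """
    if range_mm <= 0:
        raise SyntheticPlanError("range must be positive")
    z = np.asarray(depth_mm, dtype=np.float64)
    out = np.zeros_like(z)
    plateau = z <= range_mm
    out[plateau] = ENTRANCE_FRACTION + (1.0 - ENTRANCE_FRACTION) * (
        np.clip(z[plateau], 0.0, None) / range_mm) ** 8
    tail = (z > range_mm) & (z <= range_mm + FALLOFF_CUTOFF_MM)
    base = np.exp(-FALLOFF_CUTOFF_MM**2 / (2 * FALLOFF_SIGMA_MM**2))
    out[tail] = (np.exp(-((z[tail] - range_mm) ** 2) / (2 * FALLOFF_SIGMA_MM**2)) - base) / (1 - base)
    out[z < 0] = 0.0
    return out if out.ndim else float(out)


def _let_curve(depth_mm, range_mm, l_entry, l_peak, l_distal):
    """Track-averaged LET vs depth for one pristine component (no domain check)."""
    z = np.asarray(depth_mm, dtype=np.float64)
    rise = l_entry + (l_peak - l_entry) * (np.clip(z, 0.0, range_mm) / range_mm) ** 3
    past = np.clip(z - range_mm, 0.0, 3.0)
    return rise + (l_distal - l_peak) * past / 3.0


def field_let_t(depth_mm, range_mm: float, *,
                l_entry: float = 0.5, l_peak: float = 5.0, l_distal: float = 9.0):
    """Track-averaged LET (keV/um) of one pristine component at depth.

    Monotone non-decreasing: cubic rise from ``l_entry`` at the surface to
    ``l_peak`` at the range, linear climb to ``l_distal`` over the next
    3 mm, then constant out to range + 6 mm (the end of the dose tail).
    """
    if range_mm <= 0:
        raise SyntheticPlanError("range must be positive")
    z = np.asarray(depth_mm, dtype=np.float64)
    if (z < 0).any() or (z > range_mm + FALLOFF_CUTOFF_MM).any():
        raise SyntheticPlanError(
            f"depth outside [0, range + {FALLOFF_CUTOFF_MM}] mm")
    out = _let_curve(z, range_mm, l_entry, l_peak, l_distal)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Field and phantom specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """One beam: direction, modulation extent and transverse aperture.

    ``axis`` is one of +x/-x/+y/-y/+z/-z; ``entry_mm`` is the skin position
    along that axis (depth is measured from it, increasing along the beam).
    ``aperture_mm`` maps transverse axis names ("x", "y", "z") to closed
    (lo, hi) intervals in mm outside which the field deposits nothing; axes
    not listed are unconstrained.  Hard-edged: no lateral penumbra.
    """

    axis: str
    sobp_proximal_mm: float
    sobp_distal_mm: float
    entry_mm: float = 0.0
    n_pristine: int = 2
    weight_total: float = 1.0
    aperture_mm: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    l_entry: float = 0.5
    l_peak: float = 5.0
    l_distal: float = 9.0

    def __post_init__(self):
        if self.axis not in _AXES:
            raise SyntheticPlanError(f"axis must be one of {sorted(_AXES)}")
        if self.sobp_proximal_mm >= self.sobp_distal_mm:
            raise SyntheticPlanError("sobp_proximal must be < sobp_distal")
        if self.n_pristine < 1:
            raise SyntheticPlanError("n_pristine must be >= 1")
        if self.weight_total <= 0:
            raise SyntheticPlanError("weight_total must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and conditions of the synthetic SFUD phantom.

    Defaults give a 120 x 80 x 80 mm water box in 2 mm voxels holding a PTV
    ellipsoid, a brainstem analogue (cylinder along z overlapping the PTV's
    distal-x edge, distal to the +x lateral field), and a spinal-cord
    analogue inferior to the PTV, inside the superior field only.  All
    randomness flows through ``seed``.
    """

    dims: tuple[int, int, int] = (60, 40, 40)          # (nz, ny, nx)
    spacing_mm: float = 2.0
    prescription_Gy: float = 1.8
    seed: int = 20209
    noise_sigma: float = 0.01
    letd_spread_factor: float = 1.3
    ptv_center_mm: tuple[float, float, float] = (60.0, 40.0, 40.0)   # (z, y, x)
    ptv_semiaxes_mm: tuple[float, float, float] = (15.0, 12.0, 12.0)
    brainstem_center_mm: tuple[float, float] = (40.0, 60.0)          # (y, x)
    brainstem_radius_mm: float = 10.0
    brainstem_z_mm: tuple[float, float] = (45.0, 75.0)
    cord_center_mm: tuple[float, float] = (40.0, 40.0)               # (y, x)
    cord_radius_mm: float = 4.5
    cord_z_mm: tuple[float, float] = (80.0, 106.0)
    fields: tuple[FieldSpec, ...] = ()

    def __post_init__(self):
        if self.prescription_Gy <= 0:
            raise SyntheticPlanError("prescription must be positive")
        if not self.fields:
            object.__setattr__(self, "fields", default_fields())
        extents = tuple(d * self.spacing_mm for d in self.dims)
        z0, z1 = self.brainstem_z_mm
        if not (0 <= z0 < z1 <= extents[0]) or not (0 <= self.cord_z_mm[0] < self.cord_z_mm[1] <= extents[0]):
            raise SyntheticPlanError("ROI z extents fall outside the grid")
        for c, s, e in zip(self.ptv_center_mm, self.ptv_semiaxes_mm, extents):
            if c - s < 0 or c + s > e:
                raise SyntheticPlanError("PTV ellipsoid falls outside the grid")


def default_fields() -> tuple[FieldSpec, ...]:
    """The three-field SFUD arrangement: two laterals and one superior.

    The two laterals enter along +x and +y (orthogonal rather than opposed,
    so the organ at risk distal to one lateral is not flooded by the
    entrance plateau of the other); the superior field runs along +z with
    its modulation extended through the cord analogue.  Each SOBP is
    extended through every structure its beam traverses so that no ROI
    voxel sits in a distal falloff.
    """
    return (
        FieldSpec(axis="+x", sobp_proximal_mm=26.0, sobp_distal_mm=69.0,
                  n_pristine=23, aperture_mm={"y": (26.0, 54.0), "z": (43.0, 77.0)}),
        FieldSpec(axis="+y", sobp_proximal_mm=26.0, sobp_distal_mm=56.0,
                  n_pristine=16, aperture_mm={"x": (26.0, 56.0), "z": (43.0, 77.0)}),
        FieldSpec(axis="+z", sobp_proximal_mm=43.0, sobp_distal_mm=110.0,
                  n_pristine=34, aperture_mm={"x": (26.0, 56.0), "y": (26.0, 54.0)}),
    )


def single_field_spec(**overrides) -> PhantomSpec:
    """A one-field variant (the +x lateral, open SOBP through the target).

    Used for single-field depth-dose / LET studies such as the distal
    biological range extension, where the composite three-field dose floor
    would mask the falloff.
    """
    fld = FieldSpec(axis="+x", sobp_proximal_mm=26.0, sobp_distal_mm=56.0,
                    n_pristine=16, aperture_mm={"y": (26.0, 54.0), "z": (43.0, 77.0)})
    return PhantomSpec(fields=(fld,), **overrides)


# ---------------------------------------------------------------------------
# SOBP synthesis
# ---------------------------------------------------------------------------

def build_sobp(fld: FieldSpec, flatness_tol: float = 0.025) -> list[tuple[float, float]]:
    """Pristine ranges and non-negative weights forming a flat SOBP.

    Ranges are evenly spaced over [sobp_proximal, sobp_distal]; weights are
    a non-negative least-squares fit against a flat unit target across the
    modulation, then scaled so the plateau sits at ``weight_total``.
    Raises :class:`SOBPFlatnessError` if the synthesized SOBP deviates more
    than ``flatness_tol`` from flat over the central 80% of the modulation.
    """
    if fld.n_pristine == 1:
        return [(fld.sobp_distal_mm, fld.weight_total)]
    ranges = np.linspace(fld.sobp_proximal_mm, fld.sobp_distal_mm, fld.n_pristine)
    depths = np.arange(fld.sobp_proximal_mm, fld.sobp_distal_mm + 0.25, 0.5)
    design = np.stack([pristine_peak(depths, r) for r in ranges], axis=1)
    weights, _ = nnls(design, np.ones_like(depths))
    sobp = design @ weights
    span = fld.sobp_distal_mm - fld.sobp_proximal_mm
    central = (depths >= fld.sobp_proximal_mm + 0.1 * span) & (
        depths <= fld.sobp_distal_mm - 0.1 * span)
    plateau = float(sobp[central].mean())
    deviation = float(np.abs(sobp[central] / plateau - 1.0).max())
    if deviation > flatness_tol:
        raise SOBPFlatnessError(
            f"SOBP deviates {deviation:.1%} from flat (tolerance {flatness_tol:.1%})")
    scale = fld.weight_total / plateau
    return [(float(r), float(w * scale)) for r, w in zip(ranges, weights)]


# ---------------------------------------------------------------------------
# Plan generation
# ---------------------------------------------------------------------------

def _coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-center coordinate vectors (z, y, x) in mm; origin at spacing/2."""
    return tuple(spec.spacing_mm * (np.arange(n) + 0.5) for n in spec.dims)


def _field_arrays(fld: FieldSpec, spec: PhantomSpec):
    """3-D dose, LET_t and LET_d arrays for one field (plateau = weight_total)."""
    coords = _coords(spec)
    axis_idx, sign = _AXES[fld.axis]
    along = coords[axis_idx]
    depth_1d = (along - fld.entry_mm) if sign > 0 else (fld.entry_mm - along)

    components = build_sobp(fld)
    doses_1d, lets_1d = [], []
    for rng_mm, w in components:
        doses_1d.append(w * pristine_peak(depth_1d, rng_mm))
        lets_1d.append(_let_curve(depth_1d, rng_mm, fld.l_entry, fld.l_peak, fld.l_distal))
    dose_1d = np.sum(doses_1d, axis=0)
    lt_1d = mix_let_t_arrays(doses_1d, lets_1d)
    ld_1d = mix_let_d_arrays(doses_1d, [spec.letd_spread_factor * l for l in lets_1d])

    shape = [1, 1, 1]
    shape[axis_idx] = spec.dims[axis_idx]
    aperture = np.ones(spec.dims, dtype=bool)
    for name, (lo, hi) in fld.aperture_mm.items():
        t_idx = {"z": 0, "y": 1, "x": 2}[name]
        if t_idx == axis_idx:
            raise SyntheticPlanError(f"aperture axis {name} is the beam axis")
        t_shape = [1, 1, 1]
        t_shape[t_idx] = spec.dims[t_idx]
        inside = (coords[t_idx] >= lo) & (coords[t_idx] <= hi)
        aperture &= inside.reshape(t_shape)

    dose = dose_1d.reshape(shape) * aperture
    lt = np.where(dose > 0, lt_1d.reshape(shape) * np.ones(spec.dims), 0.0)
    ld = np.where(dose > 0, ld_1d.reshape(shape) * np.ones(spec.dims), 0.0)
    return dose, lt, ld


def _build_masks(spec: PhantomSpec, reference: VoxelGrid) -> dict[str, ROIMask]:
    zc, yc, xc = _coords(spec)
    z = zc[:, None, None]
    y = yc[None, :, None]
    x = xc[None, None, :]

    cz, cy, cx = spec.ptv_center_mm
    az, ay, ax = spec.ptv_semiaxes_mm
    ptv = ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0

    by, bx = spec.brainstem_center_mm
    brainstem = ((y - by) ** 2 + (x - bx) ** 2 <= spec.brainstem_radius_mm**2) & (
        (z >= spec.brainstem_z_mm[0]) & (z <= spec.brainstem_z_mm[1]))

    sy, sx = spec.cord_center_mm
    cord = ((y - sy) ** 2 + (x - sx) ** 2 <= spec.cord_radius_mm**2) & (
        (z >= spec.cord_z_mm[0]) & (z <= spec.cord_z_mm[1]))

    body = np.ones(spec.dims, dtype=bool)
    masks = {
        "ptv": ptv, "brainstem": brainstem, "spinal_cord": cord, "body": body,
    }
    for name, arr in masks.items():
        if not arr.any():
            raise SyntheticPlanError(f"ROI {name!r} contains no voxels")
    return {name: ROIMask.from_grid(name, reference, arr) for name, arr in masks.items()}


def generate_plan(spec: PhantomSpec | None = None) -> PlanBundle:
    """Generate the co-registered dose / LET_t / LET_d bundle with ROI masks.

    Per-field doses come from the SOBP synthesis; the plan dose is the field
    sum rescaled so the PTV mean equals the prescription, with seeded
    multiplicative lognormal noise (sigma = ``noise_sigma``) applied last.
    Composite LET grids use the fluence-proxy (track) and dose-weighted
    mixing rules on the noiseless field doses.  Deterministic per seed.
    """
    spec = spec or PhantomSpec()
    per_field = [_field_arrays(fld, spec) for fld in spec.fields]
    field_doses = [d for d, _, _ in per_field]
    dose = np.sum(field_doses, axis=0)

    geometry = dict(
        dims=spec.dims,
        spacing_mm=(spec.spacing_mm,) * 3,
        origin_mm=(spec.spacing_mm / 2,) * 3,
    )
    reference = VoxelGrid(values=dose, quantity=Quantity.DOSE, **geometry)
    masks = _build_masks(spec, reference)

    ptv = masks["ptv"].values
    mean_ptv = dose[ptv].mean()
    if mean_ptv <= 0:
        raise SyntheticPlanError("fields deposit no dose in the PTV")
    dose = dose * (spec.prescription_Gy / mean_ptv)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        noise = rng.lognormal(mean=0.0, sigma=spec.noise_sigma, size=spec.dims)
        dose = np.where(dose > 0, dose * noise, 0.0)

    let_t = mix_let_t_arrays(field_doses, [lt for _, lt, _ in per_field])
    let_d = mix_let_d_arrays(field_doses, [ld for _, _, ld in per_field])
    # LET is defined only where dose is deposited.
    let_t = np.where(dose > 0, let_t, 0.0)
    let_d = np.where(dose > 0, let_d, 0.0)

    return PlanBundle(
        dose=VoxelGrid(values=dose, quantity=Quantity.DOSE, **geometry),
        let_t=VoxelGrid(values=let_t, quantity=Quantity.LET_T, **geometry),
        let_d=VoxelGrid(values=let_d, quantity=Quantity.LET_D, **geometry),
        masks=masks,
        prescription_Gy=spec.prescription_Gy,
    )


def generate_step_records(
    n: int, seed: int, let_mean: float = 2.0, let_sigma_log: float = 0.3
) -> list[StepRecord]:
    """Lognormal-LET step records (path length fixed at 1 um), seeded."""
    if n < 1:
        raise SyntheticPlanError("need at least one step")
    rng = np.random.default_rng(seed)
    lets = rng.lognormal(mean=np.log(let_mean), sigma=let_sigma_log, size=n)
    return [StepRecord(float(l), 1.0) for l in lets]


def save_phantom(bundle: PlanBundle, spec: PhantomSpec, outdir: str | Path,
                 encoding: str = "csv") -> dict:
    """Write all grids and masks in the portable format plus provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, grid in (("dose", bundle.dose), ("let_t", bundle.let_t),
                       ("let_d", bundle.let_d)):
        written[name] = write_grid(grid, outdir / name, encoding=encoding).name
    for name, mask in bundle.masks.items():
        written[f"mask_{name}"] = write_grid(mask.to_grid(), outdir / f"mask_{name}",
                                             encoding=encoding).name
    provenance = {
        "spec": dataclasses.asdict(spec),
        "seed": spec.seed,
        "files": written,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return provenance
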