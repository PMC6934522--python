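"""Voxel grid data model and portable file I/O.

Every quantity in this package lives on a regular 3-D voxel grid stored in
``(z, y, x)`` index order with the x index varying fastest, voxel-center
origin, and millimetre spacing.  All grids participating in one analysis must
be co-registered (identical dims, spacing and origin); no resampling is
performed anywhere.

Undefined values (RBE or ratio in voxels that received no dose) are marked
with NaN.  Dose and LET grids must be finite and non-negative everywhere.

On-disk format: a JSON header ``<name>.vxg.json`` next to a payload file
holding the values either as comma-separated decimals (``csv``) or raw
little-endian 32-bit floats (``f32le``), x-fastest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np


class Quantity(str, Enum):
    """Physical quantity carried by a grid; controls validation rules."""

    DOSE = "dose_Gy"
    LET_T = "let_t_keV_per_um"
    LET_D = "let_d_keV_per_um"
    WEIGHTED_DOSE = "weighted_dose_Gy"
    RBE = "rbe"
    RATIO = "ratio"
    MASK = "mask"


#: Quantities for which NaN is a permitted "undefined" sentinel.
_NAN_ALLOWED = frozenset({Quantity.RBE, Quantity.RATIO})


class GridError(ValueError):
    """Base class for grid construction and I/O failures."""


class GridFormatError(GridError):
    """Malformed header or payload in the portable grid format."""


class GeometryMismatchError(GridError):
    """Two grids that must be co-registered differ in geometry."""


class RTDoseImportError(GridError):
    """DICOM file is not a usable RT-DOSE object."""


@dataclass(frozen=True)
class VoxelGrid:
    """A scalar field on a regular grid.

    Parameters
    ----------
    dims : (nz, ny, nx) voxel counts.
    spacing_mm : positive voxel pitch per axis, (z, y, x) order.
    origin_mm : position of the center of voxel (0, 0, 0), mm.
    values : array of shape ``dims`` (C order == x-fastest flat order).
    quantity : what the values represent; governs validity checks.
    """

    dims: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    values: np.ndarray
    quantity: Quantity

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        object.__setattr__(self, "quantity", Quantity(self.quantity))
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim == 1:
            if vals.size != self.nvoxels:
                raise GridError(
                    f"values length {vals.size} != nz*ny*nx = {self.nvoxels}"
                )
            vals = vals.reshape(self.dims)
        elif vals.shape != self.dims:
            raise GridError(f"values shape {vals.shape} != dims {self.dims}")
        object.__setattr__(self, "values", vals)
        if any(d < 1 for d in self.dims):
            raise GridError(f"non-positive dims {self.dims}")
        if any(s <= 0 for s in self.spacing_mm):
            raise GridError(f"non-positive spacing {self.spacing_mm}")
        if self.quantity in _NAN_ALLOWED:
            finite = vals[np.isfinite(vals)]
            if np.isinf(vals).any():
                raise GridError("infinite values not permitted")
            if finite.size and (finite < 0).any():
                raise GridError(f"negative {self.quantity.value} values")
        else:
            if not np.isfinite(vals).all():
                raise GridError(f"{self.quantity.value} grid must be finite")
            if (vals < 0).any():
                raise GridError(f"negative {self.quantity.value} values")

    # -- geometry helpers -------------------------------------------------

    @property
    def nvoxels(self) -> int:
        nz, ny, nx = self.dims
        return nz * ny * nx

    @property
    def geometry(self) -> tuple:
        return (self.dims, self.spacing_mm, self.origin_mm)

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis (0=z,1=y,2=x)."""
        return self.origin_mm[axis] + self.spacing_mm[axis] * np.arange(self.dims[axis])

    def with_values(self, values: np.ndarray, quantity: Quantity) -> "VoxelGrid":
        """New grid sharing this geometry."""
        return VoxelGrid(self.dims, self.spacing_mm, self.origin_mm, values, quantity)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return (
            self.geometry == other.geometry
            and self.quantity == other.quantity
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask on the geometry of a reference grid."""

    name: str
    dims: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))
        vals = np.asarray(self.values)
        if vals.dtype != bool:
            if not np.isin(vals, (0, 1)).all():
                raise GridError("mask values must be boolean / 0-1")
            vals = vals.astype(bool)
        if vals.ndim == 1:
            vals = vals.reshape(self.dims)
        if vals.shape != self.dims:
            raise GridError(f"mask shape {vals.shape} != dims {self.dims}")
        object.__setattr__(self, "values", vals)

    @property
    def geometry(self) -> tuple:
        return (self.dims, self.spacing_mm, self.origin_mm)

    @property
    def nvoxels_true(self) -> int:
        return int(self.values.sum())

    @classmethod
    def from_grid(cls, name: str, reference: VoxelGrid, values: np.ndarray) -> "ROIMask":
        return cls(name, reference.dims, reference.spacing_mm, reference.origin_mm, values)

    def to_grid(self) -> VoxelGrid:
        return VoxelGrid(self.dims, self.spacing_mm, self.origin_mm,
                         self.values.astype(np.float64), Quantity.MASK)


@dataclass(frozen=True)
class PlanBundle:
    """Co-registered dose + LET grids, ROI masks and the prescription."""

    dose: VoxelGrid
    let_t: VoxelGrid
    let_d: VoxelGrid
    masks: Mapping[str, ROIMask]
    prescription_Gy: float

    def __post_init__(self):
        if self.prescription_Gy <= 0:
            raise GridError("prescription must be positive")
        assert_coregistered([self.dose, self.let_t, self.let_d], *self.masks.values())
        if self.dose.quantity is not Quantity.DOSE:
            raise GridError("dose grid must carry quantity dose_Gy")
        if self.let_t.quantity is not Quantity.LET_T:
            raise GridError("let_t grid must carry quantity let_t_keV_per_um")
        if self.let_d.quantity is not Quantity.LET_D:
            raise GridError("let_d grid must carry quantity let_d_keV_per_um")
        dosed = self.dose.values > 0
        # LET_d >= LET_t wherever dose is deposited: a property of the two
        # averages (energy weighting can never fall below track weighting).
        if not (self.let_d.values[dosed] >= self.let_t.values[dosed] - 1e-9).all():
            raise GridError("let_d < let_t in dosed voxels")


def assert_coregistered(grids: Sequence[VoxelGrid], *masks: ROIMask) -> None:
    """Raise :class:`GeometryMismatchError` unless all geometries agree exactly.

    Values are never compared, only dims / spacing / origin.
    """
    items = list(grids) + list(masks)
    if len(items) < 2:
        raise ValueError("need at least two grids to compare")
    ref = items[0]
    for other in items[1:]:
        for name in ("dims", "spacing_mm", "origin_mm"):
            if getattr(ref, name) != getattr(other, name):
                raise GeometryMismatchError(
                    f"{name} mismatch: {getattr(ref, name)} vs {getattr(other, name)}"
                )


# ---------------------------------------------------------------------------
# Portable grid format
# ---------------------------------------------------------------------------

def write_grid(grid: VoxelGrid, path: str | Path, encoding: str = "csv") -> Path:
    """Write ``grid`` as a ``<stem>.vxg.json`` header plus payload file.

    ``csv`` payloads use shortest round-trip decimal representations and are
    exact for float64 values; ``f32le`` payloads are raw little-endian 32-bit
    floats and round-trip bit-exactly for float32-representable values.
    Returns the header path.
    """
    path = Path(path)
    if encoding not in ("csv", "f32le"):
        raise GridFormatError(f"unknown encoding {encoding!r}")
    stem = path.name
    for suffix in (".vxg.json", ".json", ".vxg"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    header_path = path.parent / f"{stem}.vxg.json"
    payload_name = f"{stem}.values.{'csv' if encoding == 'csv' else 'f32'}"
    payload_path = path.parent / payload_name

    flat = grid.values.ravel()
    if encoding == "csv":
        payload_path.write_text(",".join(repr(float(v)) for v in flat))
    else:
        payload_path.write_bytes(flat.astype("<f4").tobytes())
    header = {
        "dims": list(grid.dims),
        "spacing_mm": list(grid.spacing_mm),
        "origin_mm": list(grid.origin_mm),
        "quantity": grid.quantity.value,
        "payload": payload_name,
        "encoding": encoding,
    }
    header_path.write_text(json.dumps(header, indent=1))
    return header_path


def read_grid(path: str | Path) -> VoxelGrid:
    """Read a grid written by :func:`write_grid`."""
    path = Path(path)
    if not path.exists() and not str(path).endswith(".vxg.json"):
        candidate = path.parent / f"{path.name}.vxg.json"
        if candidate.exists():
            path = candidate
    if not path.exists():
        raise GridFormatError(f"missing header file {path}")
    try:
        header = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GridFormatError(f"malformed header {path}: {exc}") from exc
    for key in ("dims", "spacing_mm", "origin_mm", "quantity", "payload", "encoding"):
        if key not in header:
            raise GridFormatError(f"header missing key {key!r}")
    dims = tuple(header["dims"])
    if len(dims) != 3:
        raise GridFormatError(f"dims must have 3 entries, got {dims}")
    payload_path = path.parent / header["payload"]
    if not payload_path.exists():
        raise GridFormatError(f"missing payload file {payload_path}")
    encoding = header["encoding"]
    if encoding == "csv":
        text = payload_path.read_text().strip()
        values = np.array([float(tok) for tok in text.split(",")] if text else [])
    elif encoding == "f32le":
        values = np.frombuffer(payload_path.read_bytes(), dtype="<f4").astype(np.float64)
    else:
        raise GridFormatError(f"unknown encoding {encoding!r}")
    n_expected = dims[0] * dims[1] * dims[2]
    if values.size != n_expected:
        raise GridFormatError(
            f"payload has {values.size} values, expected {n_expected} for dims {dims}"
        )
    if any(s <= 0 for s in header["spacing_mm"]):
        raise GridFormatError(f"non-positive spacing {header['spacing_mm']}")
    return VoxelGrid(dims, header["spacing_mm"], header["origin_mm"],
                     values, Quantity(header["quantity"]))


def read_mask(path: str | Path, name: str | None = None) -> ROIMask:
    """Read an ROI mask stored as a 0/1 grid in the portable format."""
    grid = read_grid(path)
    if name is None:
        name = Path(path).name.split(".")[0]
    return ROIMask(name, grid.dims, grid.spacing_mm, grid.origin_mm, grid.values)


def import_rtdose(path: str | Path) -> VoxelGrid:
    """Import a DICOM RT-DOSE object as a dose grid in Gy.

    Stored integers are multiplied by DoseGridScaling; geometry comes from
    ImagePositionPatient / PixelSpacing / GridFrameOffsetVector.  Slice
    spacing must be uniform.  Only single-object import is supported.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise RTDoseImportError(f"not an RT-DOSE object (Modality={getattr(ds, 'Modality', None)!r})")
    if not hasattr(ds, "DoseGridScaling"):
        raise RTDoseImportError("RT-DOSE object missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    pixels = ds.pixel_array  # (frames, rows, cols) or (rows, cols)
    if pixels.ndim == 2:
        pixels = pixels[None]
    values = pixels.astype(np.float64) * scaling
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
    offsets = [float(v) for v in getattr(ds, "GridFrameOffsetVector", [0.0])]
    if len(offsets) > 1:
        dz = np.diff(offsets)
        if not np.allclose(dz, dz[0]):
            raise RTDoseImportError("non-uniform slice spacing in GridFrameOffsetVector")
        z_mm = abs(float(dz[0]))
    else:
        z_mm = float(getattr(ds, "SliceThickness", 0) or 1.0)
    origin = [float(v) for v in getattr(ds, "ImagePositionPatient", (0.0, 0.0, 0.0))]
    return VoxelGrid(
        dims=values.shape,
        spacing_mm=(z_mm, row_mm, col_mm),
        origin_mm=(origin[2], origin[1], origin[0]),
        values=values,
        quantity=Quantity.DOSE,
    )
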