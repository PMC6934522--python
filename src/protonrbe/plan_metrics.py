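"""Plan analysis products: DVHs, ROI statistics, line profiles, range extension.

Conventions (documented once, used everywhere):

* DVHs are cumulative, relative-volume ("% of ROI receiving >= dose"),
  computed by voxel counting without partial-volume weighting, default bin
  width 0.01 Gy.
* ROI statistics skip sentinel (NaN) voxels; an ROI whose defined voxels are
  exhausted is an error, not an empty record.
* Line profiles sample the nearest voxel at fixed arc-length steps; values
  are never interpolated, only the threshold-crossing *position* is.
* The distal biological range extension of a weighted-dose profile against
  the constant-RBE reference is the difference of the depths at which each
  profile falls through a fixed dose level on its distal falloff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .voxel_model import ROIMask, VoxelGrid, assert_coregistered


class PlanMetricsError(ValueError):
    pass


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume curve for one ROI."""

    roi: str
    dose_bins_Gy: np.ndarray
    cum_volume_pct: np.ndarray

    def __post_init__(self):
        bins = np.asarray(self.dose_bins_Gy, dtype=np.float64)
        vol = np.asarray(self.cum_volume_pct, dtype=np.float64)
        if bins.size != vol.size:
            raise PlanMetricsError("bins and volumes differ in length")
        if bins.size == 0 or bins[0] != 0.0 or (np.diff(bins) <= 0).any():
            raise PlanMetricsError("dose bins must increase from 0")
        if (np.diff(vol) > 1e-12).any():
            raise PlanMetricsError("cumulative volume must be non-increasing")
        if vol[0] != 100.0:
            raise PlanMetricsError("cumulative volume must start at 100%")
        object.__setattr__(self, "dose_bins_Gy", bins)
        object.__setattr__(self, "cum_volume_pct", vol)

    def volume_at(self, dose_Gy: float) -> float:
        """Volume % receiving at least ``dose_Gy`` (step interpolation)."""
        idx = np.searchsorted(self.dose_bins_Gy, dose_Gy, side="right") - 1
        if idx < 0:
            return 100.0
        return float(self.cum_volume_pct[idx])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"roi": self.roi, "dose_Gy": self.dose_bins_Gy,
             "volume_pct": self.cum_volume_pct}
        ).to_csv(path, index=False)


class ProfileSample(NamedTuple):
    """One sample on a line profile: arc length from start (mm) and value."""

    position_mm: float
    value: float


def _masked_values(grid: VoxelGrid, mask: ROIMask, *, drop_nan: bool) -> np.ndarray:
    assert_coregistered([grid], mask)
    if mask.nvoxels_true == 0:
        raise PlanMetricsError(f"mask {mask.name!r} is empty")
    vals = grid.values[mask.values]
    if drop_nan:
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise PlanMetricsError(f"mask {mask.name!r} contains only undefined voxels")
    return vals


def compute_dvh(grid: VoxelGrid, mask: ROIMask, bin_width_Gy: float = 0.01) -> DVHCurve:
    """Cumulative DVH of ``grid`` over ``mask``.

    ``cum_volume_pct[k]`` is the percentage of masked voxels with value
    >= ``dose_bins[k]``; bins run from 0 to the ROI maximum plus one bin, so
    the last bin is always above the maximum and carries 0%.
    """
    if bin_width_Gy <= 0:
        raise PlanMetricsError("bin width must be positive")
    vals = _masked_values(grid, mask, drop_nan=True)
    top = float(vals.max())
    n_bins = int(np.floor(top / bin_width_Gy)) + 2
    bins = np.arange(n_bins) * bin_width_Gy
    sorted_vals = np.sort(vals)
    # voxels >= bin == n - (number strictly below bin)
    below = np.searchsorted(sorted_vals, bins, side="left")
    cum_pct = 100.0 * (vals.size - below) / vals.size
    return DVHCurve(mask.name, bins, cum_pct)


def roi_stats(grid: VoxelGrid, mask: ROIMask) -> dict:
    """min / max / mean / D2% over the defined (non-NaN) masked voxels.

    D2% is the smallest observed value v such that the fraction of masked
    voxels with value >= v is at most 2% — the near-maximum metric used for
    serial organs.  If even the maximum is exceeded by more than 2% of the
    volume (tiny ROIs), the maximum is returned.
    """
    vals = _masked_values(grid, mask, drop_nan=True)
    sorted_vals = np.sort(vals)
    n = vals.size
    frac_ge = (n - np.searchsorted(sorted_vals, sorted_vals, side="left")) / n
    qualifying = sorted_vals[frac_ge <= 0.02]
    d2 = float(qualifying[0]) if qualifying.size else float(sorted_vals[-1])
    return {
        "roi": mask.name,
        "n_voxels": int(n),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "D2pct": d2,
    }


def line_profile(
    grid: VoxelGrid,
    start_mm: Sequence[float],
    end_mm: Sequence[float],
    step_mm: float,
) -> list[ProfileSample]:
    """Nearest-voxel samples along the segment start -> end at fixed steps.

    Coordinates are physical (z, y, x) mm.  Samples falling outside the grid
    are dropped; positions are arc lengths from ``start_mm``.
    """
    start = np.asarray(start_mm, dtype=np.float64)
    end = np.asarray(end_mm, dtype=np.float64)
    if step_mm <= 0:
        raise PlanMetricsError("step must be positive")
    length = float(np.linalg.norm(end - start))
    if length == 0:
        raise PlanMetricsError("degenerate segment: start equals end")
    direction = (end - start) / length
    positions = np.arange(0.0, length + 0.5 * step_mm, step_mm)
    origin = np.asarray(grid.origin_mm)
    spacing = np.asarray(grid.spacing_mm)
    samples: list[ProfileSample] = []
    for t in positions:
        point = start + t * direction
        idx = np.rint((point - origin) / spacing).astype(int)
        if (idx < 0).any() or (idx >= np.asarray(grid.dims)).any():
            continue
        samples.append(ProfileSample(float(t), float(grid.values[tuple(idx)])))
    if not samples:
        raise PlanMetricsError("segment does not intersect the grid")
    return samples


def _distal_crossing(profile: Sequence[ProfileSample], level: float) -> float:
    """Depth at which the profile last falls through ``level``.

    Scans from the distal end for the first pair bracketing the level
    (value >= level then < level) and interpolates the position linearly.
    """
    pos = np.asarray([s.position_mm for s in profile])
    val = np.asarray([s.value for s in profile])
    if (np.diff(pos) <= 0).any():
        raise PlanMetricsError("profile positions must be strictly increasing")
    if val[-1] >= level:
        raise PlanMetricsError("profile does not fall below the level at its distal end")
    for i in range(len(val) - 2, -1, -1):
        if val[i] >= level:
            frac = (val[i] - level) / (val[i] - val[i + 1])
            return float(pos[i] + frac * (pos[i + 1] - pos[i]))
    raise PlanMetricsError("profile never reaches the level")


def distal_extension(
    reference: Sequence[ProfileSample],
    weighted: Sequence[ProfileSample],
    level_Gy: float,
) -> float:
    """Distal biological range extension of ``weighted`` beyond ``reference``, mm.

    Both profiles must cross ``level_Gy`` on their distal falloff; the
    reference is conventionally the constant-RBE (1.1 x physical dose)
    profile.  Positive values mean the weighted dose maintains the level
    deeper than the reference — biological effect beyond the physical
    falloff.
    """
    if level_Gy <= 0:
        raise PlanMetricsError("level must be positive")
    return _distal_crossing(weighted, level_Gy) - _distal_crossing(reference, level_Gy)


def stats_to_json(stats: Sequence[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(stats), indent=1, sort_keys=True))


def profile_to_csv(profile: Sequence[ProfileSample], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(profile, columns=["position_mm", "value"]).to_csv(path, index=False)
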