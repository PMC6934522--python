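"""LET averaging from particle step records and multi-field LET mixing.

Two averages of linear energy transfer are in common use.  For a collection
of particle steps in one voxel, each depositing energy dE_i (keV) over path
length dl_i (um), the per-step LET is L_i = dE_i/dl_i and

* dose-averaged LET weights each step's LET by its share of local energy:
  LET_d = sum_i (dE_i / sum dE) * L_i
* track-averaged (fluence-averaged) LET weights by path length:
  LET_t = sum_i (dl_i / sum dl) * L_i = sum dE / sum dl

Energy weighting can never fall below track weighting (Cauchy-Schwarz), so
LET_d >= LET_t always, with equality iff every step shares one LET.

Per-field voxel LET values are combined into a composite plan value using the
fluence proxy phi_i = D_i / L_i, which reproduces track-weighted averaging
when each field contribution is mono-LET; dose-averaged mixing is the plain
dose-weighted mean.  This mixing rule is an explicit modelling assumption,
not a transport result.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np


class StepRecord(NamedTuple):
    """One particle step: energy deposited (keV) over a path length (um)."""

    deltaE_keV: float
    deltaL_um: float


class FieldContribution(NamedTuple):
    """One field's voxel contribution: dose (Gy) and its single-valued LET."""

    dose_Gy: float
    let_keV_per_um: float


class LETScoringError(ValueError):
    pass


def _step_arrays(steps: Sequence[StepRecord]) -> tuple[np.ndarray, np.ndarray]:
    if len(steps) == 0:
        raise LETScoringError("no step records supplied")
    de = np.asarray([s[0] for s in steps], dtype=np.float64)
    dl = np.asarray([s[1] for s in steps], dtype=np.float64)
    if (dl <= 0).any():
        raise LETScoringError("step path lengths must be positive")
    if (de < 0).any():
        raise LETScoringError("step energy deposits must be non-negative")
    return de, dl


def let_d_from_steps(steps: Sequence[StepRecord]) -> float:
    """Dose-averaged LET of a step collection, keV/um."""
    de, dl = _step_arrays(steps)
    total = de.sum()
    if total <= 0:
        raise LETScoringError("total deposited energy is zero")
    return float(np.sum((de / total) * (de / dl)))


def let_t_from_steps(steps: Sequence[StepRecord]) -> float:
    """Track-averaged LET of a step collection, keV/um (= sum dE / sum dl)."""
    de, dl = _step_arrays(steps)
    return float(de.sum() / dl.sum())


def mix_let_t(contribs: Sequence[FieldContribution]) -> float:
    """Composite track-averaged LET of per-field contributions.

    Uses the fluence proxy phi_i = D_i / L_i:  result = sum D_i / sum(D_i/L_i).
    Zero-dose contributions are ignored.
    """
    d = np.asarray([c[0] for c in contribs], dtype=np.float64)
    let = np.asarray([c[1] for c in contribs], dtype=np.float64)
    keep = d > 0
    if not keep.any():
        raise LETScoringError("all field doses are zero")
    if (let[keep] <= 0).any():
        raise LETScoringError("field LET must be positive where dose > 0")
    return float(d[keep].sum() / np.sum(d[keep] / let[keep]))


def mix_let_d(contribs: Sequence[FieldContribution]) -> float:
    """Composite dose-averaged LET: dose-weighted mean of per-field LET."""
    d = np.asarray([c[0] for c in contribs], dtype=np.float64)
    let = np.asarray([c[1] for c in contribs], dtype=np.float64)
    keep = d > 0
    if not keep.any():
        raise LETScoringError("all field doses are zero")
    return float(np.sum(d[keep] * let[keep]) / d[keep].sum())


def read_steps_csv(path: str | Path) -> list[StepRecord]:
    """Read step records from CSV with header ``deltaE_keV,deltaL_um``."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"deltaE_keV", "deltaL_um"} - set(df.columns)
    if missing:
        raise LETScoringError(f"step CSV missing columns {sorted(missing)}")
    return [StepRecord(float(e), float(l))
            for e, l in zip(df["deltaE_keV"], df["deltaL_um"])]


# Vectorized mixing over grids -------------------------------------------------

def mix_let_t_arrays(doses: Iterable[np.ndarray], lets: Iterable[np.ndarray]) -> np.ndarray:
    """Voxel-wise :func:`mix_let_t` over stacked component arrays.

    Voxels with zero total dose get LET 0 (no particle ever crossed them).
    """
    doses = list(doses)
    lets = list(lets)
    total = np.sum(doses, axis=0)
    denom = np.zeros_like(total)
    for d, l in zip(doses, lets):
        contrib = np.zeros_like(total)
        np.divide(d, l, out=contrib, where=(d > 0) & (l > 0))
        denom += contrib
    out = np.zeros_like(total)
    np.divide(total, denom, out=out, where=denom > 0)
    return out


def mix_let_d_arrays(doses: Iterable[np.ndarray], lets: Iterable[np.ndarray]) -> np.ndarray:
    """Voxel-wise :func:`mix_let_d` over stacked component arrays."""
    doses = list(doses)
    lets = list(lets)
    total = np.sum(doses, axis=0)
    num = np.sum([d * l for d, l in zip(doses, lets)], axis=0)
    out = np.zeros_like(total)
    np.divide(num, total, out=out, where=total > 0)
    return out
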