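"""Biological-effect models: RBE and RBE-weighted dose per voxel.

Six weighting schemes are implemented, all as pure scalar functions that
broadcast over numpy arrays, plus a grid applicator.

constant        Dose_c  = 1.1 * D                               (clinical default)
let_weighted    Dose_w  = D * (1 + kappa * LET_d)
mcnamara        Dose_Mc = D * RBE(D, LET_d, alpha/beta)          (LQ-based fit)
mm_residual     Dose_r  = D * (d*LET_t + e) * c / gamma_r
mm_misrepair    Dose_m  = D * (d*LET_t + e) * (a*(f*LET_t^2 + g*LET_t + h) + b)
                           * (1 - c) / gamma_m
mm_combined     Dose_rm = D * (num_r + num_m) / (gamma_r + gamma_m)

The mm_* correlations predict yields of residual (unrepaired at 24 h) and
misrepaired DNA double-strand breaks per cell as a function of track-averaged
LET, normalised to the corresponding photon yields per Gy (gamma_r, gamma_m).
They are mechanistic-model fits for a generic cell: no tissue alpha/beta
enters, and with dose factored out the RBE depends on LET_t only.

LET flavour is part of each model's contract: the LET-weighted and McNamara
models take dose-averaged LET, the mechanistic correlations take
track-averaged LET.  Supplying the wrong flavour raises, it is never
silently substituted.

A note on kappa: published values for the LET-weighted dose fitting
parameter differ by a factor of ten between sources (0.055 vs 0.0055
um/keV).  The default here is 0.055 um/keV; it is configurable through
:class:`LetWeightParams` or the JSON parameter file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .voxel_model import (
    Quantity,
    ROIMask,
    VoxelGrid,
    assert_coregistered,
)

logger = logging.getLogger(__name__)

#: Below this dose (Gy) the McNamara RBE uses its analytic D -> 0 limit.
MCNAMARA_DOSE_EPS = 1e-6


class RBEModelError(ValueError):
    pass


class ModelName(str, Enum):
    CONSTANT = "constant"
    LET_WEIGHTED = "let_weighted"
    MCNAMARA = "mcnamara"
    MM_RESIDUAL = "mm_residual"
    MM_MISREPAIR = "mm_misrepair"
    MM_COMBINED = "mm_combined"


#: LET flavour each model consumes (None: no LET input).
MODEL_LET_FLAVOUR: dict[ModelName, Quantity | None] = {
    ModelName.CONSTANT: None,
    ModelName.LET_WEIGHTED: Quantity.LET_D,
    ModelName.MCNAMARA: Quantity.LET_D,
    ModelName.MM_RESIDUAL: Quantity.LET_T,
    ModelName.MM_MISREPAIR: Quantity.LET_T,
    ModelName.MM_COMBINED: Quantity.LET_T,
}


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LetWeightParams:
    """kappa (um/keV) for the LET-weighted dose D*(1 + kappa*LET_d)."""

    kappa: float = 0.055

    def __post_init__(self):
        if self.kappa < 0:
            raise RBEModelError("kappa must be >= 0")


@dataclass(frozen=True)
class McNamaraParams:
    """Fit coefficients of the phenomenological LQ-based proton RBE model.

    RBE_max = z1 + (z2 / (alpha/beta)) * LET_d   (low-dose asymptote)
    RBE_min = z3 - z4 * sqrt(alpha/beta)         (high-dose asymptote)
    """

    z1: float = 0.99064
    z2: float = 0.35605  # Gy um / keV
    z3: float = 1.1012
    z4: float = 0.00387  # Gy^(-1/2)

    def __post_init__(self):
        if not (np.isfinite([self.z1, self.z2, self.z3, self.z4]).all()):
            raise RBEModelError("McNamara parameters must be finite")
        if self.z1 <= 0 or self.z3 <= 0:
            raise RBEModelError("z1 and z3 must be positive")


@dataclass(frozen=True)
class MMParams:
    """Coefficients of the residual / misrepair DSB-yield correlations.

    a, b, c, h are dimensionless; d has units um/(keV Gy), e 1/Gy,
    f um^2/keV^2, g um/keV.  gamma_r and gamma_m are the residual and
    misrepaired DSB yields per Gy of Cobalt-60 photons.  c is the fraction
    of (d*LET_t + e) assigned to the residual endpoint, so 0 < c < 1, and
    the residual photon yield exceeds the misrepair one (gamma_r > gamma_m).
    """

    a: float = 0.1966
    b: float = 0.008
    c: float = 0.0736
    d: float = 1.149
    e: float = 24.1
    f: float = 4.879e-4
    g: float = 2.84e-3
    h: float = 5.13e-2
    gamma_r: float = 1.726
    gamma_m: float = 0.0427

    def __post_init__(self):
        vals = [self.a, self.b, self.c, self.d, self.e,
                self.f, self.g, self.h, self.gamma_r, self.gamma_m]
        if any(v <= 0 for v in vals):
            raise RBEModelError("all mechanistic-correlation parameters must be > 0")
        if not 0 < self.c < 1:
            raise RBEModelError("c must lie in (0, 1)")
        if self.gamma_r <= self.gamma_m:
            raise RBEModelError("gamma_r must exceed gamma_m")


@dataclass(frozen=True)
class TissueParams:
    """Per-ROI alpha/beta (Gy) for the McNamara model.

    ``priority`` resolves overlaps: the first listed ROI containing a voxel
    wins.  ``default_alpha_beta_Gy`` applies outside every listed ROI.
    """

    alpha_beta_Gy: Mapping[str, float] = field(
        default_factory=lambda: {"ptv": 10.0, "brainstem": 2.0, "spinal_cord": 2.0}
    )
    priority: tuple[str, ...] = ("spinal_cord", "brainstem", "ptv")
    default_alpha_beta_Gy: float = 2.0

    def __post_init__(self):
        if any(v <= 0 for v in self.alpha_beta_Gy.values()):
            raise RBEModelError("alpha/beta values must be positive")
        if self.default_alpha_beta_Gy <= 0:
            raise RBEModelError("default alpha/beta must be positive")


@dataclass(frozen=True)
class ModelParams:
    """The full parameter bundle: one block per model family."""

    let_weighted: LetWeightParams = field(default_factory=LetWeightParams)
    mcnamara: McNamaraParams = field(default_factory=McNamaraParams)
    mm: MMParams = field(default_factory=MMParams)
    uncertainty_pct: Mapping[str, float] = field(default_factory=dict)


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load the parameter file; ``None`` loads the packaged defaults.

    A user file only needs the keys it overrides; anything absent falls back
    to the packaged default value.
    """
    with resources.files("protonrbe.data").joinpath("default_params.json").open() as fh:
        payload = json.load(fh)
    if path is not None:
        user = json.loads(Path(path).read_text())
        for block, entries in user.items():
            payload.setdefault(block, {}).update(entries)
    params = ModelParams(
        let_weighted=LetWeightParams(**payload.get("let_weighted", {})),
        mcnamara=McNamaraParams(**payload.get("mcnamara", {})),
        mm=MMParams(**payload.get("mm", {})),
        uncertainty_pct=payload.get("uncertainty_pct", {}),
    )
    logger.info(
        "model parameters loaded (kappa = %g um/keV; published kappa values "
        "differ tenfold between sources and the value is configurable)",
        params.let_weighted.kappa,
    )
    return params


# ---------------------------------------------------------------------------
# Scalar models (broadcast over arrays)
# ---------------------------------------------------------------------------

def _check_nonneg(name, value):
    if np.any(np.asarray(value) < 0):
        raise RBEModelError(f"{name} must be non-negative")


def dose_constant(dose_Gy):
    """RBE-weighted dose under the clinical constant RBE of 1.1."""
    _check_nonneg("dose", dose_Gy)
    return 1.1 * np.asarray(dose_Gy, dtype=np.float64)


def dose_let_weighted(dose_Gy, let_d, p: LetWeightParams = LetWeightParams()):
    """LET-weighted dose D * (1 + kappa * LET_d), Gy."""
    _check_nonneg("dose", dose_Gy)
    _check_nonneg("let_d", let_d)
    return np.asarray(dose_Gy, dtype=np.float64) * (1.0 + p.kappa * np.asarray(let_d))


def rbe_mcnamara(dose_Gy, let_d, alpha_beta_Gy, p: McNamaraParams = McNamaraParams()):
    """McNamara RBE(D, LET_d, alpha/beta).

    RBE = (sqrt(ab^2 + 4 D ab RBE_max + 4 D^2 RBE_min^2) - ab) / (2 D)
    with RBE_max = z1 + (z2/ab) LET_d and RBE_min = z3 - z4 sqrt(ab).
    For D below :data:`MCNAMARA_DOSE_EPS` the analytic D -> 0 limit RBE_max
    is returned (the closed form is 0/0 there).
    """
    _check_nonneg("dose", dose_Gy)
    _check_nonneg("let_d", let_d)
    ab = np.asarray(alpha_beta_Gy, dtype=np.float64)
    if np.any(ab <= 0):
        raise RBEModelError("alpha/beta must be positive")
    d = np.asarray(dose_Gy, dtype=np.float64)
    let = np.asarray(let_d, dtype=np.float64)
    rbe_max = p.z1 + (p.z2 / ab) * let
    rbe_min = p.z3 - p.z4 * np.sqrt(ab)
    d_safe = np.where(d < MCNAMARA_DOSE_EPS, 1.0, d)
    root = np.sqrt(ab**2 + 4.0 * d_safe * ab * rbe_max + 4.0 * d_safe**2 * rbe_min**2)
    rbe = (root - ab) / (2.0 * d_safe)
    out = np.where(d < MCNAMARA_DOSE_EPS, rbe_max, rbe)
    return out if out.ndim else float(out)


def dose_mcnamara(dose_Gy, let_d, alpha_beta_Gy, p: McNamaraParams = McNamaraParams()):
    """McNamara RBE-weighted dose D * RBE, Gy."""
    return np.asarray(dose_Gy, dtype=np.float64) * rbe_mcnamara(dose_Gy, let_d, alpha_beta_Gy, p)


def _residual_numerator(let_t, p: MMParams):
    return (p.d * let_t + p.e) * p.c


def _misrepair_numerator(let_t, p: MMParams):
    return ((p.d * let_t + p.e)
            * (p.a * (p.f * let_t**2 + p.g * let_t + p.h) + p.b)
            * (1.0 - p.c))


def rbe_residual(let_t, p: MMParams = MMParams()):
    """RBE for the residual-DSB endpoint: (d*LET_t + e)*c / gamma_r.

    Affine and strictly increasing in LET_t; at LET_t = 0 it equals
    e*c/gamma_r (~1.03 with the default parameters), the floor of any
    residual-RBE map.
    """
    let = np.asarray(let_t, dtype=np.float64)
    _check_nonneg("let_t", let)
    out = _residual_numerator(let, p) / p.gamma_r
    return out if out.ndim else float(out)


def rbe_misrepair(let_t, p: MMParams = MMParams()):
    """RBE for the misrepaired-DSB endpoint (strictly increasing in LET_t).

    Large in absolute terms (order 10) because misrepair is rare under
    photon irradiation: the photon denominator gamma_m is small.
    """
    let = np.asarray(let_t, dtype=np.float64)
    _check_nonneg("let_t", let)
    out = _misrepair_numerator(let, p) / p.gamma_m
    return out if out.ndim else float(out)


def rbe_combined(let_t, p: MMParams = MMParams()):
    """RBE for the pooled residual + misrepair endpoint.

    Satisfies exactly
    (gamma_r + gamma_m) * RBE_rm = gamma_r * RBE_r + gamma_m * RBE_m,
    i.e. it is the photon-yield-weighted pooling of the two endpoints.
    """
    let = np.asarray(let_t, dtype=np.float64)
    _check_nonneg("let_t", let)
    out = (_residual_numerator(let, p) + _misrepair_numerator(let, p)) / (p.gamma_r + p.gamma_m)
    return out if out.ndim else float(out)


def residual_misrepair_ratio(let_t, p: MMParams = MMParams()):
    """Ratio of predicted residual to misrepaired DSB yields per cell.

    Dose cancels (both yields share the factor D*(d*LET_t + e)), leaving
    c / ((a*(f*LET_t^2 + g*LET_t + h) + b) * (1 - c)):
    strictly decreasing in LET_t — misrepair catches up at high LET.
    """
    let = np.asarray(let_t, dtype=np.float64)
    _check_nonneg("let_t", let)
    out = p.c / ((p.a * (p.f * let**2 + p.g * let + p.h) + p.b) * (1.0 - p.c))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Grid application
# ---------------------------------------------------------------------------

def alpha_beta_grid(
    reference: VoxelGrid,
    masks: Mapping[str, ROIMask],
    tissue: TissueParams,
) -> np.ndarray:
    """Per-voxel alpha/beta from ROI masks, most-specific ROI first.

    ROIs listed in ``tissue.priority`` are painted in reverse priority order
    so the highest-priority ROI ends up on top; voxels in no listed ROI get
    the default value.
    """
    ab = np.full(reference.dims, tissue.default_alpha_beta_Gy, dtype=np.float64)
    for name in reversed(tissue.priority):
        if name in masks and name in tissue.alpha_beta_Gy:
            ab[masks[name].values] = tissue.alpha_beta_Gy[name]
    return ab


def apply_model(
    dose: VoxelGrid,
    let: VoxelGrid | None,
    model: ModelName | str,
    params: ModelParams | None = None,
    *,
    alpha_beta=None,
    masks: Mapping[str, ROIMask] | None = None,
    tissue: TissueParams | None = None,
) -> tuple[VoxelGrid, VoxelGrid]:
    """Apply one model voxel-wise; returns (weighted_dose, rbe_map).

    The RBE map is NaN wherever dose = 0 (RBE is a ratio of doses and is
    undefined without dose); the weighted dose is 0 there.  For the McNamara
    model supply either a scalar/array ``alpha_beta`` or ``masks`` plus
    ``tissue`` to build the per-voxel alpha/beta from ROI labels.
    """
    model = ModelName(model)
    params = params or ModelParams()
    flavour = MODEL_LET_FLAVOUR[model]
    if flavour is None:
        let_values = None
    else:
        if let is None:
            raise RBEModelError(f"model {model.value} requires a {flavour.value} grid")
        if let.quantity is not flavour:
            raise RBEModelError(
                f"model {model.value} requires {flavour.value}, got {let.quantity.value}"
            )
        assert_coregistered([dose, let])
        let_values = let.values

    d = dose.values
    if model is ModelName.CONSTANT:
        rbe = np.full(dose.dims, 1.1)
    elif model is ModelName.LET_WEIGHTED:
        rbe = 1.0 + params.let_weighted.kappa * let_values
    elif model is ModelName.MCNAMARA:
        if alpha_beta is None:
            if masks is None or tissue is None:
                raise RBEModelError(
                    "mcnamara requires alpha_beta, or masks plus tissue parameters"
                )
            alpha_beta = alpha_beta_grid(dose, masks, tissue)
        rbe = rbe_mcnamara(d, let_values, alpha_beta, params.mcnamara)
    elif model is ModelName.MM_RESIDUAL:
        rbe = np.broadcast_to(rbe_residual(let_values, params.mm), dose.dims)
    elif model is ModelName.MM_MISREPAIR:
        rbe = np.broadcast_to(rbe_misrepair(let_values, params.mm), dose.dims)
    elif model is ModelName.MM_COMBINED:
        rbe = np.broadcast_to(rbe_combined(let_values, params.mm), dose.dims)
    else:  # pragma: no cover
        raise RBEModelError(f"unhandled model {model}")

    dosed = d > 0
    rbe_map = np.where(dosed, rbe, np.nan)
    weighted = np.where(dosed, d * rbe, 0.0)
    return (
        dose.with_values(weighted, Quantity.WEIGHTED_DOSE),
        dose.with_values(rbe_map, Quantity.RBE),
    )


def ratio_map(dose: VoxelGrid, let_t: VoxelGrid, params: ModelParams | None = None) -> VoxelGrid:
    """Residual:misrepair yield-ratio grid; NaN where dose = 0."""
    params = params or ModelParams()
    if let_t.quantity is not Quantity.LET_T:
        raise RBEModelError(f"ratio map requires let_t, got {let_t.quantity.value}")
    assert_coregistered([dose, let_t])
    ratio = residual_misrepair_ratio(let_t.values, params.mm)
    out = np.where(dose.values > 0, ratio, np.nan)
    return dose.with_values(out, Quantity.RATIO)
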