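"""Voxel-wise PK model fitting and parsimonious (AIC-based) model selection.

Each masked voxel's concentration curve is fitted with all three candidate
models (Patlak, 2CFM, 2CFM-O) by bounded trust-region nonlinear least squares
with a small multi-start grid, and the model with the lowest small-sample
corrected Akaike criterion (AICc) is selected per voxel — the parsimonious
model.  The module also produces the F_T, model-choice and R-squared maps and
the fraction-of-voxels-above-R²-threshold quality summary used to compare the
parsimonious approach against each single model.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .tracer_kinetics import (
    ConcentrationCurve,
    PatlakParams,
    TCFMOParams,
    TCFMParams,
    TimeGrid,
    patlak_forward,
    tcfm_forward,
    tcfmo_forward,
)

__all__ = [
    "MODEL_ORDER",
    "K_PARAMS",
    "VoxelFit",
    "ParametricMap",
    "aic",
    "r_squared",
    "fit_voxel",
    "select_parsimonious",
    "fit_roi",
    "voxel_quality_summary",
]

#: Fixed model order, also the tie-break order in selection.
MODEL_ORDER = ("patlak", "2cfm", "2cfmo")

#: Free-parameter counts per model (baseline offsets are corrected upstream).
K_PARAMS = {"patlak": 2, "2cfm": 3, "2cfmo": 3}

#: Literature-style starting values; each start is also scaled by 0.3 and 3.
DEFAULT_INITS = {
    "patlak": {"Vp": 0.2, "FT": 0.5},
    "2cfm": {"Vp": 0.2, "FT": 0.5, "TT": 1.0},
    "2cfmo": {"k1": 2.0, "FT": 0.5, "k2": 0.1},
}

DEFAULT_BOUNDS = {
    "patlak": ([0.0, 0.0], [1.0, 50.0]),
    "2cfm": ([0.0, 0.0, 1e-3], [1.0, 50.0, 1e4]),
    "2cfmo": ([0.0, 0.0, 0.0], [1e3, 50.0, 50.0]),
}

START_SCALES = (1.0, 0.3, 3.0)

_RSS_FLOOR = 1e-12
_MAX_NFEV = 500


@dataclass(frozen=True)
class VoxelFit:
    """One candidate model's fit of one voxel."""

    model_id: str
    params: object
    rss: float
    n_points: int
    k_params: int
    aic: float
    r2: float
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_ORDER:
            raise ValueError(f"unknown model_id {self.model_id!r}")


@dataclass
class ParametricMap:
    """A scalar parameter map over a masked grid with physical spacing (mm)."""

    values: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes must match")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def aic(rss: float, n_points: int, k_params: int) -> float:
    """Small-sample corrected Akaike criterion (AICc) from a least-squares RSS.

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1).  RSS is floored at 1e-12 so
    that noiseless fits do not produce -inf.
    """
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if n_points <= k_params + 1:
        raise ValueError("need n_points > k_params + 1")
    rss = max(rss, _RSS_FLOOR)
    n, k = n_points, k_params
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    """Coefficient of determination 1 - RSS/TSS (may be negative).

    Constant observed data has no defined R²; NaN is returned as the flag.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal length")
    if obs.size < 3:
        raise ValueError("need at least 3 points")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        return float("nan")
    rss = float(np.sum((obs - fit) ** 2))
    return 1.0 - rss / tss


def _forward(model_id: str, theta: np.ndarray, cp: ConcentrationCurve,
             c3: ConcentrationCurve | None) -> np.ndarray:
    # 2CFM is optimized over the washout rate kT = 1/TT so the nested
    # Patlak limit (TT -> inf) is a finite bound, not a runaway direction.
    if model_id == "patlak":
        return patlak_forward(PatlakParams(*theta), cp).values
    if model_id == "2cfm":
        vp, ft, kt = theta
        return tcfm_forward(TCFMParams(vp, ft, 1.0 / kt), cp).values
    if model_id == "2cfmo":
        return tcfmo_forward(TCFMOParams(*theta), cp, c3).values
    raise ValueError(f"unknown model_id {model_id!r}")


def _to_internal(model_id: str, theta: np.ndarray) -> np.ndarray:
    if model_id == "2cfm":
        return np.array([theta[0], theta[1], 1.0 / theta[2]])
    return np.asarray(theta, dtype=float)


def _params_obj(model_id: str, theta: np.ndarray):
    if model_id == "2cfm":
        return TCFMParams(float(theta[0]), float(theta[1]), float(1.0 / theta[2]))
    cls = {"patlak": PatlakParams, "2cfmo": TCFMOParams}[model_id]
    return cls(*[float(v) for v in theta])


def fit_voxel(
    model_id: str,
    curve: ConcentrationCurve,
    cp: ConcentrationCurve,
    c3: ConcentrationCurve | None = None,
    inits: dict | None = None,
    bounds: tuple | None = None,
    start_scales: Sequence[float] = START_SCALES,
    max_nfev: int = _MAX_NFEV,
) -> VoxelFit:
    """Fit one model to one voxel by bounded multi-start least squares."""
    if model_id not in MODEL_ORDER:
        raise ValueError(f"unknown model_id {model_id!r}")
    if model_id == "2cfmo" and c3 is None:
        raise ValueError("2cfmo requires a C3 (inner-medullary-papilla) curve")
    if not curve.grid.matches(cp.grid):
        raise ValueError("curve and cp must share a grid")
    obs = curve.values
    x0_base = np.array(list((inits or DEFAULT_INITS[model_id]).values()), dtype=float)
    lo, hi = bounds or DEFAULT_BOUNDS[model_id]
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if model_id == "2cfm":
        # natural-space (Vp, FT, TT) bounds become (Vp, FT, kT) with kT = 1/TT
        lo, hi = (np.array([lo[0], lo[1], 1.0 / hi[2]]),
                  np.array([hi[0], hi[1], 1.0 / lo[2]]))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _forward(model_id, theta, cp, c3) - obs

    best = None
    any_success = False
    for scale in start_scales:
        x0 = np.clip(_to_internal(model_id, x0_base * scale), lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                max_nfev=max_nfev, xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:  # pragma: no cover - solver failure path
            continue
        if res.status <= 0:
            continue
        any_success = True
        if best is None or res.cost < best.cost:
            best = res
    n = obs.size
    k = K_PARAMS[model_id]
    if not any_success or best is None:
        return VoxelFit(
            model_id=model_id, params=None, rss=float("inf"), n_points=n,
            k_params=k, aic=float("inf"), r2=float("nan"),
            success=False, message="no start converged",
        )
    rss = float(2.0 * best.cost)
    fitted = _forward(model_id, best.x, cp, c3)
    return VoxelFit(
        model_id=model_id,
        params=_params_obj(model_id, best.x),
        rss=rss,
        n_points=n,
        k_params=k,
        aic=aic(rss, n, k),
        r2=r_squared(obs, fitted),
        success=True,
    )


def select_parsimonious(fits: Iterable[VoxelFit]) -> VoxelFit:
    """Pick the minimum-AIC fit; ties go to fewer parameters, then model order."""
    ok = [f for f in fits if f.success]
    if not ok:
        raise ValueError("all fits failed for this voxel")
    return min(ok, key=lambda f: (f.aic, f.k_params, MODEL_ORDER.index(f.model_id)))


def _model_code(model_id: str) -> int:
    return MODEL_ORDER.index(model_id) + 1


def fit_roi(
    conc_4d: np.ndarray,
    mask: np.ndarray,
    cp: ConcentrationCurve,
    c3: ConcentrationCurve | None = None,
    grid: TimeGrid | None = None,
    spacing: tuple[float, ...] = (1.0, 1.0),
    models: Sequence[str] = MODEL_ORDER,
    inits: dict | None = None,
) -> dict:
    """Fit all candidate models voxel-wise over a mask and select per voxel.

    Parameters
    ----------
    conc_4d:
        Concentration array of shape ``spatial + (n_times,)`` (already
        converted from signal and baseline-corrected).
    mask:
        Boolean array over the spatial axes; must be non-empty.
    cp:
        Shared plasma input curve; ``c3`` is the shared ROI-average
        inner-medullary-papilla curve, required when '2cfmo' is fitted.

    Returns a dict with ``ft_map``, ``choice_map`` (1=Patlak, 2=2CFM,
    3=2CFM-O, 0/NaN = unfit), ``r2_map``, the per-model R² maps, a tidy
    per-voxel fit table, and the count of failed voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    grid = grid or cp.grid
    spatial = conc_4d.shape[:-1]
    if mask.shape != spatial:
        raise ValueError("mask shape must match the spatial image shape")
    ft = np.full(spatial, np.nan)
    choice = np.zeros(spatial, dtype=float)
    r2 = np.full(spatial, np.nan)
    per_model_r2 = {m: np.full(spatial, np.nan) for m in models}
    rows = []
    n_failed = 0
    for idx in np.argwhere(mask):
        tidx = tuple(idx)
        curve = ConcentrationCurve(grid=grid, values=conc_4d[tidx], role="tissue")
        fits = []
        for m in models:
            f = fit_voxel(m, curve, cp, c3=c3 if m == "2cfmo" else None,
                          inits=(inits or {}).get(m) if inits else None)
            fits.append(f)
            if f.success:
                per_model_r2[m][tidx] = f.r2
            rows.append({
                "voxel": tidx, "model": m, "success": f.success,
                "rss": f.rss, "aic": f.aic, "r2": f.r2,
                "params": None if f.params is None else dataclasses.asdict(f.params),
            })
        try:
            win = select_parsimonious(fits)
        except ValueError:
            n_failed += 1
            continue
        ft[tidx] = win.params.FT
        choice[tidx] = _model_code(win.model_id)
        r2[tidx] = win.r2
    return {
        "ft_map": ParametricMap(ft, mask, spacing),
        "choice_map": ParametricMap(choice, mask, spacing),
        "r2_map": ParametricMap(r2, mask, spacing),
        "per_model_r2": {m: ParametricMap(v, mask, spacing) for m, v in per_model_r2.items()},
        "fits": pd.DataFrame(rows),
        "n_failed": n_failed,
    }


def voxel_quality_summary(r2_map: ParametricMap, threshold: float = 0.70) -> float:
    """Percentage of masked voxels with R² above ``threshold``.

    Failed (NaN) voxels count in the denominator, matching the convention
    that unfit voxels degrade the quality summary.
    """
    vals = r2_map.masked_values()
    if vals.size == 0:
        raise ValueError("empty mask")
    good = np.sum(vals > threshold)  # NaN compares False
    return 100.0 * float(good) / float(vals.size)
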