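"""Diffusion-weighted MRI fitting: mono-exponential ADC and bi-exponential IVIM.

The mono-exponential model S(b) = S0 exp(-b*ADC) is fitted log-linearly over
the full b-value set.  The intravoxel incoherent motion (IVIM) model

    S(b) = S0 [ f exp(-b*D*) + (1 - f) exp(-b*D) ]

is fitted with the standard segmented strategy: true diffusion D from the
high-b regime (b > 200 s/mm^2 by default, between b = 140 and 230 in the
13-b acquisition grid), perfusion fraction f and pseudodiffusion D* from the
residual fast component, then an optional joint bounded polish.  Diffusion
coefficients are in mm^2/s; b-values in s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_BVALUES",
    "DWISeries",
    "IVIMParams",
    "ADCResult",
    "ivim_forward",
    "fit_adc",
    "fit_ivim_segmented",
    "trace_average",
]

#: Acquisition b-values in s/mm^2 (13-value renal protocol).
DEFAULT_BVALUES = (20, 30, 40, 50, 60, 80, 140, 230, 350, 570, 840, 1120, 1460)

_D_BOUNDS = (1e-5, 1e-2)
_DSTAR_UPPER = 1.0


@dataclass(frozen=True)
class DWISeries:
    """One multi-b-value DWI signal series (ROI-averaged or single voxel)."""

    bvalues: np.ndarray
    signals: np.ndarray
    trace_averaged: bool = True

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "signals", s)
        if b.ndim != 1 or s.shape != b.shape:
            raise ValueError("bvalues and signals must be 1-D and equal length")
        if np.any(np.diff(b) <= 0) or np.any(b < 0):
            raise ValueError("bvalues must be nonnegative and strictly increasing")
        if np.any(s <= 0):
            raise ValueError("signals must be positive")


@dataclass(frozen=True)
class IVIMParams:
    """IVIM parameters; ``warning`` flags identifiability problems."""

    D: float        # mm^2/s
    Dstar: float    # mm^2/s
    f: float        # perfusion fraction
    S0: float       # signal at b = 0
    warning: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f must be in [0, 1]")
        if self.D <= 0 or self.Dstar <= 0:
            raise ValueError("D and D* must be positive")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")


@dataclass(frozen=True)
class ADCResult:
    ADC: float  # mm^2/s
    S0: float

    def __post_init__(self) -> None:
        if self.ADC < 0:
            raise ValueError("ADC must be >= 0")


def ivim_forward(p: IVIMParams, bvalues: np.ndarray) -> np.ndarray:
    """Bi-exponential IVIM signal S(b)."""
    b = np.asarray(bvalues, dtype=float)
    return p.S0 * (p.f * np.exp(-b * p.Dstar) + (1.0 - p.f) * np.exp(-b * p.D))


def trace_average(signals_per_direction: np.ndarray, axis: int = 0) -> np.ndarray:
    """Geometric-mean average of orthogonal diffusion directions into a trace."""
    s = np.asarray(signals_per_direction, dtype=float)
    if np.any(s <= 0):
        raise ValueError("signals must be positive")
    return np.exp(np.mean(np.log(s), axis=axis))


def fit_adc(series: DWISeries) -> ADCResult:
    """Log-linear mono-exponential fit over all b-values; ADC = -slope."""
    b, s = series.bvalues, series.signals
    if b.size < 2:
        raise ValueError("need at least 2 b-values")
    slope, intercept = np.polyfit(b, np.log(s), 1)
    return ADCResult(ADC=max(0.0, -float(slope)), S0=float(np.exp(intercept)))


def fit_ivim_segmented(
    series: DWISeries,
    b_threshold: float = 200.0,
    polish: bool = True,
) -> IVIMParams:
    """Segmented IVIM fit: high-b mono-exponential, then fast component.

    Step 1 fits ln S on b for b > ``b_threshold`` giving D and the
    extrapolated slow-pool intercept P = S0 (1 - f).  Step 2 fits the fast
    component amplitude Q = S0 f and D* on all b-values with (D, P) fixed,
    so f = Q/(P + Q) and S0 = P + Q.  Step 3 optionally polishes all four
    parameters jointly under bounds f in [0, 1], D in [1e-5, 1e-2] mm^2/s,
    D* in [D, 1] mm^2/s.

    A fit where f collapses to a bound or D* is indistinguishable from D is
    returned with a ``warning`` flag set.
    """
    b, s = series.bvalues, series.signals
    hi = b > b_threshold
    lo = ~hi
    if hi.sum() < 3 or lo.sum() < 3:
        raise ValueError("need >= 3 b-values on each side of b_threshold")

    slope, intercept = np.polyfit(b[hi], np.log(s[hi]), 1)
    d_hat = float(np.clip(-slope, *_D_BOUNDS))
    p_amp = float(np.exp(intercept))  # S0 (1 - f)

    slow = p_amp * np.exp(-b * d_hat)
    fast0 = max(float(np.mean(s[lo] - slow[lo])), 1e-6 * p_amp)

    def resid_fast(theta: np.ndarray) -> np.ndarray:
        q_amp, dstar = theta
        return slow + q_amp * np.exp(-b * dstar) - s

    res = least_squares(
        resid_fast, x0=[fast0, 10.0 * d_hat],
        bounds=([0.0, d_hat], [np.inf, _DSTAR_UPPER]), method="trf",
    )
    q_amp, dstar_hat = res.x
    s0_hat = p_amp + q_amp
    f_hat = float(q_amp / s0_hat) if s0_hat > 0 else 0.0

    if polish:
        def resid_joint(theta: np.ndarray) -> np.ndarray:
            s0, f, d, dstar = theta
            return s0 * (f * np.exp(-b * dstar) + (1 - f) * np.exp(-b * d)) - s

        x0 = np.array([s0_hat, np.clip(f_hat, 1e-6, 1 - 1e-6),
                       d_hat, max(dstar_hat, d_hat * (1 + 1e-6))])
        lo_b = [1e-12, 0.0, _D_BOUNDS[0], _D_BOUNDS[0]]
        hi_b = [np.inf, 1.0, _D_BOUNDS[1], _DSTAR_UPPER]
        res = least_squares(resid_joint, np.clip(x0, lo_b, hi_b),
                            bounds=(lo_b, hi_b), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        s0_hat, f_hat, d_hat, dstar_hat = (float(v) for v in res.x)

    warning = None
    if f_hat <= 1e-6 or f_hat >= 1 - 1e-6:
        warning = "f at bound"
    elif dstar_hat <= d_hat * (1 + 1e-3):
        warning = "Dstar ~= D: perfusion fraction unidentifiable"
    return IVIMParams(D=d_hat, Dstar=max(dstar_hat, d_hat * (1 + 1e-9)),
                      f=float(np.clip(f_hat, 0.0, 1.0)), S0=s0_hat,
                      warning=warning)
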