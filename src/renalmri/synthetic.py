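"""Seeded synthetic-data generators for every pipeline input.

Since no raw animal data accompany the study design this package implements,
every analysis stage is exercised against seeded phantoms: a gamma-variate
arterial input function, DCE phantoms whose sub-regions are generated by the
three PK forward models and converted to SPGR magnitude signal with Rician
noise, FAIR inversion-recovery series pairs, 13-b-value IVIM signals, and a
9-animal x 3-timepoint x 2-kidney cohort whose group means/SDs follow the
published group statistics of the unilateral-IRI experiment (SD reconstructed
from SEM with n = 9).  Every generator is a pure function of its spec and
seed, and every generated dataset is returned together with its ground truth
so recovery error can be measured at any downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .diffusion import DEFAULT_BVALUES, DWISeries, IVIMParams, ivim_forward
from .relaxometry import DEFAULT_TI_MS, IRSeries, T1Result, ir_forward
from .tracer_kinetics import (
    AcquisitionParams,
    ConcentrationCurve,
    PatlakParams,
    TCFMOParams,
    TCFMParams,
    TimeGrid,
    blood_to_plasma,
    patlak_forward,
    spgr_signal,
    tcfm_forward,
    tcfmo_forward,
)

__all__ = [
    "AIFSpec",
    "RegionSpec",
    "PhantomSpec",
    "CohortSpec",
    "TABLE_GROUP_STATS",
    "make_aif",
    "make_dce_phantom",
    "standard_phantom_spec",
    "make_ir_series",
    "make_dwi_series",
    "make_cohort",
]


# ---------------------------------------------------------------------------
# Arterial input function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AIFSpec:
    """Gamma-variate AIF with a slow washout tail.

    Cp(t) = A ((t-t0)/tau)^k exp(-(t-t0)/tau)
            + A*tail_fraction (1 - exp(-(t-t0)/(k tau))) exp(-washout (t-t0))

    for t >= onset t0, zero before.  The gamma-variate mode (peak) sits at
    t0 + k*tau.  Defaults describe a compact first pass (~9 s to peak) of a
    small-animal gadolinium bolus peaking in the low-mM range in plasma.
    """

    amplitude: float = 5.0       # mM at the gamma-variate peak scale
    shape: float = 3.0           # k, dimensionless
    timescale: float = 0.05      # tau, minutes
    onset: float = 2.0           # t0, minutes (end of the baseline window)
    washout_rate: float = 0.1    # 1/min
    tail_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.shape <= 0 or self.timescale <= 0:
            raise ValueError("invalid gamma-variate parameters")
        if self.washout_rate < 0 or self.tail_fraction < 0:
            raise ValueError("washout parameters must be >= 0")


def make_aif(grid: TimeGrid, spec: AIFSpec = AIFSpec()) -> ConcentrationCurve:
    """Evaluate the gamma-variate + washout-tail AIF on ``grid``."""
    t = grid.times
    u = t - spec.onset
    cp = np.zeros_like(t)
    post = u > 0
    up = u[post]
    gamma = spec.amplitude * (up / (spec.shape * spec.timescale)) ** spec.shape \
        * np.exp(spec.shape - up / spec.timescale)
    # normalized so the gamma part peaks at exactly `amplitude` at u = k*tau
    tail = spec.amplitude * spec.tail_fraction \
        * (1.0 - np.exp(-up / (spec.shape * spec.timescale))) \
        * np.exp(-spec.washout_rate * up)
    cp[post] = gamma + tail
    return ConcentrationCurve(grid=grid, values=cp, role="plasma")


# ---------------------------------------------------------------------------
# DCE phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """One phantom sub-region: its mask, generating model and true params."""

    mask: np.ndarray
    model_id: str
    params: object  # PatlakParams | TCFMParams | TCFMOParams


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int] = (12, 12)
    spacing: tuple[float, float] = (40.0 / 192.0, 20.0 / 96.0)  # mm, DCE matrix
    regions: tuple[RegionSpec, ...] = ()
    aif: AIFSpec = AIFSpec()
    duration_min: float = 6.0
    noise: str = "rician"  # or 'gaussian'
    snr: float = 20.0      # baseline signal / noise SD
    seed: int = 0
    baseline_signal: float = 1000.0
    c3_delay_min: float = 0.3
    c3_smooth_frames: float = 5.0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if self.noise not in ("rician", "gaussian"):
            raise ValueError("noise must be 'rician' or 'gaussian'")
        total = np.zeros(self.shape, dtype=int)
        for r in self.regions:
            if r.mask.shape != self.shape:
                raise ValueError("region mask shape must match phantom shape")
            total += r.mask.astype(int)
        if np.any(total > 1):
            raise ValueError("phantom regions must be disjoint")


def standard_phantom_spec(snr: float = 20.0, seed: int = 0,
                          shape: tuple[int, int] = (12, 12)) -> PhantomSpec:
    """The standard three-region phantom: one stripe per generating model.

    True parameters sit near healthy-kidney values (F_T ~ 0.6 1/min) and are
    deliberately different from the fitting start values.
    """
    h, w = shape
    third = h // 3
    m1 = np.zeros(shape, bool); m1[:third] = True
    m2 = np.zeros(shape, bool); m2[third:2 * third] = True
    m3 = np.zeros(shape, bool); m3[2 * third:] = True
    regions = (
        RegionSpec(m1, "patlak", PatlakParams(Vp=0.15, FT=0.6)),
        RegionSpec(m2, "2cfm", TCFMParams(Vp=0.15, FT=0.6, TT=0.8)),
        RegionSpec(m3, "2cfmo", TCFMOParams(k1=2.5, FT=0.6, k2=0.15)),
    )
    return PhantomSpec(shape=shape, regions=regions, snr=snr, seed=seed)


def _region_curve(region: RegionSpec, cp: ConcentrationCurve,
                  c3: ConcentrationCurve | None) -> np.ndarray:
    if region.model_id == "patlak":
        return patlak_forward(region.params, cp).values
    if region.model_id == "2cfm":
        return tcfm_forward(region.params, cp).values
    if region.model_id == "2cfmo":
        return tcfmo_forward(region.params, cp, c3).values
    raise ValueError(f"unknown model {region.model_id!r}")


def _add_noise(signal: np.ndarray, sigma: float, kind: str,
               rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return signal
    n1 = rng.normal(0.0, sigma, signal.shape)
    if kind == "gaussian":
        return signal + n1
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def make_dce_phantom(spec: PhantomSpec,
                     acq: AcquisitionParams = AcquisitionParams()) -> dict:
    """Generate a 2-D + time DCE phantom in SPGR magnitude-signal space.

    Per region: forward PK model -> concentration -> SPGR signal scaled to a
    common baseline -> Rician (or Gaussian) noise at SNR = baseline/sigma.
    The shared C3 curve is a delayed, smoothed copy of the mean tissue
    concentration of the non-outflow regions, mimicking an inner-medullary-
    papilla ROI average.  Returns signal, grid, plasma AIF, C3, acquisition
    constants and a truth dict with per-voxel parameter maps.
    """
    if not spec.regions:
        raise ValueError("phantom needs at least one region")
    rng = np.random.default_rng(spec.seed)
    grid = TimeGrid.from_duration(spec.duration_min)
    aif = make_aif(grid, spec.aif)

    # C3 from the mean of the non-2cfmo region curves, delayed and smoothed
    base_curves = [
        _region_curve(r, aif, None) for r in spec.regions if r.model_id != "2cfmo"
    ]
    ref = np.mean(base_curves, axis=0) if base_curves else aif.values
    shift = int(round(spec.c3_delay_min / grid.dt))
    delayed = np.concatenate([np.zeros(shift), ref[: len(ref) - shift]])
    c3_vals = gaussian_filter1d(delayed, sigma=spec.c3_smooth_frames)
    c3 = ConcentrationCurve(grid=grid, values=c3_vals, role="imp")

    n_t = len(grid)
    conc = np.zeros(spec.shape + (n_t,))
    truth_ft = np.full(spec.shape, np.nan)
    truth_model = np.zeros(spec.shape, dtype="U8")
    truth_params: dict[str, object] = {}
    for r in spec.regions:
        curve = _region_curve(r, aif, c3)
        conc[r.mask] = curve
        truth_ft[r.mask] = r.params.FT
        truth_model[r.mask] = r.model_id
        truth_params[r.model_id] = r.params

    mask = np.zeros(spec.shape, bool)
    for r in spec.regions:
        mask |= r.mask

    scale = spec.baseline_signal / spgr_signal(0.0, acq)
    signal = spgr_signal(conc, acq, scale=scale)
    sigma = spec.baseline_signal / spec.snr
    signal = _add_noise(signal, sigma, spec.noise, rng)
    signal = np.clip(signal, 1e-6, None)

    return {
        "signal": signal,
        "grid": grid,
        "aif": aif,
        "c3": c3,
        "mask": mask,
        "acq": acq,
        "spacing": spec.spacing,
        "truth": {
            "ft_map": truth_ft,
            "model_map": truth_model,
            "params": truth_params,
            "concentration": conc,
        },
    }


# ---------------------------------------------------------------------------
# IR and DWI series
# ---------------------------------------------------------------------------

def make_ir_series(
    t1_selective: float,
    t1_global: float,
    snr: float = np.inf,
    seed: int = 0,
    s0: float = 1000.0,
    inv_eff: float = 1.95,
    inversion_times: tuple[float, ...] = DEFAULT_TI_MS,
) -> dict:
    """Generate a FAIR selective/global magnitude IR series pair.

    Gaussian noise with SD = s0/snr is added to each magnitude series
    (``snr=inf`` for noiseless).  T1 in ms.
    """
    if t1_selective <= 0 or t1_global <= 0:
        raise ValueError("T1 values must be positive")
    rng = np.random.default_rng(seed)
    ti = np.asarray(inversion_times, dtype=float)
    out = {}
    for name, t1 in (("selective", t1_selective), ("global", t1_global)):
        clean = ir_forward(T1Result(T1=t1, S0=s0, inv_eff=inv_eff), ti)
        if np.isfinite(snr):
            clean = np.abs(clean + rng.normal(0.0, s0 / snr, clean.shape))
        out[name] = IRSeries(inversion_times=ti, signals=clean, labeling=name)
    out["truth"] = {"t1_selective": t1_selective, "t1_global": t1_global,
                    "s0": s0, "inv_eff": inv_eff}
    return out


def make_dwi_series(
    params: IVIMParams,
    snr: float = np.inf,
    seed: int = 0,
    bvalues: tuple[float, ...] = DEFAULT_BVALUES,
    n_directions: int = 3,
    roi_voxels: int = 30,
    noise: str = "gaussian",
) -> dict:
    """Generate an ROI-averaged trace DWI series at a per-image SNR.

    The fitting layer consumes ROI-averaged trace signals (geometric mean of
    three orthogonal directions, then mean over a renal-cortex ROI), so the
    generator emulates that chain: ``snr`` is the single-image SNR and the
    averaged series carries noise reduced by sqrt(n_directions * roi_voxels).
    ``noise='gaussian'`` (the default for ROI-averaged series) adds the
    reduced-variance Gaussian directly; ``noise='rician'`` simulates every
    per-voxel per-direction magnitude image and averages, retaining the
    Rician noise floor.  ``roi_voxels=1, n_directions=1`` recovers a raw
    single-voxel series.
    """
    rng = np.random.default_rng(seed)
    b = np.asarray(bvalues, dtype=float)
    clean = ivim_forward(params, b)
    if np.isfinite(snr):
        sigma = params.S0 / snr
        if noise == "gaussian":
            eff = sigma / np.sqrt(n_directions * roi_voxels)
            clean = clean + rng.normal(0.0, eff, clean.shape)
        elif noise == "rician":
            mags = _add_noise(
                np.broadcast_to(clean, (roi_voxels, n_directions, b.size)).copy(),
                sigma, "rician", rng)
            trace = np.exp(np.mean(np.log(np.clip(mags, 1e-12, None)), axis=1))
            clean = trace.mean(axis=0)
        else:
            raise ValueError("noise must be 'gaussian' or 'rician'")
    return {"series": DWISeries(bvalues=b, signals=np.clip(clean, 1e-9, None)),
            "truth": params}


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

# Group means +/- SEM per (timepoint, side): right kidney is the clamped
# (injured) one at day1/day15.  Units: Volume mm^3, RBF ml/min/100g,
# ADC/D/Dstar mm^2/s, f unitless, FT 1/min.
TABLE_GROUP_STATS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("baseline", "right"): {
        "Volume": (202.46, 4.24), "RBF": (322.02, 23.37),
        "ADC": (0.0026, 0.00015), "D": (0.0017, 0.00018),
        "Dstar": (0.047, 0.019), "f": (0.29, 0.045), "FT": (0.67, 0.068),
    },
    ("baseline", "left"): {
        "Volume": (202.19, 4.36), "RBF": (333.92, 25.81),
        "ADC": (0.0021, 0.0002), "D": (0.0016, 0.00016),
        "Dstar": (0.049, 0.02), "f": (0.30, 0.04), "FT": (0.59, 0.059),
    },
    ("day1", "right"): {
        "Volume": (180.97, 3.08), "RBF": (236.25, 23.84),
        "ADC": (0.0016, 0.00015), "D": (0.0015, 0.00014),
        "Dstar": (0.045, 0.0045), "f": (0.27, 0.037), "FT": (0.44, 0.02),
    },
    ("day1", "left"): {
        "Volume": (205.18, 3.96), "RBF": (395.92, 16.76),
        "ADC": (0.0022, 0.00015), "D": (0.0017, 0.00015),
        "Dstar": (0.068, 0.0069), "f": (0.26, 0.044), "FT": (0.72, 0.09),
    },
    ("day15", "right"): {
        "Volume": (163.51, 3.74), "RBF": (271.10, 37.18),
        "ADC": (0.0019, 0.00017), "D": (0.0013, 0.00015),
        "Dstar": (0.033, 0.01), "f": (0.34, 0.047), "FT": (0.55, 0.05),
    },
    ("day15", "left"): {
        "Volume": (217.00, 4.47), "RBF": (354.01, 31.77),
        "ADC": (0.0021, 0.00015), "D": (0.0013, 0.00017),
        "Dstar": (0.051, 0.015), "f": (0.25, 0.03), "FT": (0.60, 0.05),
    },
}

_COHORT_N_REPORTED = 9  # animals behind the published SEMs


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generator configuration.

    Group SDs default to SEM * sqrt(9) from the published group statistics.
    ``tgfr_bias`` and ``tgfr_sd`` control the paired transcutaneous-GFR
    readings: T-GFR = MRI-GFR + bias + N(0, sd); the defaults reproduce the
    published agreement (bias 40.08 ul/min, LoA [-24.70, 104.85] ul/min).
    """

    n_animals: int = 9
    group_stats: dict = field(default_factory=lambda: TABLE_GROUP_STATS)
    sem_to_sd: float = float(np.sqrt(_COHORT_N_REPORTED))
    tgfr_bias: float = 40.08        # ul/min
    tgfr_sd: float = 33.05          # ul/min, (104.85 - 40.08)/1.96
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("need at least 2 animals")
        if self.tgfr_sd < 0:
            raise ValueError("tgfr_sd must be >= 0")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal draws truncated at zero (redraw; means here are many SDs > 0)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, 1e-12, None)


def make_cohort(spec: CohortSpec = CohortSpec()) -> dict:
    """Draw a tidy per-kidney cohort plus paired transcutaneous-GFR readings.

    Per (animal, timepoint, side), each parameter is drawn independently from
    a zero-truncated normal with the configured group mean and SD.  GFR is
    not drawn: it is the per-animal product FT x Volume, so the unit identity
    holds by construction.  T-GFR = MRI-GFR + bias + N(0, sd).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    tgfr_rows = []
    animals = [f"m{i + 1:02d}" for i in range(spec.n_animals)]
    truth = {"group_stats": spec.group_stats, "tgfr_bias": spec.tgfr_bias,
             "tgfr_sd": spec.tgfr_sd}
    for (timepoint, side), params in spec.group_stats.items():
        drawn = {
            name: _truncated_normal(rng, mean, sem * spec.sem_to_sd,
                                    spec.n_animals)
            for name, (mean, sem) in params.items()
        }
        gfr = drawn["FT"] * drawn["Volume"]
        for i, animal in enumerate(animals):
            for name, vals in drawn.items():
                rows.append({"animal_id": animal, "timepoint": timepoint,
                             "side": side, "parameter": name,
                             "value": float(vals[i])})
            rows.append({"animal_id": animal, "timepoint": timepoint,
                         "side": side, "parameter": "GFR",
                         "value": float(gfr[i])})
        noise = rng.normal(0.0, spec.tgfr_sd, spec.n_animals)
        for i, animal in enumerate(animals):
            tgfr_rows.append({
                "animal_id": animal, "timepoint": timepoint, "side": side,
                "mri_gfr": float(gfr[i]),
                "tgfr": float(gfr[i] + spec.tgfr_bias + noise[i]),
            })
    cohort = pd.DataFrame(rows)
    tgfr = pd.DataFrame(tgfr_rows)
    return {"cohort": cohort, "tgfr": tgfr, "truth": truth}
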