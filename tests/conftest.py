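"""Shared fixtures: time grids, AIFs, and the fitted standard phantom."""

from __future__ import annotations

import numpy as np
import pytest

from renalmri.pk_fitting import fit_roi
from renalmri.synthetic import make_aif, make_dce_phantom, standard_phantom_spec
from renalmri.tracer_kinetics import TimeGrid, concentration_from_signal


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid.from_duration(6.0)


@pytest.fixture(scope="session")
def aif(grid):
    return make_aif(grid)


@pytest.fixture(scope="session")
def imp_curve(aif):
    """A plausible inner-medullary-papilla curve: delayed, smoothed tissue mean."""
    from scipy.ndimage import gaussian_filter1d

    from renalmri import PatlakParams, patlak_forward

    base = patlak_forward(PatlakParams(Vp=0.15, FT=0.6), aif).values
    shift = 18
    delayed = np.concatenate([np.zeros(shift), base[:-shift]])
    return aif.with_values(gaussian_filter1d(delayed, 5.0), role="imp")


def _convert_phantom(phantom):
    conc = np.zeros_like(phantom["signal"])
    for idx in np.argwhere(phantom["mask"]):
        curve, _ = concentration_from_signal(
            phantom["signal"][tuple(idx)], phantom["acq"], phantom["grid"]
        )
        conc[tuple(idx)] = curve.values
    return conc


@pytest.fixture(scope="session")
def phantom_snr20():
    """The standard three-region phantom at SNR 20, fixed seed."""
    return make_dce_phantom(standard_phantom_spec(snr=20.0, seed=0))


@pytest.fixture(scope="session")
def phantom_snr20_fit(phantom_snr20):
    """Voxel-wise three-model fit + parsimonious selection of the phantom."""
    ph = phantom_snr20
    conc = _convert_phantom(ph)
    result = fit_roi(conc, ph["mask"], ph["aif"], c3=ph["c3"], grid=ph["grid"])
    return ph, result
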