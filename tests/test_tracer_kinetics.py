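"""Forward-model oracles: closed-form solutions for the PK models."""

import numpy as np
import pytest

from renalmri.tracer_kinetics import (
    AcquisitionParams,
    ConcentrationCurve,
    GridError,
    PatlakParams,
    TCFMOParams,
    TCFMParams,
    TimeGrid,
    blood_to_plasma,
    concentration_from_signal,
    exp_convolve,
    extrapolate_te0,
    patlak_forward,
    spgr_signal,
    tcfm_forward,
    tcfmo_forward,
)


@pytest.fixture(scope="module")
def fine_grid():
    return TimeGrid.from_duration(10.0, dt_min=1.0 / 60.0)


def const_curve(grid, value=1.0, role="plasma"):
    return ConcentrationCurve(grid=grid, values=np.full(len(grid), value), role=role)


class TestTimeGrid:
    def test_default_spacing_is_sub_second(self):
        g = TimeGrid.from_duration(6.0)
        assert g.dt == pytest.approx(0.987 / 60.0)
        assert g.times[0] == 0.0
        assert g.n_baseline >= 1

    @pytest.mark.parametrize(
        "times,n_baseline",
        [
            ([0.0, 1.0, 2.5], 1),       # non-uniform
            ([1.0, 2.0, 3.0], 1),       # does not start at zero
            ([0.0, 1.0, 2.0], 0),       # no baseline frames
            ([0.0, 1.0, 2.0], 3),       # baseline covers everything
            ([0.0, 1.0, 1.0], 1),       # not strictly increasing
        ],
    )
    def test_invalid_grids_rejected(self, times, n_baseline):
        with pytest.raises(GridError):
            TimeGrid(times=np.array(times), n_baseline=n_baseline)


class TestExpConvolve:
    def test_zero_input_gives_zero(self, fine_grid):
        out = exp_convolve(const_curve(fine_grid, 0.0), rate=1.0)
        assert np.all(out.values == 0.0)

    def test_constant_input_closed_form(self, fine_grid):
        # integral_0^t e^{-(t-s)} ds = 1 - e^{-t}
        out = exp_convolve(const_curve(fine_grid), rate=1.0)
        t = fine_grid.times
        assert np.allclose(out.values, 1.0 - np.exp(-t), rtol=1e-9, atol=1e-12)
        i2 = np.argmin(np.abs(t - 2.0))
        assert out.values[i2] == pytest.approx(0.864665, abs=1e-6)

    def test_rate_zero_is_running_integral(self, fine_grid):
        out = exp_convolve(const_curve(fine_grid), rate=0.0)
        assert np.allclose(out.values, fine_grid.times, rtol=1e-9, atol=1e-12)

    def test_exponential_input_within_tenth_percent(self, fine_grid):
        # (e^{-2t} * e^{-t})(t) = e^{-t} - e^{-2t}
        t = fine_grid.times
        cp = ConcentrationCurve(grid=fine_grid, values=np.exp(-t), role="plasma")
        out = exp_convolve(cp, rate=2.0)
        exact = np.exp(-t) - np.exp(-2.0 * t)
        assert np.max(np.abs(out.values - exact)) < 1e-3 * exact.max()

    def test_negative_rate_rejected(self, fine_grid):
        with pytest.raises(ValueError):
            exp_convolve(const_curve(fine_grid), rate=-1.0)


class TestPatlak:
    def test_null_model(self, fine_grid):
        out = patlak_forward(PatlakParams(0.0, 0.0), const_curve(fine_grid))
        assert np.all(out.values == 0.0)

    def test_constant_input(self, fine_grid):
        out = patlak_forward(PatlakParams(0.1, 0.5), const_curve(fine_grid))
        i2 = np.argmin(np.abs(fine_grid.times - 2.0))
        assert out.values[i2] == pytest.approx(1.1, rel=1e-9)

    def test_exponential_input_closed_form(self, fine_grid):
        t = fine_grid.times
        cp = ConcentrationCurve(grid=fine_grid, values=np.exp(-t), role="plasma")
        out = patlak_forward(PatlakParams(0.2, 0.5), cp)
        exact = 0.2 * np.exp(-t) + 0.5 * (1.0 - np.exp(-t))
        assert np.max(np.abs(out.values - exact)) < 1e-3 * 0.5
        assert exact[-1] == pytest.approx(0.5, abs=1e-4)  # t -> inf limit

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            PatlakParams(Vp=-0.1, FT=0.5)
        with pytest.raises(ValueError):
            PatlakParams(Vp=0.1, FT=-0.5)


class TestTCFM:
    def test_constant_input_closed_form(self, fine_grid):
        out = tcfm_forward(TCFMParams(0.1, 0.5, 1.0), const_curve(fine_grid))
        t = fine_grid.times
        exact = 0.1 + 0.5 * (1.0 - np.exp(-t))
        assert np.allclose(out.values, exact, rtol=1e-9, atol=1e-12)
        assert exact[-1] == pytest.approx(0.6, abs=1e-4)  # plateau Vp + FT*TT

    def test_large_tt_reduces_to_patlak(self, aif):
        pat = patlak_forward(PatlakParams(0.1, 0.5), aif)
        tc = tcfm_forward(TCFMParams(0.1, 0.5, 1e6), aif)
        assert np.max(np.abs(tc.values - pat.values)) < 1e-3 * np.max(np.abs(pat.values))

    def test_ft_zero_is_vascular_only(self, aif):
        out = tcfm_forward(TCFMParams(0.25, 0.0, 1.0), aif)
        assert np.allclose(out.values, 0.25 * aif.values, rtol=1e-12)

    def test_nonpositive_tt_rejected(self):
        with pytest.raises(ValueError):
            TCFMParams(0.1, 0.5, 0.0)


class TestTCFMO:
    def test_closed_form_constant_inputs(self, fine_grid):
        # k1=1, FT=0.5, k2=0, C0=1, C3=0: C1 = 1-e^-t, C2 = 0.5(t-1+e^-t)
        c0 = const_curve(fine_grid)
        c3 = const_curve(fine_grid, 0.0, role="imp")
        out = tcfmo_forward(TCFMOParams(k1=1.0, FT=0.5, k2=0.0), c0, c3)
        t = fine_grid.times
        exact = (1 - np.exp(-t)) + 0.5 * (t - 1 + np.exp(-t))
        assert np.max(np.abs(out.values - exact)) < 1e-6 * max(exact.max(), 1.0)
        i2 = np.argmin(np.abs(t - 2.0))
        assert out.values[i2] == pytest.approx(1.432332, abs=1e-5)

    def test_fast_exchange_limit(self, fine_grid):
        c0 = const_curve(fine_grid)
        c3 = const_curve(fine_grid, 0.0, role="imp")
        out = tcfmo_forward(TCFMOParams(k1=1e5, FT=0.5, k2=0.0), c0, c3)
        t = fine_grid.times
        assert np.allclose(out.values[10:], 1.0 + 0.5 * t[10:], rtol=1e-3)

    def test_bounded_relaxation(self, aif):
        c3 = aif.with_values(np.zeros(len(aif.grid)), role="imp")
        out = tcfmo_forward(TCFMOParams(k1=2.0, FT=0.0, k2=0.0), aif, c3)
        assert np.all(out.values <= aif.values.max() + 1e-12)
        assert np.all(out.values >= -1e-12)

    def test_grid_mismatch_rejected(self, fine_grid):
        other = TimeGrid.from_duration(5.0, dt_min=1.0 / 60.0)
        c0 = const_curve(fine_grid)
        c3 = const_curve(other, 0.0, role="imp")
        with pytest.raises(GridError):
            tcfmo_forward(TCFMOParams(1.0, 0.5, 0.1), c0, c3)


class TestForwardNonnegativity:
    @pytest.mark.parametrize("ft,vp", [(0.0, 0.0), (0.5, 0.1), (2.0, 1.0)])
    def test_nonnegative_output_for_nonnegative_input(self, aif, imp_curve, ft, vp):
        assert np.all(patlak_forward(PatlakParams(vp, ft), aif).values >= -1e-12)
        assert np.all(tcfm_forward(TCFMParams(vp, ft, 0.5), aif).values >= -1e-12)
        out = tcfmo_forward(TCFMOParams(k1=1.0, FT=ft, k2=0.0), aif, imp_curve)
        assert np.all(out.values >= -1e-12)


class TestSignalConversion:
    def test_te0_no_decay(self):
        assert extrapolate_te0(100.0, 100.0, AcquisitionParams()) == pytest.approx(100.0)

    def test_te0_formula(self):
        out = extrapolate_te0(100.0, 50.0, AcquisitionParams())
        assert out == pytest.approx(116.46, abs=0.01)

    def test_te0_round_trip(self):
        acq = AcquisitionParams()
        rng = np.random.default_rng(0)
        for _ in range(20):
            s0 = rng.uniform(50, 5000)
            r2s = rng.uniform(0.0, 0.3)  # 1/ms
            s1 = s0 * np.exp(-acq.TE1 * r2s)
            s2 = s0 * np.exp(-acq.TE2 * r2s)
            assert extrapolate_te0(s1, s2, acq) == pytest.approx(s0, rel=1e-10)

    def test_te0_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_te0(0.0, 50.0, AcquisitionParams())

    def test_spgr_round_trip_identity(self):
        acq = AcquisitionParams()
        grid = TimeGrid.from_duration(2.0, dt_min=1.0 / 60.0, baseline_min=0.5)
        for c_true in [0.0, 0.1, 0.5, 1.0, 2.5, 5.0]:
            conc = np.zeros(len(grid))
            conc[grid.n_baseline:] = c_true
            sig = spgr_signal(conc, acq, scale=700.0)
            curve, info = concentration_from_signal(sig, acq, grid)
            assert np.max(np.abs(curve.values - conc)) < 1e-6
            assert info["n_clamped"] == 0

    def test_no_enhancement_gives_zero(self):
        acq = AcquisitionParams()
        grid = TimeGrid.from_duration(2.0, dt_min=1.0 / 60.0, baseline_min=0.5)
        curve, _ = concentration_from_signal(np.full(len(grid), 400.0), acq, grid)
        assert np.all(curve.values == 0.0)

    def test_out_of_range_marked_missing(self):
        acq = AcquisitionParams()
        grid = TimeGrid.from_duration(1.0, dt_min=1.0 / 60.0, baseline_min=0.25)
        sig = np.full(len(grid), 100.0)
        sig[-1] = 1e4  # unreachable ratio for any finite R1
        curve, info = concentration_from_signal(sig, acq, grid)
        assert info["missing"][-1]
        assert not info["missing"][:-1].any()

    def test_plasma_scaling(self, aif):
        cp = blood_to_plasma(aif, hematocrit=0.45)
        assert np.allclose(cp.values, aif.values / 0.55, rtol=1e-12)
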