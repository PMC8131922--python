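"""Resampling, smoothing, boundary finding and feature quantification."""
import math

import numpy as np
import pytest

import mbrquant as mq
from mbrquant.tracing import (
    Chromatogram,
    DegenerateInputError,
    TraceParams,
    find_boundaries,
    quantify_feature,
    resample,
    smooth,
)
from tests.conftest import build_peak_map


class TestResample:
    def test_linear_interpolation(self):
        c = resample([0.0, 1.0, 2.0], [0.0, 10.0, 0.0], interval=0.5)
        np.testing.assert_allclose(c.intensities, [0, 5, 10, 5, 0])
        np.testing.assert_allclose(np.diff(c.times), 0.5)

    def test_uniform_input_is_identity(self):
        t = np.arange(0, 2.01, 0.25)
        y = np.sin(t)
        c = resample(t, y, interval=0.25)
        np.testing.assert_allclose(c.intensities, y, atol=1e-12)

    def test_single_point_errors(self):
        with pytest.raises(DegenerateInputError):
            resample([1.0], [5.0])

    def test_duplicate_times_summed(self):
        c = resample([0.0, 1.0, 1.0, 2.0], [0.0, 4.0, 6.0, 0.0], interval=1.0)
        np.testing.assert_allclose(c.intensities, [0, 10, 0])

    def test_default_interval_is_median_spacing(self):
        c = resample([0.0, 0.1, 0.2, 0.4], [1, 1, 1, 1.0])
        assert c.resample_interval == pytest.approx(0.1)


class TestSmooth:
    def test_reproduces_cubic(self):
        t = np.arange(0, 2, 0.05)
        y = 2 * t ** 3 - t ** 2 + 3
        c = Chromatogram(t, y.copy(), 0.05)
        out = smooth(c, window=7, polyorder=3)
        np.testing.assert_allclose(out.intensities, y, rtol=1e-9, atol=1e-9)

    def test_constant_unchanged(self):
        c = Chromatogram(np.arange(10.0), np.full(10, 7.0), 1.0)
        np.testing.assert_allclose(smooth(c).intensities, 7.0)

    def test_impulse_matches_local_quadratic_fit(self):
        # independent oracle: least-squares quadratic over the 5-point window
        y = np.array([0.0, 0.0, 10.0, 0.0, 0.0, 0.0, 0.0])
        c = Chromatogram(np.arange(7.0), y, 1.0)
        out = smooth(c, window=5, polyorder=2)
        x = np.arange(5.0)
        coef = np.polyfit(x, y[:5], 2)
        expected_center = np.polyval(coef, 2.0)
        assert out.intensities[2] == pytest.approx(expected_center, abs=1e-9)

    def test_matches_scipy_reference(self):
        from scipy.signal import savgol_filter

        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        c = Chromatogram(np.arange(40.0), y.copy(), 1.0)
        out = smooth(c, window=9, polyorder=3)
        np.testing.assert_allclose(
            out.intensities, savgol_filter(y, 9, 3, mode="interp"), atol=1e-10)

    def test_window_too_long_falls_back(self, caplog):
        c = Chromatogram(np.arange(5.0), np.arange(5.0), 1.0)
        with caplog.at_level("WARNING"):
            out = smooth(c, window=7, polyorder=2)
        np.testing.assert_array_equal(out.intensities, c.intensities)
        assert any("skipping" in r.message for r in caplog.records)


class TestFindBoundaries:
    def test_triangular_peak(self):
        t = np.arange(0.0, 4.01, 0.5)
        y = np.maximum(0, 10 - 10 * np.abs(t - 2.0))
        c = Chromatogram(t, y, 0.5)
        start, apex, end = find_boundaries(c, apex_hint=2.0)
        assert (start, apex, end) == (1.0, 2.0, 3.0)

    def test_locality_near_hint(self):
        t = np.arange(0.0, 10.01, 0.25)
        y = 10 * np.exp(-0.5 * ((t - 2) / 0.3) ** 2) \
            + 8 * np.exp(-0.5 * ((t - 7) / 0.3) ** 2)
        c = Chromatogram(t, y, 0.25)
        start, apex, end = find_boundaries(c, apex_hint=6.8)
        assert apex == pytest.approx(7.0)
        assert start > 4.0 and end < 10.0

    def test_plateau_earliest_maximum(self):
        y = np.array([0.0, 5.0, 9.0, 9.0, 5.0, 0.0])
        c = Chromatogram(np.arange(6.0), y, 1.0)
        _, apex, _ = find_boundaries(c, apex_hint=3.4)
        assert apex == 2.0

    def test_all_zero_returns_none(self):
        c = Chromatogram(np.arange(5.0), np.zeros(5), 1.0)
        assert find_boundaries(c, apex_hint=2.0) is None


class TestQuantifyFeature:
    MZ = 500.0

    def test_gaussian_area(self):
        sigma, area = 0.05, 1000 * sigma_area()
        pm = build_peak_map(peaks=[(self.MZ, 5.0, 0.05, area)])
        feat = quantify_feature(pm, self.MZ, 2, 4.7, 5.3, apex_hint=5.0)
        assert feat is not None
        assert feat.intensity == pytest.approx(area, rel=0.02)
        assert abs(feat.rt_apex - 5.0) < 0.05

    def test_background_subtraction(self):
        area = 1000 * sigma_area()
        clean = build_peak_map(peaks=[(self.MZ, 5.0, 0.05, area)])
        on_baseline = build_peak_map(peaks=[(self.MZ, 5.0, 0.05, area)],
                                     baseline=100.0, baseline_mz=self.MZ)
        f0 = quantify_feature(clean, self.MZ, 2, 4.7, 5.3, apex_hint=5.0)
        f1 = quantify_feature(on_baseline, self.MZ, 2, 4.7, 5.3, apex_hint=5.0)
        assert f1.intensity == pytest.approx(f0.intensity, rel=0.05)

    def test_empty_region_returns_none(self):
        pm = build_peak_map(peaks=[(self.MZ, 5.0, 0.05, 100.0)])
        assert quantify_feature(pm, 600.0, 2, 4.7, 5.3) is None

    def test_isotope_envelope_traced(self):
        from mbrquant.model import ISOTOPE_SPACING

        charge = 2
        peaks = [(self.MZ + k * ISOTOPE_SPACING / charge, 5.0, 0.05,
                  100.0 * w) for k, w in enumerate((1.0, 0.5, 0.15))]
        pm = build_peak_map(peaks=peaks)
        feat = quantify_feature(pm, self.MZ, charge, 4.7, 5.3, apex_hint=5.0)
        i0, i1, i2 = feat.isotope_intensities
        assert i1 / i0 == pytest.approx(0.5, rel=0.05)
        assert i2 / i0 == pytest.approx(0.15, rel=0.1)

    @pytest.mark.parametrize("scale", [0.5, 3.0])
    def test_scaling_is_monotone_linear(self, scale):
        pm = build_peak_map(peaks=[(self.MZ, 5.0, 0.06, 500.0)])
        scaled = mq.RunPeakMap(run_id="s", mz=pm.mz.copy(), rt=pm.rt.copy(),
                               intensity=pm.intensity * scale)
        f0 = quantify_feature(pm, self.MZ, 2, 4.7, 5.3)
        f1 = quantify_feature(scaled, self.MZ, 2, 4.7, 5.3)
        assert f1.intensity == pytest.approx(scale * f0.intensity, rel=1e-6)

    def test_translation_equivariance(self):
        delta = 2.5
        pm = build_peak_map(peaks=[(self.MZ, 5.0, 0.06, 500.0)])
        shifted = mq.RunPeakMap(run_id="s", mz=pm.mz.copy(),
                                rt=pm.rt + delta, intensity=pm.intensity.copy())
        f0 = quantify_feature(pm, self.MZ, 2, 4.7, 5.3)
        f1 = quantify_feature(shifted, self.MZ, 2, 4.7 + delta, 5.3 + delta)
        assert f1.rt_apex == pytest.approx(f0.rt_apex + delta, abs=1e-9)
        assert f1.rt_start == pytest.approx(f0.rt_start + delta, abs=1e-9)
        assert f1.intensity == pytest.approx(f0.intensity, rel=1e-6)

    def test_boundary_stability_wider_region(self):
        pm = build_peak_map(peaks=[(self.MZ, 5.0, 0.05, 800.0)])
        f0 = quantify_feature(pm, self.MZ, 2, 4.7, 5.3, apex_hint=5.0)
        f1 = quantify_feature(pm, self.MZ, 2, 4.4, 5.6, apex_hint=5.0)
        assert f1.intensity == pytest.approx(f0.intensity, rel=0.02)

    def test_im_volume_and_center(self):
        pm = build_peak_map(peaks=[(self.MZ, 5.0, 0.05, 500.0)])
        pm_im = mq.RunPeakMap(run_id="im", mz=pm.mz.copy(), rt=pm.rt.copy(),
                              intensity=pm.intensity.copy(),
                              im=np.full(len(pm), 1.05))
        feat = quantify_feature(pm_im, self.MZ, 2, 4.7, 5.3,
                                im_lo=1.0, im_hi=1.1, apex_hint=5.0)
        assert feat is not None
        assert feat.im_center == pytest.approx(1.05)
        out = quantify_feature(pm_im, self.MZ, 2, 4.7, 5.3,
                               im_lo=1.3, im_hi=1.4, apex_hint=5.0)
        assert out is None  # IM window excludes the signal


def sigma_area() -> float:
    """Analytic area of a unit-height sigma=0.05 Gaussian: h*sigma*sqrt(2pi)."""
    return 0.05 * math.sqrt(2 * math.pi)
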