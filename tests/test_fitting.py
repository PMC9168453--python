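"""Constrained Lorentzian multiplet fitting against generator ground truth."""

import math

import numpy as np
import pytest

from citrace.errors import FitError, LowSignalError, UndefinedRatioError
from citrace.nmr.fitting import (
    FitResult,
    fit_citrate_c24_region,
    fit_citrate_c3_region,
    fit_citrate_regions,
    fit_multiplet,
    fit_proton_doublet_with_satellites,
    fit_singlet,
    measured_ratio_R1,
    PeakModel,
)
from citrace.nmr.spectrum import Spectrum1D

FREQ = 125.76


def build_13c_window(anchor, lines, lw_hz=8.0, noise_sigma=0.0, seed=0,
                     half_width_ppm=1.5):
    """Synthesize a 13C window from (offset_hz, area) pairs (the oracle)."""
    ppm = np.arange(anchor - half_width_ppm, anchor + half_width_ppm, 0.00626)
    intensity = np.zeros_like(ppm)
    for offset_hz, area in lines:
        height = 2.0 * area / (math.pi * lw_hz)
        hw = lw_hz / 2.0 / FREQ
        dx = ppm - (anchor + offset_hz / FREQ)
        intensity += height * hw * hw / (dx * dx + hw * hw)
    if noise_sigma > 0:
        intensity = intensity + np.random.default_rng(seed).normal(
            0, noise_sigma, intensity.size
        )
    return Spectrum1D("13C", ppm, intensity, FREQ)


class TestC24Region:
    def test_recovers_known_amplitudes_at_snr_100(self):
        """Singlet 1.0 + doublet 0.3 each (lw 8 Hz): integrals within 3%."""
        areas = [(0.0, 1.0), (-19.0, 0.3), (19.0, 0.3)]
        tallest = 2.0 * 1.0 / (math.pi * 8.0)
        spec = build_13c_window(46.5, areas, noise_sigma=tallest / 100, seed=1)
        fit = fit_citrate_c24_region(spec)
        assert fit.total("C2/4") == pytest.approx(1.6, rel=0.03)
        assert fit.component_areas["singlet"] == pytest.approx(1.0, rel=0.03)
        assert fit.component_areas["doublet_lo"] == pytest.approx(0.3, rel=0.05)

    def test_zero_signal_window_gives_near_zero_integrals(self):
        spec = build_13c_window(46.5, [], noise_sigma=0.01, seed=2)
        fit = fit_citrate_c24_region(spec)
        # noise floor: area of a 20 Hz line of height ~2 sigma
        floor = 2 * 0.01 * math.pi * 20.0 / 2
        assert fit.total("C2/4") < floor

    def test_broad_line_clamps_at_upper_linewidth_bound(self):
        """Ground-truth 25 Hz linewidth converges at the 20 Hz bound."""
        areas = [(0.0, 1.0), (-19.0, 0.2), (19.0, 0.2)]
        spec = build_13c_window(46.5, areas, lw_hz=25.0)
        fit = fit_citrate_c24_region(spec)
        assert fit.linewidths_hz["lw"] == pytest.approx(20.0, abs=1e-6)
        assert "lw" in fit.at_bound

    def test_amplitude_linearity(self):
        """Doubling all intensities doubles all fitted integrals (noiseless)."""
        areas = [(0.0, 1.0), (-19.0, 0.3), (19.0, 0.3)]
        spec1 = build_13c_window(46.5, areas)
        spec2 = Spectrum1D("13C", spec1.ppm, 2.0 * spec1.intensity, FREQ)
        f1 = fit_citrate_c24_region(spec1)
        f2 = fit_citrate_c24_region(spec2)
        assert f2.total("C2/4") == pytest.approx(2.0 * f1.total("C2/4"), rel=1e-6)

    def test_missing_window_raises(self):
        spec = build_13c_window(100.0, [(0.0, 1.0)])
        with pytest.raises(FitError, match="window"):
            fit_citrate_c24_region(spec)

    def test_low_signal_guard(self):
        spec = build_13c_window(46.5, [], noise_sigma=0.01, seed=3)
        with pytest.raises(LowSignalError):
            fit_citrate_c24_region(spec, require_signal=True)


class TestC3Region:
    def test_recovers_five_line_pattern(self):
        areas = [(0.0, 0.6), (-19.0, 0.15), (19.0, 0.15), (-38.0, 0.05), (38.0, 0.05)]
        tallest = 2.0 * 0.6 / (math.pi * 8.0)
        spec = build_13c_window(76.2, areas, noise_sigma=tallest / 100, seed=4)
        fit = fit_citrate_c3_region(spec)
        assert fit.total("C3") == pytest.approx(1.0, rel=0.03)

    def test_central_line_only_gives_zero_outer(self):
        spec = build_13c_window(76.2, [(0.0, 1.0)])
        fit = fit_citrate_c3_region(spec)
        assert fit.component_areas["outer_m19"] == pytest.approx(0.0, abs=1e-6)
        assert fit.component_areas["outer_m38"] == pytest.approx(0.0, abs=1e-6)

    def test_extraneous_line_degrades_goodness_of_fit(self):
        """An unmodeled line 60 Hz away shows up in the residual."""
        areas = [(0.0, 0.6), (-19.0, 0.15), (19.0, 0.15), (60.0, 0.5)]
        tallest = 2.0 * 0.6 / (math.pi * 8.0)
        clean = [(0.0, 0.6), (-19.0, 0.15), (19.0, 0.15)]
        noisy = build_13c_window(76.2, areas, noise_sigma=tallest / 200, seed=5)
        ref = build_13c_window(76.2, clean, noise_sigma=tallest / 200, seed=5)
        bad = fit_citrate_c3_region(noisy)
        good = fit_citrate_c3_region(ref)
        assert bad.gof > 3.0 * good.gof

    def test_linewidth_carry_over_pipeline(self):
        """fit_citrate_regions pins the C3 linewidth from the C2/4 fit."""
        c24_lines = [(0.0, 1.0), (-19.0, 0.3), (19.0, 0.3)]
        ppm = np.arange(40.0, 80.0, 0.00626)
        intensity = np.zeros_like(ppm)
        for anchor, lines in ((46.5, c24_lines), (76.2, [(0.0, 0.25)])):
            for offset_hz, area in lines:
                height = 2.0 * area / (math.pi * 8.0)
                hw = 8.0 / 2.0 / FREQ
                dx = ppm - (anchor + offset_hz / FREQ)
                intensity += height * hw * hw / (dx * dx + hw * hw)
        spec = Spectrum1D("13C", ppm, intensity, FREQ)
        c24, c3 = fit_citrate_regions(spec)
        assert c3.linewidths_hz["lw"] == pytest.approx(c24.linewidths_hz["lw"])
        assert c3.total("C3") == pytest.approx(0.25, rel=0.01)


class TestSingletAndProton:
    def test_singlet_area(self):
        spec = build_13c_window(179.7, [(0.0, 0.8)])
        fit = fit_singlet(spec, 179.7, group="C1/5")
        assert fit.total("C1/5") == pytest.approx(0.8, rel=0.01)

    def test_proton_satellite_enrichment_recovery(self):
        """Satellite/total fraction of a methyl doublet recovers f = 0.8."""
        freq_h = 500.0
        ppm = np.arange(1.0, 1.7, 0.00061)
        intensity = np.zeros_like(ppm)
        total = 3.0
        f = 0.8
        lw = 1.2
        for sign in (-1, 1):
            for s2, area in [(0, total * (1 - f) / 2)]:
                dx = ppm - (1.33 + sign * 3.45 / freq_h)
                hw = lw / 2 / freq_h
                intensity += (2 * area / (math.pi * lw)) * hw * hw / (dx * dx + hw * hw)
            for s2 in (-1, 1):
                area = total * f / 4
                dx = ppm - (1.33 + sign * 63.5 / freq_h + s2 * 3.45 / freq_h)
                hw = lw / 2 / freq_h
                intensity += (2 * area / (math.pi * lw)) * hw * hw / (dx * dx + hw * hw)
        spec = Spectrum1D("1H", ppm, intensity, freq_h)
        fit = fit_proton_doublet_with_satellites(spec, 1.33)
        sat = fit.total("satellite")
        unl = fit.total("unlabeled")
        assert sat / (sat + unl) == pytest.approx(0.8, abs=0.01)


class TestMeasuredR1:
    def _fit_result(self, totals):
        return FitResult(
            component_areas={}, component_area_stderr={}, group_totals=totals,
            anchor_ppm=0.0, linewidths_hz={}, phase_rad=0.0,
            residual_rms=0.0, noise_sigma=1.0,
        )

    def test_midpoint_construction(self):
        c24 = self._fit_result({"C2/4": 4.0})
        c3 = self._fit_result({"C3": 1.0})
        assert measured_ratio_R1(c24, c3) == pytest.approx(0.75)

    def test_half_and_one(self):
        c24 = self._fit_result({"C2/4": 2.0})
        assert measured_ratio_R1(c24, self._fit_result({"C3": 1.0})) == pytest.approx(0.5)
        assert measured_ratio_R1(c24, self._fit_result({"C3": 0.0})) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(UndefinedRatioError):
            measured_ratio_R1(self._fit_result({"C2/4": 0.0}),
                              self._fit_result({"C3": 1.0}))
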