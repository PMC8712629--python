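"""Baseline subtraction, peak picking, recalibration, summing, discovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nglyco.process import (CalibrationError, discover_compositions, pick_peaks,
                            preprocess, recalibrate, sum_spectra)
from nglyco.sim import InstrumentModel, render_spectrum
from nglyco.spectrum import Spectrum


def _gaussian_spectrum(centers, areas, sigma=0.05, mz0=1000.0, mz1=1100.0,
                       step=0.01, baseline=None, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    mz = np.arange(mz0, mz1 + step / 2, step)
    y = np.zeros_like(mz)
    for c, a in zip(centers, areas):
        y += a / (sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    if baseline is not None:
        y += baseline(mz)
    if noise:
        y += rng.normal(0, noise, mz.size)
    return Spectrum(mz, y)


def test_flat_spectrum_goes_to_zero():
    spec = Spectrum(np.arange(1000.0, 1100.0, 0.01),
                    np.full(10000, 37.0))
    out = preprocess(spec, baseline_window=5.0)
    assert np.abs(out.intensity).max() < 1e-6
    assert out.baseline_subtracted and out.smoothed


def test_peak_area_recovered_on_exponential_baseline():
    area = 120.0
    spec = _gaussian_spectrum([1050.0], [area],
                              baseline=lambda mz: 40 * np.exp(-(mz - 1000) / 200))
    out = preprocess(spec, baseline_window=5.0)
    lo, hi = np.searchsorted(out.mz, [1049.0, 1051.0])
    got = np.trapezoid(out.intensity[lo:hi], out.mz[lo:hi])
    assert got == pytest.approx(area, rel=0.02)


def test_smoothing_near_idempotent():
    spec = _gaussian_spectrum([1050.0], [50.0], sigma=0.2)
    once = preprocess(spec, baseline_window=5.0)
    twice = preprocess(once.copy_with(baseline_subtracted=False, smoothed=False),
                       baseline_window=5.0)
    assert np.abs(twice.intensity - once.intensity).max() < \
        0.01 * once.intensity.max()


def test_single_peak_picked_at_apex():
    spec = _gaussian_spectrum([1050.0], [100.0])
    out = preprocess(spec, baseline_window=5.0)
    peaks = pick_peaks(out, snr_min=3.0)
    top = max(peaks, key=lambda p: p.intensity)
    assert abs(top.mz - 1050.0) < 0.01
    assert top.rel_intensity == 1.0


def test_two_peaks_separated_by_four_sigma_both_found():
    spec = _gaussian_spectrum([1050.0, 1050.0 + 4 * 0.05], [100.0, 80.0])
    peaks = pick_peaks(preprocess(spec, baseline_window=5.0), snr_min=3.0)
    big = sorted(peaks, key=lambda p: -p.intensity)[:2]
    assert {round(p.mz, 1) for p in big} == {1050.0, 1050.2}


def test_noise_false_positive_rate_is_threshold_consistent():
    """At snr_min = 3 on pure Gaussian noise the picked-peak count is a
    small fraction of all local maxima (upper-tail behaviour of the
    MAD-calibrated threshold), and drops further at snr_min = 5."""
    counts3, counts5, maxima = [], [], []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        spec = Spectrum(np.arange(1000.0, 1200.0, 0.01),
                        rng.normal(0, 4.0, 20000))
        n_max = int(np.sum((np.diff(np.sign(np.diff(spec.intensity))) < 0)))
        counts3.append(len(pick_peaks(spec, snr_min=3.0)))
        counts5.append(len(pick_peaks(spec, snr_min=5.0)))
        maxima.append(n_max)
    frac3 = sum(counts3) / sum(maxima)
    assert 0 < frac3 < 0.02
    assert sum(counts5) < sum(counts3)


def _render(registry, baseline, inst, seed=0):
    return render_spectrum(baseline, registry, inst, seed=seed)


def test_recalibration_removes_planted_drift(registry, baseline, calibrants):
    inst = InstrumentModel(drift_ppm=(30.0, 0.0, 0.0),
                           drift_jitter_ppm=(0.0, 0.0, 0.0), scale_cv=0.0)
    spec = preprocess(_render(registry, baseline, inst))
    cal = recalibrate(spec, calibrants)
    assert cal.calibrated
    held_out = [r for r in registry
                if r.code not in set(cal.calibration.calibrant_codes)]
    ppms = []
    for rec in held_out:
        lo, hi = np.searchsorted(cal.mz, [rec.mass_sodiated - 0.4,
                                          rec.mass_sodiated + 0.4])
        apex = cal.mz[lo + np.argmax(cal.intensity[lo:hi])]
        ppms.append((apex - rec.mass_sodiated) / rec.mass_sodiated * 1e6)
    assert np.mean(np.abs(ppms)) < 5.0


def test_zero_drift_calibration_is_near_identity(registry, baseline, calibrants,
                                                 clean_instrument):
    spec = preprocess(_render(registry, baseline, clean_instrument))
    cal = recalibrate(spec, calibrants)
    assert np.abs(cal.mz - spec.mz).max() < 1e-3


def test_too_few_calibrants_is_calibration_failure(registry, baseline,
                                                   clean_instrument):
    spec = preprocess(_render(registry, baseline, clean_instrument))
    two = [("H5N2", registry.mass("H5N2")), ("H5N4E2", registry.mass("H5N4E2"))]
    with pytest.raises(CalibrationError, match="calibrants"):
        recalibrate(spec, two, min_calibrants=4)


@given(c0=st.floats(-100, 100), c1=st.floats(-30, 30), c2=st.floats(-10, 10))
@settings(max_examples=8, deadline=None)
def test_calibration_improves_any_drift_within_100ppm(c0, c1, c2, registry,
                                                      baseline, calibrants):
    # rescale the sampled polynomial so the drift stays within the +/-100 ppm
    # envelope over the analyte mass range (the property's stated domain)
    u = (np.linspace(1250.0, 3700.0, 50) - 1000.0) / 1000.0
    peak = np.abs(c0 + c1 * u + c2 * u ** 2).max()
    if peak > 100.0:
        c0, c1, c2 = (c * 100.0 / peak for c in (c0, c1, c2))
    inst = InstrumentModel(noise_sd=0.0, baseline_amplitude=0.0,
                           drift_ppm=(c0, c1, c2),
                           drift_jitter_ppm=(0.0, 0.0, 0.0), scale_cv=0.0)
    spec = preprocess(_render(registry, baseline, inst))
    cal = recalibrate(spec, calibrants, ppm_window=250.0)

    def mean_abs_ppm(s):
        vals = []
        for rec in registry:
            if rec.code in set(c for c, _ in calibrants):
                continue
            lo, hi = np.searchsorted(s.mz, [rec.mass_sodiated - 0.6,
                                            rec.mass_sodiated + 0.6])
            apex = s.mz[lo + np.argmax(s.intensity[lo:hi])]
            vals.append(abs(apex - rec.mass_sodiated) / rec.mass_sodiated * 1e6)
        return float(np.mean(vals))

    assert mean_abs_ppm(cal) < 5.0
    if max(abs(c0), abs(c1), abs(c2)) > 5:
        assert mean_abs_ppm(cal) <= mean_abs_ppm(spec)


def test_peak_areas_conserved_through_calibration(registry, baseline, calibrants):
    inst = InstrumentModel(noise_sd=0.0, baseline_amplitude=0.0,
                           drift_ppm=(60.0, 20.0, 0.0),
                           drift_jitter_ppm=(0.0, 0.0, 0.0), scale_cv=0.0)
    spec = preprocess(_render(registry, baseline, inst))
    cal = recalibrate(spec, calibrants)
    for code in ("H5N2", "H5N4E2", "H7N6E4"):
        m = registry.mass(code)
        drifted = m * (1 + inst.drift_at(m) / 1e6)
        lo, hi = np.searchsorted(spec.mz, [drifted - 0.45, drifted + 0.45])
        before = np.trapezoid(spec.intensity[lo:hi], spec.mz[lo:hi])
        lo, hi = np.searchsorted(cal.mz, [m - 0.45, m + 0.45])
        after = np.trapezoid(cal.intensity[lo:hi], cal.mz[lo:hi])
        assert after == pytest.approx(before, rel=0.005), code


def test_sum_spectra_linearity_and_errors(registry, baseline, clean_instrument):
    spec = preprocess(_render(registry, baseline, clean_instrument))
    grid = spec.mz.copy()
    total = sum_spectra([spec] * 3, grid)
    np.testing.assert_allclose(total.intensity, 3 * spec.intensity, rtol=1e-12)
    single = sum_spectra([spec], grid)
    np.testing.assert_allclose(single.intensity, spec.intensity, atol=1e-9)
    with pytest.raises(ValueError):
        sum_spectra([], grid)


def test_summed_group_spectrum_improves_snr(registry, baseline, calibrants):
    inst = InstrumentModel(drift_ppm=(0.0, 0.0, 0.0),
                           drift_jitter_ppm=(0.0, 0.0, 0.0), scale_cv=0.0)
    specs = [preprocess(_render(registry, baseline, inst, seed=s))
             for s in range(4)]
    grid = specs[0].mz
    summed = sum_spectra(specs, grid)

    def snr_of(spec, code):
        peaks = pick_peaks(spec, snr_min=3.0)
        m = registry.mass(code)
        cand = [p for p in peaks if abs(p.mz - m) < 0.3]
        return max((p.snr for p in cand), default=0.0)

    code = "H6N3E1"     # a minor analyte
    assert snr_of(summed, code) > np.mean([snr_of(s, code) for s in specs])


class TestDiscovery:
    def test_recovers_planted_compositions_without_noise(self, registry,
                                                         clean_instrument):
        picks = ["H5N2", "H4N4F1", "H5N4E1", "H5N4E2", "H5N4L1E1", "H6N5E3",
                 "H6N5L1E2", "H7N6E4", "H5N5F1", "H6N3E1"]
        a = pd.Series(0.0, index=registry.codes)
        a[picks] = 1.0 / len(picks)
        spec = render_spectrum(a, registry, clean_instrument, seed=0)
        found = discover_compositions(preprocess(spec), ppm_tol=10.0)
        good = found[found["qc_score"] < 0.25]
        assert set(picks) <= set(good["code"])

    def test_relative_intensity_threshold_semantics(self, registry,
                                                    clean_instrument):
        a = pd.Series(0.0, index=registry.codes)
        a["H5N4E2"] = 1.0 - 0.0002
        a["H5N2"] = 0.0002            # ~0.05% apex relative intensity
        spec = render_spectrum(a, registry, clean_instrument, seed=0)
        found = discover_compositions(preprocess(spec), rel_int_min=0.001)
        assert "H5N2" not in set(found["code"])
        found_loose = discover_compositions(preprocess(spec), rel_int_min=1e-5)
        assert "H5N2" in set(found_loose["code"])

    def test_match_is_smallest_abs_ppm(self, registry, clean_instrument):
        a = pd.Series(0.0, index=registry.codes)
        a["H5N4E2"] = 1.0
        spec = render_spectrum(a, registry, clean_instrument, seed=0)
        found = discover_compositions(preprocess(spec), ppm_tol=20.0)
        row = found[found["code"] == "H5N4E2"].iloc[0]
        assert abs(row["ppm_error"]) < 3.0
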