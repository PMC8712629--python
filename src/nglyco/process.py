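"""Spectrum preprocessing, peak picking, internal recalibration and
composition discovery.

The processing chain mirrors standard MALDI-TOF glycomics practice:

1. baseline estimation by a moving minimum followed by a moving average
   (window in Da) and subtraction;
2. Savitzky-Golay (polynomial-kernel) smoothing;
3. peak picking on local maxima with a windowed-MAD noise estimate
   (sigma = 1.4826 x MAD) and 3-point parabolic apex refinement;
4. internal recalibration against theoretical [M+Na]+ masses of abundant
   glycan calibrants (degree-2 polynomial of observed -> theoretical m/z);
5. group-summed spectra and S/N + relative-intensity gated matching of
   peaks to a composition search space (candidate discovery).

Intensities are never rescaled by the axis transform: integrated areas are
computed by trapezoidal integration on the (possibly non-uniform)
calibrated axis, which conserves area through calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks, savgol_filter

from .chem import (ISOTOPE_SPACING, enumerate_compositions, isotopic_distribution,
                   min_isotopologues, molecular_formula, monoisotopic_mass)
from .spectrum import CalibrationFit, Spectrum

logger = logging.getLogger(__name__)

__all__ = ["Peak", "CalibrationError", "preprocess", "local_noise", "pick_peaks",
           "recalibrate", "sum_spectra", "discover_compositions",
           "isotopologue_areas", "default_calibrants"]


class CalibrationError(RuntimeError):
    """Internal recalibration failed for one spectrum (excluded downstream)."""


@dataclass(frozen=True)
class Peak:
    """One picked peak with its local-noise context."""

    mz: float                 # parabola-refined apex m/z
    intensity: float          # apex intensity
    area: float               # trapezoidal area between flanking minima
    noise: float              # local noise (1.4826 x windowed MAD)
    snr: float
    rel_intensity: float      # fraction of the base peak's apex intensity


def preprocess(spectrum: Spectrum, baseline_window: float = 10.0,
               smooth_window: int = 7, smooth_polyorder: int = 2) -> Spectrum:
    """Baseline-subtract (moving minimum + moving average, window in Da)
    and Savitzky-Golay smooth a raw spectrum."""
    if baseline_window <= 0 or smooth_window <= 0:
        raise ValueError("windows must be positive")
    span = spectrum.mz[-1] - spectrum.mz[0]
    if baseline_window >= span:
        raise ValueError(f"baseline window {baseline_window} Da exceeds spectrum "
                         f"span {span:.1f} Da")
    step = float(np.median(np.diff(spectrum.mz)))
    size = max(3, int(round(baseline_window / step)) | 1)
    baseline = uniform_filter1d(minimum_filter1d(spectrum.intensity, size), size)
    y = spectrum.intensity - baseline
    # the moving minimum sits ~3 noise SD below the true background; re-center
    # on the blockwise local median so signal-free regions sit at zero
    y = y - _local_median(spectrum.mz, y, window=baseline_window)
    win = max(smooth_polyorder + 2, int(smooth_window)) | 1
    y = savgol_filter(y, win, smooth_polyorder)
    return spectrum.copy_with(intensity=y, baseline_subtracted=True, smoothed=True)


def _local_median(mz: np.ndarray, y: np.ndarray, window: float) -> np.ndarray:
    nblocks = max(1, int(np.ceil((mz[-1] - mz[0]) / window)))
    edges = np.linspace(mz[0], mz[-1], nblocks + 1)
    idx = np.searchsorted(mz, edges)
    centers, meds = [], []
    for i in range(nblocks):
        seg = y[idx[i]:max(idx[i + 1], idx[i] + 1)]
        if seg.size:
            meds.append(float(np.median(seg)))
            centers.append(0.5 * (edges[i] + edges[i + 1]))
    return np.interp(mz, centers, meds)


def local_noise(spectrum: Spectrum, window: float = 5.0) -> np.ndarray:
    """Pointwise noise level: 1.4826 x median absolute deviation, estimated
    in consecutive m/z blocks of ``window`` Da and linearly interpolated."""
    mz, y = spectrum.mz, spectrum.intensity
    nblocks = max(1, int(np.ceil((mz[-1] - mz[0]) / window)))
    edges = np.linspace(mz[0], mz[-1], nblocks + 1)
    idx = np.searchsorted(mz, edges)
    centers, levels = [], []
    for i in range(nblocks):
        seg = y[idx[i]:max(idx[i + 1], idx[i] + 1)]
        if seg.size == 0:
            continue
        med = np.median(seg)
        levels.append(1.4826 * np.median(np.abs(seg - med)))
        centers.append(0.5 * (edges[i] + edges[i + 1]))
    return np.interp(mz, centers, levels)


def _parabolic_apex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i-1, i, i+1 (non-uniform x)."""
    if i == 0 or i == x.size - 1:
        return float(x[i]), float(y[i])
    c = np.polyfit(x[i - 1:i + 2] - x[i], y[i - 1:i + 2], 2)
    if c[0] >= 0:
        return float(x[i]), float(y[i])
    dx = -c[1] / (2 * c[0])
    return float(x[i] + dx), float(np.polyval(c, dx))


def _peak_area(mz: np.ndarray, y: np.ndarray, i: int) -> float:
    """Trapezoidal area between the local minima flanking index ``i``."""
    lo = i
    while lo > 0 and y[lo - 1] < y[lo]:
        lo -= 1
    hi = i
    while hi < y.size - 1 and y[hi + 1] < y[hi]:
        hi += 1
    if hi - lo < 1:
        return 0.0
    return float(np.trapezoid(y[lo:hi + 1], mz[lo:hi + 1]))


def pick_peaks(spectrum: Spectrum, snr_min: float = 3.0,
               noise_window: float = 5.0) -> list[Peak]:
    """Local maxima above ``snr_min`` x local noise, sorted by m/z."""
    y = spectrum.intensity
    noise = np.maximum(local_noise(spectrum, noise_window), 1e-12)
    idx, _ = find_peaks(y)
    idx = idx[y[idx] > snr_min * noise[idx]]
    if idx.size == 0:
        return []
    base = float(y[idx].max())
    peaks = []
    for i in idx:
        apex_mz, apex_int = _parabolic_apex(spectrum.mz, y, int(i))
        peaks.append(Peak(mz=apex_mz, intensity=apex_int,
                          area=_peak_area(spectrum.mz, y, int(i)),
                          noise=float(noise[i]),
                          snr=float(y[i] / noise[i]),
                          rel_intensity=float(y[i] / base)))
    return peaks


def recalibrate(spectrum: Spectrum, calibrants, ppm_window: float = 200.0,
                min_calibrants: int = 4, degree: int = 2,
                snr_min: float = 3.0) -> Spectrum:
    """Recalibrate the m/z axis against internal glycan calibrants.

    ``calibrants`` is a sequence of (code, theoretical m/z).  Picked peaks
    are matched to each calibrant within ``ppm_window``; a polynomial of
    ``degree`` mapping observed to theoretical m/z is fitted and applied.
    Fewer than ``min_calibrants`` matches (or a non-monotone transform)
    raises :class:`CalibrationError`.
    """
    peaks = pick_peaks(spectrum, snr_min=snr_min)
    apexes = np.array([p.mz for p in peaks])
    # candidate peaks per calibrant within the ppm window; the initial match
    # is the nearest, then matches are iteratively reassigned to the
    # candidate most consistent with the current polynomial fit (a nearest
    # match alone can lock onto the M+1 isotopologue under strong drift)
    cands, matched_obs, matched_theo, matched_codes = [], [], [], []
    for code, theo in calibrants:
        if apexes.size == 0:
            break
        within = apexes[np.abs(apexes - theo) / theo * 1e6 <= ppm_window]
        if within.size:
            cands.append(within)
            matched_obs.append(within[np.argmin(np.abs(within - theo))])
            matched_theo.append(theo)
            matched_codes.append(code)
    needed = max(min_calibrants, degree + 1)
    if len(matched_obs) < needed:
        raise CalibrationError(
            f"{spectrum.sample_id or 'spectrum'}: only {len(matched_obs)} of "
            f"{len(list(calibrants))} calibrants matched (minimum {needed})")
    obs = np.asarray(matched_obs)
    theo = np.asarray(matched_theo)
    if obs.size >= 3:
        # robust (Theil-Sen) line through the ppm offsets disambiguates
        # candidates before the polynomial fit: a least-squares fit alone
        # can be bent toward a mismatched high-leverage endpoint
        from scipy.stats import theilslopes
        ppm = (obs - theo) / theo * 1e6
        slope, intercept, _, _ = theilslopes(ppm, theo)
        obs = np.array([
            c[np.argmin(np.abs((c - t) / t * 1e6 - (intercept + slope * t)))]
            for c, t in zip(cands, theo)])
    for _ in range(3):
        coeffs = np.polyfit(obs, theo, degree)
        new_obs = np.array([c[np.argmin(np.abs(np.polyval(coeffs, c) - t))]
                            for c, t in zip(cands, theo)])
        if np.array_equal(new_obs, obs):
            break
        obs = new_obs
    coeffs = np.polyfit(obs, theo, degree)
    resid = np.abs(np.polyval(coeffs, obs) - theo) / theo * 1e6
    keep = resid <= max(10.0, 5.0 * float(np.median(resid)))
    if keep.sum() >= needed and not keep.all():
        obs, theo = obs[keep], theo[keep]
        matched_codes = [c for c, k in zip(matched_codes, keep) if k]
        coeffs = np.polyfit(obs, theo, degree)
    new_mz = np.polyval(coeffs, spectrum.mz)
    if not np.all(np.diff(new_mz) > 0):
        raise CalibrationError(f"{spectrum.sample_id or 'spectrum'}: "
                               f"calibration transform is not monotone")
    residual_ppm = (np.polyval(coeffs, obs) - theo) / theo * 1e6
    fit = CalibrationFit(coefficients=coeffs, calibrant_codes=matched_codes,
                         residual_ppm=residual_ppm)
    return spectrum.copy_with(mz=new_mz, calibrated=True, calibration=fit)


def sum_spectra(spectra, grid: np.ndarray) -> Spectrum:
    """Sum calibrated spectra after linear interpolation onto a common grid."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot sum an empty list of spectra")
    total = np.zeros_like(grid, dtype=float)
    for spec in spectra:
        total += np.interp(grid, spec.mz, spec.intensity, left=0.0, right=0.0)
    return Spectrum(grid, total, sample_id="summed",
                    baseline_subtracted=all(s.baseline_subtracted for s in spectra),
                    smoothed=all(s.smoothed for s in spectra),
                    calibrated=all(s.calibrated for s in spectra))


def isotopologue_areas(spectrum: Spectrum, mz_mono: float, n_iso: int,
                       resolving_power: float = 15000.0,
                       spacing: float = 1.00336) -> tuple[np.ndarray, float, float]:
    """Background-corrected areas of the first ``n_iso`` isotopologue windows.

    Each window is centered on ``mz_mono + i x spacing`` with half-width
    4 sigma (sigma from the FWHM resolving power, clipped to [0.08, 0.35]
    Da); the local background is the line through the minimum points of
    the flanking gap regions and is subtracted before trapezoidal
    integration.  Returns (areas, apex m/z, apex intensity) where the apex
    refers to the background-corrected monoisotopic window.
    """
    areas = np.zeros(n_iso)
    apex_mz, apex_int = float("nan"), 0.0
    for i in range(n_iso):
        c = mz_mono + i * spacing
        sigma = c / resolving_power / 2.3548
        w = float(np.clip(4.0 * sigma, 0.08, 0.35))
        x, y = spectrum.slice(c - w, c + w)
        if x.size < 3:
            continue
        bg_lo = _region_min(spectrum, c - 0.5, c - w)
        bg_hi = _region_min(spectrum, c + w, c + 0.5)
        if bg_lo is None or bg_hi is None:
            bg = np.zeros_like(y)
        else:
            (x0, y0), (x1, y1) = bg_lo, bg_hi
            bg = y0 + (y1 - y0) * (x - x0) / (x1 - x0)
        ysub = y - bg
        areas[i] = max(float(np.trapezoid(ysub, x)), 0.0)
        if i == 0:
            j = int(np.argmax(ysub))
            apex_mz, apex_int = _parabolic_apex(x, ysub, j)
    return areas, apex_mz, apex_int


def _region_min(spectrum: Spectrum, lo: float, hi: float):
    x, y = spectrum.slice(lo, hi)
    if x.size == 0:
        return None
    j = int(np.argmin(y))
    return float(x[j]), float(y[j])


def default_calibrants(registry, baseline: dict, n: int = 8) -> list[tuple[str, float]]:
    """Pick the highest-abundance registry composition in each of ``n``
    equal mass bins as internal calibrants spanning the mass range."""
    recs = sorted(registry, key=lambda r: r.mass_sodiated)
    masses = np.array([r.mass_sodiated for r in recs])
    edges = np.linspace(masses[0] - 1e-9, masses[-1] + 1e-9, n + 1)
    picks = []
    for i in range(n):
        members = [r for r, m in zip(recs, masses)
                   if edges[i] <= m < edges[i + 1]]
        if not members:
            continue
        best = max(members, key=lambda r: baseline.get(r.code, 0.0))
        picks.append((best.code, best.mass_sodiated))
    return picks


def discover_compositions(summed: Spectrum, *, h_max: int = 9, n_max: int = 7,
                          f_max: int = 3, sialic_max: int = 4,
                          ppm_tol: float = 20.0, snr_min: float = 3.0,
                          rel_int_min: float = 0.001,
                          resolving_power: float = 15000.0) -> pd.DataFrame:
    """Match quality-gated peaks of a summed spectrum to a composition
    search space.

    Peaks passing the S/N and relative-intensity cut-offs are matched to
    the candidate composition of smallest |ppm error| within ``ppm_tol``
    (exact ties resolved toward the lower mass, logged).  Each match
    carries the isotopic-pattern deviation (QC score) computed from the
    summed trace.  Returns one row per matched composition.
    """
    peaks = [p for p in pick_peaks(summed, snr_min=snr_min)
             if p.rel_intensity > rel_int_min]
    candidates = sorted(enumerate_compositions(h_max, n_max, f_max, sialic_max),
                        key=lambda c: monoisotopic_mass(c, "sodiated"))
    cand_masses = np.array([monoisotopic_mass(c, "sodiated") for c in candidates])
    rows = []
    seen = {}
    for p in peaks:
        ppm = (p.mz - cand_masses) / cand_masses * 1e6
        order = np.lexsort((cand_masses, np.abs(ppm)))
        j = int(order[0])
        if abs(ppm[j]) > ppm_tol:
            continue
        if order.size > 1 and abs(abs(ppm[order[1]]) - abs(ppm[j])) < 1e-9:
            logger.info("discovery tie at m/z %.4f broken toward lower mass (%s)",
                        p.mz, candidates[j].code)
        comp = candidates[j]
        formula = molecular_formula(comp)
        k = min_isotopologues(formula)
        theo = isotopic_distribution(formula, k)
        obs, _, _ = isotopologue_areas(summed, cand_masses[j], k,
                                       resolving_power=resolving_power)
        qc = float(np.abs(obs / obs.sum() - theo).sum()) if obs.sum() > 0 else 2.0
        row = {"code": comp.code, "mz_theoretical": float(cand_masses[j]),
               "mz_observed": p.mz, "ppm_error": float(ppm[j]), "snr": p.snr,
               "rel_intensity": p.rel_intensity, "qc_score": qc}
        # keep the best (smallest |ppm|) peak per composition
        prev = seen.get(comp.code)
        if prev is None or abs(row["ppm_error"]) < abs(prev["ppm_error"]):
            seen[comp.code] = row
    rows = sorted(seen.values(), key=lambda r: r["mz_theoretical"])
    return pd.DataFrame(rows, columns=["code", "mz_theoretical", "mz_observed",
                                       "ppm_error", "snr", "rel_intensity",
                                       "qc_score"])
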