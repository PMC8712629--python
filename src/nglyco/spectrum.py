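"""Mass-spectrum container and two-column XY text I/O.

Profile-mode spectra travel through the pipeline as plain ``.xy`` files:
two whitespace- or tab-separated numeric columns (m/z in Da, strictly
increasing, and intensity in arbitrary units).  The container keeps the
processing provenance (baseline-subtracted, smoothed, calibrated) and,
once internally recalibrated, the calibration fit with its residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Spectrum", "CalibrationFit", "XYFormatError", "read_xy", "write_xy"]


class XYFormatError(ValueError):
    """Malformed two-column XY spectrum file."""


@dataclass
class CalibrationFit:
    """Polynomial m/z correction fitted against internal glycan calibrants."""

    coefficients: np.ndarray            # np.polyval order (highest first)
    calibrant_codes: list[str]
    residual_ppm: np.ndarray            # per-calibrant residual after transform

    @property
    def mean_abs_residual_ppm(self) -> float:
        return float(np.mean(np.abs(self.residual_ppm)))


@dataclass
class Spectrum:
    """An m/z-intensity trace with processing provenance."""

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str | None = None
    baseline_subtracted: bool = False
    smoothed: bool = False
    calibrated: bool = False
    calibration: CalibrationFit | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z axis must be strictly increasing")

    def copy_with(self, **kwargs) -> "Spectrum":
        return replace(self, **kwargs)

    def slice(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        """Views of (mz, intensity) on the half-open index range [lo, hi]."""
        i = np.searchsorted(self.mz, lo, side="left")
        j = np.searchsorted(self.mz, hi, side="right")
        return self.mz[i:j], self.intensity[i:j]


def write_xy(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text (full float round-trip precision)."""
    data = np.column_stack([spectrum.mz, spectrum.intensity])
    np.savetxt(path, data, fmt="%.17g\t%.17g".split("\t"), delimiter="\t")


def read_xy(path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column XY spectrum; errors carry the offending line number."""
    import warnings
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            data = np.loadtxt(path, ndmin=2)
        bad_line = None
    except ValueError:
        data, bad_line = None, _first_bad_line(path)
    if bad_line is not None:
        raise XYFormatError(f"{path}: non-numeric or malformed row at line {bad_line}")
    if data is None or data.size == 0:
        raise XYFormatError(f"{path}: empty spectrum file")
    if data.shape[1] != 2:
        raise XYFormatError(f"{path}: expected two columns, got {data.shape[1]}")
    mz, inten = data[:, 0], data[:, 1]
    steps = np.diff(mz)
    if np.any(steps <= 0):
        line = int(np.argmax(steps <= 0)) + 2
        raise XYFormatError(f"{path}: m/z not strictly increasing at line {line}")
    if mz.size < 2:
        raise XYFormatError(f"{path}: fewer than two data rows")
    return Spectrum(mz, inten, sample_id=sample_id)


def _first_bad_line(path) -> int:
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            if len(parts) != 2:
                return i
            try:
                float(parts[0]), float(parts[1])
            except ValueError:
                return i
    return 1
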