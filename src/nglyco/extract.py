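"""Targeted per-sample quantification, quality scoring, curation and
total-area normalization.

For every curated composition the extractor integrates the isotopologue
windows that cover at least 95% of the theoretical envelope, corrects each
window by a local linear background (interpolated between the flanking
minima), and records: the background-corrected area, the local S/N of the
monoisotopic apex, the signed ppm mass error, and the isotopic-pattern
quality score (QC score) - the L1 deviation between observed and
theoretical isotopologue fractions, a number in [0, 2] conventionally
expressed as a percentage.

Curation applies the cascade of per-spectrum cut-offs (S/N > 9,
|ppm error| < 20, QC score < 25%) and retains a composition when it passes
in more than 50% of the spectra of at least one of the HAE, HC or QC
groups ("any-group" rule; the stricter all-groups reading is available as
``mode="all"``).  The retained areas of each sample are normalized to a
total of one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import isotopic_distribution, min_isotopologues, molecular_formula
from .process import isotopologue_areas, local_noise
from .registry import CompositionRegistry
from .spectrum import Spectrum

logger = logging.getLogger(__name__)

__all__ = ["AnalyteMeasurement", "ExtractionParams", "CurationThresholds",
           "CurationReport", "extract_analyte", "extract_cohort", "curate",
           "normalize", "CURATION_GROUPS"]

#: Mapping of sample groups onto the three curation groups.
CURATION_GROUPS = {"untreated-HAE": "HAE", "treated-HAE": "HAE",
                   "HC": "HC", "QC": "QC"}


@dataclass(frozen=True)
class ExtractionParams:
    ppm_tol: float = 50.0            # presence gate on the apex mass error
    resolving_power: float = 15000.0
    coverage: float = 0.95           # theoretical envelope coverage to integrate
    spacing: float = 1.00336         # isotopologue window spacing, Da
    noise_window: float = 5.0        # Da, for the local-MAD noise estimate
    presence_snr: float = 2.0        # apex must exceed this multiple of noise


@dataclass(frozen=True)
class AnalyteMeasurement:
    """Per-sample, per-composition extraction record."""

    sample_id: str
    code: str
    area: float
    snr: float
    ppm_error: float
    qc_score: float
    present: bool


@dataclass(frozen=True)
class CurationThresholds:
    snr: float = 9.0
    ppm: float = 20.0
    qc: float = 0.25
    presence: float = 0.50


@dataclass
class CurationReport:
    report: pd.DataFrame             # per-composition pass rates and decision
    retained: list                   # retained composition codes
    thresholds: CurationThresholds


def extract_analyte(spectrum: Spectrum, code: str, registry: CompositionRegistry,
                    params: ExtractionParams = ExtractionParams()) -> AnalyteMeasurement:
    """Extract one composition from one calibrated spectrum.

    When no apex rises above the local noise in the monoisotopic window
    (or the mass error exceeds the presence gate) the measurement is
    returned with ``present=False`` and zero area.
    """
    rec = registry[code]
    formula = molecular_formula(rec.composition)
    k = min_isotopologues(formula, coverage=params.coverage)
    theo = isotopic_distribution(formula, k)
    areas, apex_mz, apex_int = isotopologue_areas(
        spectrum, rec.mass_sodiated, k,
        resolving_power=params.resolving_power, spacing=params.spacing)
    lo = max(spectrum.mz[0], rec.mass_sodiated - 10.0)
    hi = min(spectrum.mz[-1], rec.mass_sodiated + 10.0)
    seg_mz, seg_y = spectrum.slice(lo, hi)
    if seg_mz.size >= 4:
        noise = float(np.median(local_noise(
            Spectrum(seg_mz, seg_y), params.noise_window)))
    else:
        noise = 0.0
    noise_floor = max(noise, 1e-12)
    snr = float(apex_int / noise_floor)
    if np.isnan(apex_mz):
        ppm = float("nan")
    else:
        ppm = float((apex_mz - rec.mass_sodiated) / rec.mass_sodiated * 1e6)
    present = (apex_int > params.presence_snr * noise and apex_int > 0
               and np.isfinite(ppm) and abs(ppm) <= params.ppm_tol)
    total = float(areas.sum())
    if present and total > 0:
        qc = float(np.abs(areas / total - theo).sum())
        area = total
    else:
        present = False
        qc, area = 2.0, 0.0
    return AnalyteMeasurement(sample_id=spectrum.sample_id or "", code=code,
                              area=area, snr=snr, ppm_error=ppm,
                              qc_score=qc, present=present)


def extract_cohort(spectra, codes, registry: CompositionRegistry,
                   params: ExtractionParams = ExtractionParams()) -> pd.DataFrame:
    """Extract a composition list from every spectrum; long-format table."""
    rows = []
    for sid, spec in spectra.items():
        if spec.sample_id is None:
            spec = spec.copy_with(sample_id=sid)
        for code in codes:
            m = extract_analyte(spec, code, registry, params)
            rows.append({"sample_id": sid, "code": code, "area": m.area,
                         "snr": m.snr, "ppm_error": m.ppm_error,
                         "qc_score": m.qc_score, "present": m.present})
    return pd.DataFrame(rows)


def curate(measurements: pd.DataFrame, groups,
           thresholds: CurationThresholds = CurationThresholds(),
           mode: str = "any") -> CurationReport:
    """Apply the curation cascade and decide the retained composition list.

    ``groups`` maps sample_id -> sample group (untreated-HAE, treated-HAE,
    HC or QC).  A composition passes in one spectrum when it is present
    with S/N > ``snr``, |ppm error| < ``ppm`` and QC score < ``qc``
    jointly; it is retained when its pass fraction exceeds ``presence`` in
    at least one curation group (``mode="any"``) or in all of them
    (``mode="all"``).
    """
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    df = measurements.copy()
    grp = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    unknown = set(grp.unique()) - set(CURATION_GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    df["cgroup"] = df["sample_id"].map(grp).map(CURATION_GROUPS)
    if df["cgroup"].isna().any():
        missing = sorted(df.loc[df["cgroup"].isna(), "sample_id"].unique())
        raise ValueError(f"samples without a group label: {missing}")
    df["pass_snr"] = df["present"] & (df["snr"] > thresholds.snr)
    df["pass_ppm"] = df["present"] & (df["ppm_error"].abs() < thresholds.ppm)
    df["pass_qc"] = df["present"] & (df["qc_score"] < thresholds.qc)
    df["pass_all"] = df["pass_snr"] & df["pass_ppm"] & df["pass_qc"]

    rows = []
    cgroups = sorted(df["cgroup"].unique())
    for code, sub in df.groupby("code", sort=False):
        row = {"code": code}
        fracs = {}
        for cg in cgroups:
            g = sub[sub["cgroup"] == cg]
            fracs[cg] = float(g["pass_all"].mean()) if len(g) else float("nan")
            row[f"presence_{cg}"] = fracs[cg]
        for crit in ("snr", "ppm", "qc"):
            row[f"rate_{crit}"] = float(sub[f"pass_{crit}"].mean())
        valid = {cg: f for cg, f in fracs.items() if not np.isnan(f)}
        if mode == "any":
            retained = any(f > thresholds.presence for f in valid.values())
        else:
            retained = bool(valid) and all(f > thresholds.presence
                                           for f in valid.values())
        row["deciding_group"] = max(valid, key=valid.get) if valid else ""
        row["retained"] = retained
        rows.append(row)
    report = pd.DataFrame(rows)
    retained = report.loc[report["retained"], "code"].tolist()
    return CurationReport(report=report, retained=retained, thresholds=thresholds)


def normalize(areas: pd.DataFrame) -> pd.DataFrame:
    """Total-area normalization: each sample's retained areas sum to one.

    Samples whose retained areas are all zero are excluded with a log
    entry rather than propagated as NaN rows.
    """
    if (areas.to_numpy() < 0).any():
        raise ValueError("negative areas cannot be normalized")
    totals = areas.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        for sid in areas.index[zero]:
            logger.warning("sample %s has zero total retained area; excluded", sid)
    kept = areas.loc[~zero]
    return kept.div(kept.sum(axis=1), axis=0)


def measurements_to_wide(measurements: pd.DataFrame, value: str = "area") -> pd.DataFrame:
    """Pivot the long extraction table to samples x compositions."""
    return measurements.pivot(index="sample_id", columns="code", values=value)
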