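"""Synthetic two-cohort glycomics studies with planted trait effects.

The generator emulates a case/control plasma N-glycomics study: true
per-sample composition abundances on the simplex, group-level effects
planted on the numerator compositions of targeted derived traits, clinical
covariates linked to the true traits, and rendering of every sample as a
realistic MALDI-TOF profile spectrum (isotopologue envelopes, Gaussian
peak shapes, exponential baseline, additive noise and a per-sample
calibration drift).

Compositional noise is logistic-normal: abundances are the softmax of
log-mean plus correlated Gaussian perturbations, so samples stay on the
simplex and the coefficient of variation is interpreted on the log scale.
Effects are multiplicative on the numerator compositions of the targeted
trait - the simplest mechanism that moves a ratio trait predictably - and
are recorded in the ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import isotopic_distribution, min_isotopologues, molecular_formula
from .chem import ISOTOPE_SPACING
from .registry import CompositionRegistry
from .spectrum import Spectrum
from .traits import compute_all, parse_trait_name, trait_weights

__all__ = ["GROUPS", "InstrumentModel", "PlantedEffect", "CovariateModel",
           "CohortDesign", "CohortDataset", "GroundTruth", "simulate_cohort",
           "render_spectrum", "default_baseline", "two_cohort_study"]

GROUP_UNTREATED = "untreated-HAE"
GROUP_TREATED = "treated-HAE"
GROUP_HC = "HC"
GROUP_QC = "QC"
GROUPS = (GROUP_UNTREATED, GROUP_TREATED, GROUP_HC, GROUP_QC)


# Baseline mean relative abundances (arbitrary weights, normalized at use).
# Shaped like a healthy plasma profile: a dominant disialylated diantennary
# glycan, abundant fucosylated diantennary species, minor high-mannose,
# hybrid, bisected and tri-/tetra-antennary series.
_BASELINE_WEIGHTS = {
    "H5N2": 1.5, "H6N2": 0.8, "H7N2": 0.5, "H8N2": 0.4, "H9N2": 0.6,
    "H5N3": 0.3, "H6N3": 0.25, "H5N3E1": 0.35, "H6N3E1": 0.2,
    "H3N4": 0.5, "H3N4F1": 0.6, "H4N4": 0.7, "H4N4F1": 0.9,
    "H5N4": 1.2, "H5N4F1": 1.8, "H4N4E1": 0.5, "H4N4F1E1": 0.6,
    "H5N4E1": 6.0, "H5N4L1": 1.2, "H5N4F1E1": 3.5, "H5N4F1L1": 0.5,
    "H5N4E2": 36.0, "H5N4L1E1": 3.0, "H5N4L2": 0.4,
    "H5N4F1E2": 4.0, "H5N4F1L1E1": 0.7,
    "H3N5": 0.2, "H3N5F1": 0.25, "H4N5": 0.2, "H4N5F1": 0.5,
    "H5N5": 0.3, "H5N5F1": 1.0, "H5N5F1E1": 0.8,
    "H6N5": 0.3, "H6N5F1": 0.25, "H6N5E1": 0.7, "H6N5L1": 0.3,
    "H6N5E2": 1.8, "H6N5L1E1": 1.2, "H6N5E3": 2.5, "H6N5L1E2": 2.0,
    "H6N5L2E1": 0.5, "H6N5F1E1": 0.3, "H6N5F1E2": 0.6, "H6N5F1L1E1": 0.6, "H6N5F1E3": 0.9, "H6N5F1L1E2": 0.7,
    "H7N6": 0.15, "H7N6F1": 0.15, "H7N6E1": 0.15, "H7N6E2": 0.35,
    "H7N6E3": 0.7, "H7N6L1E2": 0.7, "H7N6E4": 0.9,
    "H7N6L1E3": 0.8, "H7N6L2E2": 0.4, "H7N6F1E2": 0.2,
    "H7N6F1E3": 0.35, "H7N6F1L1E2": 0.35, 
}


def default_baseline(registry: CompositionRegistry) -> pd.Series:
    """Default baseline mean abundance vector (sums to one)."""
    w = pd.Series({code: _BASELINE_WEIGHTS.get(code, 0.1)
                   for code in registry.codes}, dtype=float)
    return w / w.sum()


@dataclass(frozen=True)
class InstrumentModel:
    """Forward model of the MALDI-TOF acquisition."""

    mz_min: float = 1000.0
    mz_max: float = 5000.0
    grid_step: float = 0.01
    resolving_power: float = 15000.0        # FWHM definition, m/z-proportional
    drift_ppm: tuple = (0.0, 0.0, 0.0)      # c0 + c1*u + c2*u^2, u=(mz-mz_min)/1000
    drift_jitter_ppm: tuple = (15.0, 5.0, 3.0)  # per-sample SD of each coefficient
    baseline_amplitude: float = 50.0
    baseline_decay: float = 1500.0          # Da
    noise_sd: float = 5.0
    intensity_scale: float = 5e4            # total analyte area at abundance 1
    scale_cv: float = 0.2                   # per-sample log-normal intensity spread

    def __post_init__(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ValueError("mz range low must be below high")
        if self.resolving_power <= 0:
            raise ValueError("resolving power must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be nonnegative")

    def grid(self) -> np.ndarray:
        n = int(round((self.mz_max - self.mz_min) / self.grid_step)) + 1
        return self.mz_min + self.grid_step * np.arange(n)

    def drift_at(self, mz, coefficients=None) -> np.ndarray:
        c = self.drift_ppm if coefficients is None else coefficients
        u = (np.asarray(mz) - self.mz_min) / 1000.0
        return c[0] + c[1] * u + c[2] * u ** 2


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative group effect on the numerator compositions of a trait.

    ``factor`` applies to the untreated case group; the treated group
    keeps ``factor ** treated_residual`` (a small residual models traits
    that respond to therapy, ``1.0`` models unresponsive ones).
    """

    trait: str
    factor: float
    treated_residual: float = 0.15


# Default planted effects: eight differential derived traits spanning
# antennarity, sialylation linkage, fucosylation and bisection, with
# multiplicative factors tuned to produce roughly 1-SD shifts of the true
# trait values under the default biological variability.
DEFAULT_EFFECTS: tuple = (
    PlantedEffect("CA4", 0.90),
    PlantedEffect("CA3", 1.05),
    PlantedEffect("A4L", 1.11),
    PlantedEffect("A3L", 1.11),
    PlantedEffect("A3F", 1.10),
    PlantedEffect("A2F0L", 0.87),
    PlantedEffect("TA2FS0", 0.88, treated_residual=1.0),
    PlantedEffect("A2B", 1.18, treated_residual=1.0),
)


@dataclass(frozen=True)
class CovariateModel:
    """Links from true derived traits to the clinical covariates.

    Edema flags are Bernoulli with logistic links on the within-case
    standardized trait; the 0-7 severity score is Binomial(7, p) with a
    logistic p; C4 and C1-INH levels (g/l) are log-normal around
    disease-typical medians, C1-INH additionally tilted by a trait.
    """

    laryngeal_trait: str = "A2G"
    laryngeal_intercept: float = 0.9
    laryngeal_slope: float = 1.6
    gi_trait: str = "A2F0L"
    gi_intercept: float = 0.9
    gi_slope: float = -1.6
    severity_trait: str = "A2G"
    severity_intercept: float = 0.2
    severity_slope: float = 0.8
    c4_case_median: float = 0.078
    c4_control_median: float = 0.25
    c4_log_sd: float = 0.45
    c1inh_case_median: float = 0.080
    c1inh_control_median: float = 0.30
    c1inh_log_sd: float = 0.30
    c1inh_trait: str = "A3F"
    c1inh_slope: float = -0.15


@dataclass(frozen=True)
class CohortDesign:
    """Design of one simulated cohort.

    Default sample sizes follow a typical rare-disease discovery cohort
    (21 untreated cases, 12 treated cases, 50 controls) plus technical
    replicates of a plasma standard as the quality-control group.
    """

    n_untreated: int = 21
    n_treated: int = 12
    n_hc: int = 50
    n_qc: int = 8
    biological_cv: float = 0.12             # log-scale SD of composition noise
    technical_cv: float = 0.035             # log-scale SD, all spectra incl. QC
    correlation: float = 0.3                # exchangeable biological correlation
    effects: tuple = DEFAULT_EFFECTS
    covariates: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0
    label: str = "cohort"

    def __post_init__(self) -> None:
        if min(self.n_untreated, self.n_treated, self.n_hc, self.n_qc) < 0:
            raise ValueError("sample sizes must be nonnegative")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")


@dataclass
class GroundTruth:
    """Record of what was planted, for downstream truth comparisons."""

    group_means: pd.DataFrame               # compositions x groups
    effects: tuple
    trait_shifts: pd.Series                 # realized standardized shifts (planted traits)
    null_traits: list                       # registry traits with identical group means


@dataclass
class CohortDataset:
    design: CohortDesign
    registry: CompositionRegistry
    metadata: pd.DataFrame                  # sample_id, group, covariates
    abundance: pd.DataFrame                 # true abundances, samples x compositions
    truth: GroundTruth
    spectra: dict | None = None             # sample_id -> Spectrum (rendered)


def _apply_effects(mean: pd.Series, effects, registry, exponent: float = 1.0) -> pd.Series:
    out = mean.to_numpy(dtype=float).copy()
    for eff in effects:
        defn = parse_trait_name(eff.trait)
        w_num, _ = trait_weights(defn, registry)
        mask = w_num > 0
        if not mask.any():
            raise ValueError(f"planted effect {eff.trait!r} selects no registry "
                             f"composition")
        out[mask] *= eff.factor ** exponent
    out /= out.sum()
    return pd.Series(out, index=mean.index)


def _logistic_normal(rng, mean: np.ndarray, sigma: float, rho: float,
                     n: int, tech_sigma: float) -> np.ndarray:
    p = mean.size
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, p))
    z = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * indep
    logx = np.log(mean) + sigma * z + tech_sigma * rng.standard_normal((n, p))
    x = np.exp(logx)
    return x / x.sum(axis=1, keepdims=True)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _standardize(v: pd.Series) -> pd.Series:
    sd = v.std(ddof=1)
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def simulate_cohort(design: CohortDesign, registry: CompositionRegistry | None = None,
                    baseline: pd.Series | None = None,
                    instrument: InstrumentModel | None = None,
                    render: bool = False,
                    seed: int | None = None) -> CohortDataset:
    """Simulate one cohort; optionally render every sample's spectrum.

    Reproducible: the same (design, seed) yields a bit-identical dataset.
    """
    if registry is None:
        registry = CompositionRegistry.default()
    if baseline is None:
        baseline = default_baseline(registry)
    baseline = baseline.reindex(registry.codes)
    if baseline.isna().any() or not np.isclose(baseline.sum(), 1.0):
        raise ValueError("baseline must cover the registry and sum to one")
    rng = np.random.default_rng(design.seed if seed is None else seed)

    mean_hc = baseline.copy()
    mean_untreated = _apply_effects(baseline, design.effects, registry)
    treated_effects = [replace(e, factor=e.factor ** e.treated_residual)
                       for e in design.effects]
    mean_treated = _apply_effects(baseline, treated_effects, registry)
    group_means = pd.DataFrame({GROUP_UNTREATED: mean_untreated,
                                GROUP_TREATED: mean_treated,
                                GROUP_HC: mean_hc, GROUP_QC: baseline})

    rows, abunds = [], []
    plan = [(GROUP_UNTREATED, design.n_untreated, mean_untreated, design.biological_cv),
            (GROUP_TREATED, design.n_treated, mean_treated, design.biological_cv),
            (GROUP_HC, design.n_hc, mean_hc, design.biological_cv),
            (GROUP_QC, design.n_qc, baseline, 0.0)]
    for group, n, mean, bio_cv in plan:
        if n == 0:
            continue
        x = _logistic_normal(rng, mean.to_numpy(), bio_cv, design.correlation,
                             n, design.technical_cv)
        for i in range(n):
            rows.append({"sample_id": f"{design.label}-{group}-{i + 1:03d}",
                         "group": group})
        abunds.append(x)
    metadata = pd.DataFrame(rows)
    abundance = pd.DataFrame(np.vstack(abunds), index=metadata["sample_id"],
                             columns=registry.codes)

    truth_traits = compute_all(abundance, registry)
    metadata = _draw_covariates(rng, metadata, truth_traits, design.covariates)
    truth = _ground_truth(group_means, design.effects, truth_traits,
                          metadata, registry)

    spectra = None
    if render:
        if instrument is None:
            instrument = InstrumentModel()
        spectra = {}
        for sid in metadata["sample_id"]:
            spectra[sid] = render_spectrum(
                abundance.loc[sid], registry, instrument,
                seed=int(rng.integers(0, 2 ** 31 - 1)), sample_id=sid)
    return CohortDataset(design=design, registry=registry, metadata=metadata,
                         abundance=abundance, truth=truth, spectra=spectra)


def _draw_covariates(rng, metadata: pd.DataFrame, traits: pd.DataFrame,
                     cov: CovariateModel) -> pd.DataFrame:
    md = metadata.set_index("sample_id")
    is_case = md["group"].isin([GROUP_UNTREATED, GROUP_TREATED])
    md["laryngeal_edema"] = pd.array([pd.NA] * len(md), dtype="boolean")
    md["gi_edema"] = pd.array([pd.NA] * len(md), dtype="boolean")
    md["severity_score"] = pd.array([pd.NA] * len(md), dtype="Int64")
    md["c4_g_l"] = np.nan
    md["c1inh_g_l"] = np.nan
    case_ids = md.index[is_case]
    if len(case_ids) >= 2:
        z_lar = _standardize(traits.loc[case_ids, cov.laryngeal_trait])
        z_gi = _standardize(traits.loc[case_ids, cov.gi_trait])
        z_sev = _standardize(traits.loc[case_ids, cov.severity_trait])
        z_c1 = _standardize(traits.loc[case_ids, cov.c1inh_trait])
        p_lar = _sigmoid(cov.laryngeal_intercept + cov.laryngeal_slope * z_lar)
        p_gi = _sigmoid(cov.gi_intercept + cov.gi_slope * z_gi)
        p_sev = _sigmoid(cov.severity_intercept + cov.severity_slope * z_sev)
        md.loc[case_ids, "laryngeal_edema"] = rng.random(len(case_ids)) < p_lar
        md.loc[case_ids, "gi_edema"] = rng.random(len(case_ids)) < p_gi
        md.loc[case_ids, "severity_score"] = rng.binomial(7, p_sev)
        md.loc[case_ids, "c4_g_l"] = np.exp(
            np.log(cov.c4_case_median) + cov.c4_log_sd * rng.standard_normal(len(case_ids)))
        md.loc[case_ids, "c1inh_g_l"] = np.exp(
            np.log(cov.c1inh_case_median) + cov.c1inh_slope * z_c1.to_numpy()
            + cov.c1inh_log_sd * rng.standard_normal(len(case_ids)))
    hc_ids = md.index[md["group"] == GROUP_HC]
    if len(hc_ids):
        md.loc[hc_ids, "c4_g_l"] = np.exp(
            np.log(cov.c4_control_median) + cov.c4_log_sd * rng.standard_normal(len(hc_ids)))
        md.loc[hc_ids, "c1inh_g_l"] = np.exp(
            np.log(cov.c1inh_control_median)
            + cov.c1inh_log_sd * rng.standard_normal(len(hc_ids)))
    return md.reset_index()


def _ground_truth(group_means, effects, truth_traits, metadata, registry) -> GroundTruth:
    md = metadata.set_index("sample_id")
    case = truth_traits.loc[md.index[md["group"] == GROUP_UNTREATED]]
    ctrl = truth_traits.loc[md.index[md["group"] == GROUP_HC]]
    shifts = {}
    for eff in effects:
        pooled_sd = float(pd.concat([case[eff.trait], ctrl[eff.trait]]).std(ddof=1))
        if pooled_sd == 0 or len(case) == 0 or len(ctrl) == 0:
            shifts[eff.trait] = float("nan")
        else:
            shifts[eff.trait] = float(
                (case[eff.trait].mean() - ctrl[eff.trait].mean()) / pooled_sd)
    # traits whose true group means are (numerically) identical
    mean_traits_u = compute_all(group_means[[GROUP_UNTREATED]].T, registry).iloc[0]
    mean_traits_h = compute_all(group_means[[GROUP_HC]].T, registry).iloc[0]
    rel = (mean_traits_u - mean_traits_h).abs() / mean_traits_h.abs().clip(lower=1e-12)
    null_traits = sorted(rel.index[rel < 1e-9])
    return GroundTruth(group_means=group_means, effects=tuple(effects),
                       trait_shifts=pd.Series(shifts), null_traits=null_traits)


def render_spectrum(abundances, registry: CompositionRegistry,
                    instrument: InstrumentModel, seed: int | None = None,
                    sample_id: str | None = None,
                    drift_coefficients=None) -> Spectrum:
    """Render a simplex abundance vector as a profile MALDI-TOF spectrum.

    Isotopologue peaks are placed at the drifted theoretical sodiated m/z
    with Gaussian profiles (FWHM = m/z / resolving power); peak areas are
    proportional to abundance x isotopologue fraction x intensity scale.
    An exponential baseline and white noise are added.  Compositions whose
    monoisotopic m/z falls outside the range are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    a = pd.Series(abundances).reindex(registry.codes)
    if a.isna().any():
        raise ValueError("abundance vector must cover the registry")
    grid = instrument.grid()
    y = np.zeros_like(grid)
    if drift_coefficients is None:
        jit = instrument.drift_jitter_ppm
        drift_coefficients = tuple(
            c + rng.normal(0.0, s) for c, s in zip(instrument.drift_ppm, jit))
    scale = instrument.intensity_scale * float(
        np.exp(rng.normal(0.0, instrument.scale_cv))) if instrument.scale_cv > 0 \
        else instrument.intensity_scale
    for rec in registry:
        mz0 = rec.mass_sodiated
        if not instrument.mz_min <= mz0 <= instrument.mz_max:
            import warnings
            warnings.warn(f"{rec.code}: m/z {mz0:.2f} outside instrument range; "
                          f"peak skipped", stacklevel=2)
            continue
        formula = molecular_formula(rec.composition)
        k = min_isotopologues(formula)
        dist = isotopic_distribution(formula, k)
        for i in range(k):
            mz_i = mz0 + i * ISOTOPE_SPACING
            mz_obs = mz_i * (1.0 + instrument.drift_at(mz_i, drift_coefficients) / 1e6)
            sigma = mz_obs / instrument.resolving_power / 2.3548
            area = float(a[rec.code]) * dist[i] * scale
            amp = area / (sigma * math.sqrt(2.0 * math.pi))
            lo = np.searchsorted(grid, mz_obs - 6 * sigma)
            hi = np.searchsorted(grid, mz_obs + 6 * sigma)
            if hi > lo:
                g = grid[lo:hi]
                y[lo:hi] += amp * np.exp(-0.5 * ((g - mz_obs) / sigma) ** 2)
    if instrument.baseline_amplitude > 0:
        y += instrument.baseline_amplitude * np.exp(
            -(grid - instrument.mz_min) / instrument.baseline_decay)
    if instrument.noise_sd > 0:
        y += rng.normal(0.0, instrument.noise_sd, grid.size)
    return Spectrum(grid, y, sample_id=sample_id)


def two_cohort_study(discovery: CohortDesign | None = None,
                     validation: CohortDesign | None = None,
                     registry: CompositionRegistry | None = None,
                     instrument: InstrumentModel | None = None,
                     render: bool = False, seed: int = 0) -> dict:
    """Simulate a discovery + validation cohort pair sharing one design
    of planted effects (independent noise draws)."""
    if registry is None:
        registry = CompositionRegistry.default()
    if discovery is None:
        discovery = CohortDesign(label="discovery")
    if validation is None:
        validation = CohortDesign(n_untreated=18, n_treated=30, n_hc=40,
                                  label="validation", effects=discovery.effects)
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(2))
    return {
        "discovery": simulate_cohort(discovery, registry, instrument=instrument,
                                     render=render, seed=s1),
        "validation": simulate_cohort(validation, registry, instrument=instrument,
                                      render=render, seed=s2),
    }
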