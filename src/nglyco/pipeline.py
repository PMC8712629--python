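"""End-to-end orchestration: simulate -> preprocess -> recalibrate ->
discover -> extract -> curate -> normalize -> traits -> statistics ->
biomarker models, as a seeded, logged, reproducible run.

Every stage consumes and produces plain-text tables, so stages are also
runnable independently (see :mod:`nglyco.cli`).  A run manifest records
the package and library versions, the configuration hash and the seed;
re-running with the same configuration and seed reproduces every numeric
output bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .extract import (CURATION_GROUPS, curate, extract_cohort,
                      measurements_to_wide, normalize)
from .mccv import apply_model, fit_final_model, mccv_evaluate
from .process import (CalibrationError, default_calibrants, discover_compositions,
                      preprocess, recalibrate, sum_spectra)
from .registry import CompositionRegistry, DEFAULT_TRAIT_NAMES
from .sim import (GROUP_HC, GROUP_QC, GROUP_TREATED, GROUP_UNTREATED,
                  default_baseline, simulate_cohort)
from .stats import (associate, mwu_compare, replicate_filter, roc_single,
                    treatment_response)
from .traits import compute_all, load_trait_registry

logger = logging.getLogger(__name__)

__all__ = ["CohortResult", "PipelineReport", "process_cohort", "run_pipeline"]


@dataclass
class CohortResult:
    """All per-cohort pipeline products."""

    name: str
    metadata: pd.DataFrame
    discovery: pd.DataFrame
    measurements: pd.DataFrame
    curation_report: pd.DataFrame
    retained: list
    abundance: pd.DataFrame
    traits: pd.DataFrame
    comparisons: dict = field(default_factory=dict)   # pair-name -> DataFrame
    calibration_failures: list = field(default_factory=list)
    truth: object = None


@dataclass
class PipelineReport:
    cohorts: dict
    replicated: list
    response: pd.DataFrame | None
    associations: pd.DataFrame | None
    roc_table: pd.DataFrame | None
    mccv_discovery: object = None
    mccv_validation: tuple | None = None   # (auc, accuracy)
    manifest: dict = field(default_factory=dict)


def _load_registry(config: PipelineConfig) -> CompositionRegistry:
    if config.registry_path:
        return CompositionRegistry.from_table(config.registry_path)
    return CompositionRegistry.default()


def _trait_names(config: PipelineConfig):
    if config.trait_registry_path:
        return load_trait_registry(config.trait_registry_path)
    return DEFAULT_TRAIT_NAMES


def process_cohort(name: str, dataset, config: PipelineConfig,
                   registry: CompositionRegistry,
                   trait_names=None) -> CohortResult:
    """Run the per-cohort processing chain on a rendered dataset."""
    t = config.thresholds
    calib = config.calibration
    baseline = default_baseline(registry)
    calibrants = default_calibrants(registry, baseline.to_dict(),
                                    n=calib.n_calibrants)
    groups = dataset.metadata.set_index("sample_id")["group"]

    calibrated, failures = {}, []
    group_sums: dict = {}
    grid = config.instrument.grid()
    for sid, spec in dataset.spectra.items():
        pre = preprocess(spec)
        try:
            cal = recalibrate(pre, calibrants, ppm_window=calib.ppm_window,
                              min_calibrants=calib.min_calibrants,
                              degree=calib.degree, snr_min=calib.snr_min)
        except CalibrationError as exc:
            logger.warning("%s", exc)
            failures.append(sid)
            continue
        calibrated[sid] = cal
    if len(failures) > config.calibration.max_failure_fraction * len(dataset.spectra):
        raise RuntimeError(
            f"{name}: calibration failed for {len(failures)}/{len(dataset.spectra)} "
            f"spectra; aborting run")

    # summed spectra per biological group drive candidate discovery
    for grp in (GROUP_UNTREATED, GROUP_TREATED, GROUP_HC, GROUP_QC):
        members = [calibrated[s] for s in calibrated
                   if groups.get(s) == grp]
        if members:
            group_sums[grp] = sum_spectra(members, grid)
    disc_frames = []
    for grp, summed in group_sums.items():
        d = discover_compositions(
            summed, ppm_tol=t.ppm_match, snr_min=t.snr_discovery,
            rel_int_min=t.rel_int,
            resolving_power=config.extraction.resolving_power)
        d["group"] = grp
        disc_frames.append(d)
    discovery = (pd.concat(disc_frames, ignore_index=True)
                 if disc_frames else pd.DataFrame())

    if config.target_source == "discovered":
        # isotopic-pattern gate removes isotopologue shadows of strong peaks
        good = (set(discovery.loc[discovery["qc_score"] < t.qc, "code"])
                if not discovery.empty else set())
        codes = [c for c in registry.codes if c in good]
        if not codes:
            logger.warning("%s: discovery found no registry composition; "
                           "falling back to the registry list", name)
            codes = registry.codes
    else:
        codes = registry.codes

    measurements = extract_cohort(calibrated, codes, registry, config.extraction)
    report = curate(measurements, groups.loc[list(calibrated)],
                    thresholds=config.curation_thresholds,
                    mode=t.presence_mode)
    areas = measurements_to_wide(measurements)[report.retained]
    abundance = normalize(areas)
    traits = compute_all(abundance, registry,
                         trait_names or _trait_names(config))

    comparisons = {}
    tr_groups = groups.reindex(traits.index)
    pairs = [("untreated_vs_hc", GROUP_UNTREATED, GROUP_HC),
             ("treated_vs_hc", GROUP_TREATED, GROUP_HC),
             ("untreated_vs_treated", GROUP_UNTREATED, GROUP_TREATED)]
    m = traits.shape[1]
    for key, a, b in pairs:
        if (tr_groups == a).sum() >= 2 and (tr_groups == b).sum() >= 2:
            comparisons[key] = mwu_compare(traits, tr_groups, a, b,
                                           alpha=t.alpha, m=m)
    return CohortResult(name=name, metadata=dataset.metadata,
                        discovery=discovery, measurements=measurements,
                        curation_report=report.report, retained=report.retained,
                        abundance=abundance, traits=traits,
                        comparisons=comparisons, calibration_failures=failures,
                        truth=dataset.truth)


def _associations(result: CohortResult, alpha: float) -> pd.DataFrame:
    """Per-trait clinical associations within the case group."""
    md = result.metadata.set_index("sample_id")
    cases = md.index[md["group"].isin([GROUP_UNTREATED, GROUP_TREATED])]
    cases = cases.intersection(result.traits.index)
    rows = []
    outcomes = [("laryngeal_edema", "logistic"), ("gi_edema", "logistic"),
                ("severity_score", "linear"), ("c1inh_g_l", "linear"),
                ("c4_g_l", "linear")]
    for outcome, kind in outcomes:
        if outcome not in md.columns:
            continue
        y = pd.to_numeric(md.loc[cases, outcome], errors="coerce")
        if y.dropna().nunique() < 2:
            continue
        for trait in result.traits.columns:
            v = result.traits.loc[cases, trait]
            if v.dropna().nunique() < 3:
                continue
            try:
                res = associate(v, y, kind, trait_name=trait, outcome_name=outcome)
            except ValueError:
                continue
            rows.append({"cohort": result.name, "trait": trait,
                         "outcome": outcome, "kind": kind,
                         "estimate": res.estimate, "p": res.p_value,
                         "converged": res.converged, "n": res.n})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineReport:
    """Simulate the configured cohorts and run the full analysis chain."""
    config.validate()
    registry = _load_registry(config)
    trait_names = _trait_names(config)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.cohorts))

    results: dict = {}
    for (name, design), child in zip(config.cohorts.items(), children):
        seed = int(child.generate_state(1)[0] % (2 ** 31 - 1))
        dataset = simulate_cohort(design, registry, instrument=config.instrument,
                                  render=True, seed=seed)
        results[name] = process_cohort(name, dataset, config, registry,
                                       trait_names)
        logger.info("cohort %s: %d retained compositions, %d traits",
                    name, len(results[name].retained),
                    results[name].traits.shape[1])

    names = list(results)
    replicated: list = []
    if len(names) >= 2:
        r1 = results[names[0]].comparisons.get("untreated_vs_hc")
        r2 = results[names[1]].comparisons.get("untreated_vs_hc")
        if r1 is not None and r2 is not None:
            replicated = replicate_filter(r1, r2)

    response = None
    first = results[names[0]]
    needed = {"untreated_vs_hc", "untreated_vs_treated", "treated_vs_hc"}
    if needed <= set(first.comparisons):
        response = treatment_response(first.comparisons["untreated_vs_hc"],
                                      first.comparisons["untreated_vs_treated"],
                                      first.comparisons["treated_vs_hc"],
                                      alpha=config.thresholds.alpha)

    associations = pd.concat([_associations(r, config.thresholds.alpha)
                              for r in results.values()], ignore_index=True)

    roc_rows = []
    for name, res in results.items():
        groups = res.metadata.set_index("sample_id")["group"].reindex(res.traits.index)
        case_ctrl = groups.isin([GROUP_UNTREATED, GROUP_HC])
        labels = groups[case_ctrl]
        for trait in replicated:
            try:
                roc = roc_single(res.traits.loc[labels.index, trait], labels,
                                 positive=GROUP_UNTREATED)
            except ValueError:
                continue
            roc_rows.append({"cohort": name, "trait": trait, "outcome": "HAE-vs-HC",
                             "auc": roc.auc, "cutoff": roc.cutoff,
                             "sensitivity": roc.sensitivity,
                             "specificity": roc.specificity})
    roc_table = pd.DataFrame(roc_rows)

    mccv_result, external = None, None
    model_traits = replicated if len(replicated) >= 2 else []
    if model_traits:
        disc = results[names[0]]
        groups = disc.metadata.set_index("sample_id")["group"].reindex(disc.traits.index)
        mask = groups.isin([GROUP_UNTREATED, GROUP_HC])
        X = disc.traits.loc[mask, model_traits]
        y = groups[mask]
        mccv_cfg = dataclasses.replace(config.mccv, seed=config.seed)
        mccv_result = mccv_evaluate(X, y, mccv_cfg, positive=GROUP_UNTREATED)
        if len(names) >= 2:
            order = mccv_result.selection_frequency[mccv_result.best_size]
            feats = order.sort_values(ascending=False).index[:mccv_result.best_size]
            final = fit_final_model(X, y, feats, positive=GROUP_UNTREATED)
            val = results[names[1]]
            vgroups = val.metadata.set_index("sample_id")["group"].reindex(val.traits.index)
            vmask = vgroups.isin([GROUP_UNTREATED, GROUP_HC])
            _, vauc, vacc = apply_model(final, val.traits.loc[vmask, model_traits],
                                        vgroups[vmask])
            external = (vauc, vacc)

    manifest = {
        "package": "nglyco",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "replicated_traits": replicated,
    }
    report = PipelineReport(cohorts=results, replicated=replicated,
                            response=response, associations=associations,
                            roc_table=roc_table, mccv_discovery=mccv_result,
                            mccv_validation=external, manifest=manifest)
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: PipelineReport, outdir) -> None:
    """Write every pipeline product as TSV plus a JSON manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, res in report.cohorts.items():
        d = out / name
        d.mkdir(exist_ok=True)
        res.metadata.to_csv(d / "metadata.tsv", sep="\t", index=False)
        res.discovery.to_csv(d / "discovery.tsv", sep="\t", index=False)
        res.measurements.to_csv(d / "extraction.tsv", sep="\t", index=False)
        res.curation_report.to_csv(d / "curation_report.tsv", sep="\t", index=False)
        res.abundance.to_csv(d / "abundance.tsv", sep="\t")
        res.traits.to_csv(d / "traits.tsv", sep="\t")
        for key, cmp_df in res.comparisons.items():
            cmp_df.to_csv(d / f"comparison_{key}.tsv", sep="\t")
    pd.Series(report.replicated, name="trait").to_csv(
        out / "replicated_traits.tsv", sep="\t", index=False)
    if report.response is not None:
        report.response.to_csv(out / "treatment_response.tsv", sep="\t")
    if report.associations is not None:
        report.associations.to_csv(out / "associations.tsv", sep="\t", index=False)
    if report.roc_table is not None:
        report.roc_table.to_csv(out / "roc_single_trait.tsv", sep="\t", index=False)
    if report.mccv_discovery is not None:
        sweep = report.mccv_discovery
        pd.DataFrame({"size": list(sweep.sizes),
                      "auc": [sweep.auc[k] for k in sweep.sizes],
                      "accuracy": [sweep.accuracy[k] for k in sweep.sizes]}
                     ).to_csv(out / "mccv_model_sweep.tsv", sep="\t", index=False)
        sweep.selection_frequency.to_csv(out / "mccv_selection_frequency.tsv", sep="\t")
        rows = []
        for k, (fpr, tpr) in sweep.roc.items():
            for f, t in zip(fpr, tpr):
                rows.append({"size": k, "fpr": f, "tpr": t})
        pd.DataFrame(rows).to_csv(out / "mccv_roc_points.csv", index=False)
        if report.mccv_validation is not None:
            vauc, vacc = report.mccv_validation
            pd.DataFrame([{"auc": vauc, "accuracy": vacc}]).to_csv(
                out / "mccv_validation.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True, default=str)
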