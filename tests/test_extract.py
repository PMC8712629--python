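"""Targeted extraction, quality scoring, curation cascade, normalization."""

import numpy as np
import pandas as pd
import pytest

from nglyco.chem import (ISOTOPE_SPACING, isotopic_distribution,
                         min_isotopologues, molecular_formula)
from nglyco.extract import (CurationThresholds, ExtractionParams, curate,
                            extract_analyte, extract_cohort,
                            measurements_to_wide, normalize)
from nglyco.process import preprocess
from nglyco.sim import render_spectrum
from nglyco.spectrum import Spectrum


@pytest.fixture(scope="module")
def clean_spectrum(registry, baseline, clean_instrument):
    spec = render_spectrum(baseline, registry, clean_instrument, seed=0)
    return preprocess(spec).copy_with(calibrated=True, sample_id="s1")


def test_noise_free_extraction_matches_rendered_truth(registry, baseline,
                                                      clean_spectrum):
    for code in ("H5N4E2", "H5N2", "H6N5E3", "H7N6E4"):
        m = extract_analyte(clean_spectrum, code, registry)
        expected = baseline[code] * 5e4      # abundance x intensity scale
        assert m.present
        assert m.area == pytest.approx(expected, rel=0.06)
        assert m.qc_score < 0.02
        assert abs(m.ppm_error) < 5.0


def test_absent_analyte_reports_not_present(registry, clean_instrument):
    a = pd.Series(0.0, index=registry.codes)
    a["H5N4E2"] = 1.0
    spec = preprocess(render_spectrum(a, registry, clean_instrument, seed=0))
    m = extract_analyte(spec.copy_with(calibrated=True), "H9N2", registry)
    assert not m.present and m.area == 0.0


def test_wrong_isotope_pattern_flagged_by_qc_score(registry, clean_instrument):
    """An analyte rendered with a much heavier formula's envelope at the
    position of a light glycan must exceed the 25% QC cut-off."""
    target = registry["H3N4"]
    heavy = molecular_formula(registry["H7N6E4"].composition)
    k = min_isotopologues(heavy)
    dist = isotopic_distribution(heavy, k)
    grid = clean_instrument.grid()
    y = np.zeros_like(grid)
    sigma = target.mass_sodiated / clean_instrument.resolving_power / 2.3548
    for i in range(k):
        c = target.mass_sodiated + i * ISOTOPE_SPACING
        y += (1000.0 * dist[i] / (sigma * np.sqrt(2 * np.pi))
              * np.exp(-0.5 * ((grid - c) / sigma) ** 2))
    spec = Spectrum(grid, y, sample_id="adv", calibrated=True)
    m = extract_analyte(spec, "H3N4", registry)
    theo = isotopic_distribution(molecular_formula(target.composition),
                                 min_isotopologues(molecular_formula(target.composition)))
    assert m.present
    assert m.qc_score > 0.25
    # hand oracle: L1 distance between the two (renormalized) envelopes
    kk = min(len(theo), k)
    hand = np.abs(dist[:kk] / dist[:kk].sum() - theo[:kk] / theo[:kk].sum()).sum()
    assert m.qc_score == pytest.approx(hand, abs=0.08)


def _toy_measurements():
    """5 compositions x 6 samples (2 per group); C4 and C5 fail only ppm."""
    rows = []
    samples = {"u1": "untreated-HAE", "u2": "untreated-HAE",
               "h1": "HC", "h2": "HC", "q1": "QC", "q2": "QC"}
    for code in ("C1", "C2", "C3", "C4", "C5"):
        for sid in samples:
            ppm = 25.0 if code in ("C4", "C5") else 2.0
            rows.append({"sample_id": sid, "code": code, "area": 10.0,
                         "snr": 50.0, "ppm_error": ppm, "qc_score": 0.05,
                         "present": True})
    return pd.DataFrame(rows), pd.Series(samples)


def test_curation_counts_hand_fixture():
    meas, groups = _toy_measurements()
    rep = curate(meas, groups)
    assert rep.retained == ["C1", "C2", "C3"]
    assert set(rep.report.columns) >= {"presence_HAE", "presence_HC",
                                       "presence_QC", "deciding_group"}


def test_any_group_rule_keeps_qc_only_composition():
    meas, groups = _toy_measurements()
    # C1 present only in QC samples
    meas.loc[(meas.code == "C1") & ~meas.sample_id.str.startswith("q"),
             "present"] = False
    rep_any = curate(meas, groups, mode="any")
    rep_all = curate(meas, groups, mode="all")
    assert "C1" in rep_any.retained
    assert "C1" not in rep_all.retained


def test_impossible_thresholds_empty_but_complete_report():
    meas, groups = _toy_measurements()
    rep = curate(meas, groups, thresholds=CurationThresholds(snr=np.inf))
    assert rep.retained == []
    assert len(rep.report) == 5


def test_unknown_group_label_rejected():
    meas, groups = _toy_measurements()
    groups["u1"] = "mystery"
    with pytest.raises(ValueError, match="unknown group"):
        curate(meas, groups)


def test_curation_monotone_in_thresholds():
    rng = np.random.default_rng(0)
    rows = []
    groups = {}
    for i in range(12):
        sid = f"s{i}"
        groups[sid] = ["untreated-HAE", "HC", "QC"][i % 3]
        for code in "ABCDEFG":
            rows.append({"sample_id": sid, "code": code,
                         "area": rng.uniform(0, 10),
                         "snr": rng.uniform(0, 40),
                         "ppm_error": rng.uniform(-40, 40),
                         "qc_score": rng.uniform(0, 0.6),
                         "present": bool(rng.random() < 0.9)})
    meas = pd.DataFrame(rows)
    loose = curate(meas, groups, CurationThresholds(snr=5, ppm=30, qc=0.4,
                                                    presence=0.3))
    for tighter in (CurationThresholds(snr=15, ppm=30, qc=0.4, presence=0.3),
                    CurationThresholds(snr=5, ppm=10, qc=0.4, presence=0.3),
                    CurationThresholds(snr=5, ppm=30, qc=0.1, presence=0.3),
                    CurationThresholds(snr=5, ppm=30, qc=0.4, presence=0.7)):
        assert set(curate(meas, groups, tighter).retained) <= set(loose.retained)


def test_normalize_rows():
    areas = pd.DataFrame([[2.0, 3.0, 5.0], [1.0, 1.0, 2.0]],
                         index=["a", "b"], columns=["x", "y", "z"])
    out = normalize(areas)
    assert out.loc["a"].tolist() == [0.2, 0.3, 0.5]
    assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)


def test_normalize_drops_zero_rows_and_rejects_negative():
    areas = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["a", "b"],
                         columns=["x", "y"])
    out = normalize(areas)
    assert list(out.index) == ["a"]
    with pytest.raises(ValueError):
        normalize(pd.DataFrame([[-1.0, 2.0]], columns=["x", "y"]))


def test_normalized_abundance_invariant_to_intensity_scaling(registry, baseline,
                                                             clean_instrument):
    """Scaling a sample's raw spectrum 10x leaves the normalized row
    unchanged (end-to-end through rendering and extraction)."""
    import dataclasses
    inst10 = dataclasses.replace(clean_instrument,
                                 intensity_scale=clean_instrument.intensity_scale * 10)
    specs = {}
    for name, inst in (("s1", clean_instrument), ("s10", inst10)):
        spec = render_spectrum(baseline, registry, inst, seed=0)
        specs[name] = preprocess(spec).copy_with(calibrated=True, sample_id=name)
    meas = extract_cohort(specs, registry.codes, registry)
    wide = measurements_to_wide(meas)
    out = normalize(wide)
    np.testing.assert_allclose(out.loc["s1"].to_numpy(),
                               out.loc["s10"].to_numpy(), rtol=1e-3)
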