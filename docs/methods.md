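# Methods

This note documents the models, parameter choices and numerical decisions
behind `nglyco`, and what the synthetic-data tests do and do not establish
about real data.

## 1. Mass model of derivatized N-glycans

Compositions are vectors over five residue letters with fixed elemental
formulas: hexose C6H10O5, N-acetylhexosamine C8H13NO5, deoxyhexose
C6H10O4, lactonized α2,3-linked N-acetylneuraminic acid C11H15NO7, and
ethyl-esterified α2,6-linked N-acetylneuraminic acid C13H21NO8.  The
derivatization chemistry is encoded purely as formula deltas on the NeuAc
residue (lactone −H2O, ethyl ester +C2H4); no attempt is made to model the
reactions themselves.  A neutral glycan is the residue sum plus one
terminal water; the sodium adduct adds m(Na) − m(e⁻) = 22.989221 Da.
Atomic masses are CODATA/IUPAC monoisotopic values; masses agree with an
independent atom-sum oracle (pyteomics) to < 1e-8 Da.

Isotopic envelopes are computed by polynomial convolution of per-element
isotope distributions, using exponentiation-by-squaring with truncation at
the requested number of isotopologues.  The default isotopologue count per
analyte is the smallest k whose cumulative theoretical abundance reaches
95%.  On small formulas the convolution matches brute-force enumeration
over all isotope placements to 1e-12.

### Structure rules

Composition alone cannot determine topology, so structural features are
inferred by rule with a per-composition annotation table for the genuinely
ambiguous cases:

* high-mannose iff N = 2 and F = L = E = 0;
* hybrid iff N = 3 and H ≥ 5;
* otherwise complex with antennae = min(N − 2, 4), or N − 3 when the
  registry marks the composition bisected, and antenna galactoses
  = max(0, min(H − 3, antennae)).

Bisection is registry-annotated only (here: the low-hexose N5 series).
A complex composition whose sialic acids exceed its galactoses is accepted
with a warning; counts are retained.

## 2. Composition and trait registries

The default composition registry is a 58-entry plasma-convention panel
(high-mannose series, sialylated hybrids, di/tri/tetra-antennary complex
glycans with fucosyl- and linkage-specific sialyl-variants, bisected
diantennary series) spanning m/z 1257–3670 as [M+Na]⁺.  Four minor
compositions whose masses collide with far more abundant panel members to
within 16 ppm (the +H1N1L1 ≈ +E2 coincidence, Δ ≈ 0.036 Da) are excluded:
at the modeled resolving power they cannot be distinguished from their
partners and would only report the partner's area.  The registry
round-trips through TSV (`code`, `class`, `bisected`, `include`) so a
curated list can replace it.

The trait registry is a list of 82 names enumerated from the trait grammar
(per-antenna and per-galactose degrees, presence fractions and abundance
fractions over di/tri/tetra-antennary, fucosyl-split and class-level
subsets).  The engine is grammar-driven, so the registry is editable text;
a line of the form `name = CODES / CODES` overrides a name with an
explicit sum-ratio formula.  Undefined values (zero-abundance denominator
subset) propagate as missing and are dropped pairwise in statistics — no
imputation.

## 3. Synthetic studies

`nglyco.sim` generates a two-cohort case/control study and is itself part
of the tested surface.

**Abundances.** Per-sample composition abundances are logistic-normal:
softmax of log(group mean) plus correlated Gaussian noise (exchangeable
correlation, default ρ = 0.3; biological log-SD 0.12; technical log-SD
0.035 applied to every spectrum including the QC replicates of a plasma
standard).  The softmax keeps samples on the simplex, and zero noise
reproduces the mean exactly.

**Planted effects.** A group effect multiplies the numerator compositions
of a targeted derived trait and renormalizes — the simplest mechanism that
moves a ratio trait predictably.  This moves fraction-type traits and
degree traits whose numerator members are a minority of their subset; a
saturated degree (e.g. A4G, which is 1.0 in the default panel) cannot be
moved this way.  The default effect set targets eight traits spanning
antennarity, α2,3-sialylation, fucosylation and bisection (CA4↓, CA3↑,
A4L↑, A3L↑, A3F↑, A2F0L↓, TA2FS0↓, A2B↑), with factors chosen once so the
realized standardized shifts are ≈ 1–1.4 SD under the default
variability.  Six of the eight respond to therapy in the treated group
(residual 0.15 of the log-effect); TA2FS0 and A2B are unresponsive.  The
ground-truth record stores the group means, the realized shifts and the
list of traits whose true group means are identical (the honest "null"
set — traits structurally correlated with a planted one are *not* null).

**Covariates.** Within cases, laryngeal edema is Bernoulli with a
logistic link on the standardized A2G (positive), gastrointestinal edema
on A2F0L (negative), and the 0–7 severity score is Binomial(7, p) with a
logistic p on A2G.  C4 and C1-INH levels are log-normal around
disease-typical medians (cases 0.078/0.080 g/l, controls 0.25/0.30 g/l),
C1-INH tilted by A3F.  These links mirror the association structure the
statistics stage is meant to detect without copying any coefficients.

**Rendering.** Each isotopologue peak is a Gaussian at the drifted
theoretical sodiated m/z, FWHM = m/z / R with R = 15000, area proportional
to abundance × isotopologue fraction × intensity scale (5e4 total area,
per-sample log-normal spread 0.2).  Calibration drift is a quadratic in
m/z on the ppm scale with per-sample jitter (SD 15/5/3 ppm per
coefficient); an exponential baseline (amplitude 50, decay 1500 Da) and
white noise (SD 5) are added on a uniform grid (default 1000–5000 m/z,
step 0.01).  Not emulated: ionization suppression, detector saturation,
isotope-resolved peak-shape asymmetry, batch/acquisition-order drift.
Passing tests therefore demonstrate correctness of the computational
chain under a well-specified forward model, not robustness to every
artifact of real MALDI-TOF data.

## 4. Spectrum processing

Baseline: moving minimum followed by moving average (window 10 Da),
then a blockwise-median re-centering — the moving minimum sits ~3 noise
SD below the true background, and the re-centering restores signal-free
regions to zero (which the S/N estimator assumes).  Smoothing:
Savitzky-Golay, window 7 points, order 2.  Noise: 1.4826 × median
absolute deviation in 5-Da blocks, interpolated per point; the cut-off
names follow the common S/N convention but the estimator itself is a
package choice.  Peak apexes are refined by 3-point parabolic
interpolation on the (possibly non-uniform) axis.

Recalibration fits a degree-2 polynomial of observed→theoretical m/z over
internal calibrants — by default the most abundant registry composition
in each of 8 equal mass bins — requiring ≥ 4 matches within 200 ppm;
failures flag the spectrum and exclude it downstream (a run aborts if
more than 20% of spectra fail).  The axis transform leaves intensities
untouched; areas integrate trapezoidally on the transformed axis, which
conserves area without an explicit Jacobian factor.  Planted drifts
within ±100 ppm are corrected to mean |ppm| < 2 on held-out analytes.

Candidate discovery on group-summed spectra gates peaks at S/N > 3 and
relative intensity > 0.1% of the base peak, then matches each peak to the
candidate composition (search bounds H ≤ 9, N ≤ 7, F ≤ 3, L+E ≤ 4,
chemical-plausibility filtered) with smallest |ppm| within 20 ppm; exact
ties resolve toward the lower mass and are logged.  The isotopic-pattern
score computed for each match removes isotopologue shadows of strong
peaks when the discovered list is used as the extraction target.

## 5. Targeted extraction and curation

Per analyte, isotopologue windows at theoretical m/z + i × 1.00336 are
integrated after subtracting a local linear background interpolated
between the flanking minima of each window; the summed area covers the
≥ 95% envelope.  The QC score is the L1 distance between observed and
theoretical isotopologue fractions (range 0–2, reported against a 25%
cut-off); the ppm error is signed, from the parabola-refined monoisotopic
apex.  An analyte with no apex above twice the local noise (or outside
the 50-ppm presence gate) is recorded absent with zero area.

Curation retains a composition when S/N > 9, |ppm| < 20 and QC < 25%
hold jointly in more than 50% of the spectra of at least one of the HAE
(treated + untreated), HC or QC groups.  The "any-group" reading of the
presence rule is the default — it is the established convention of this
curation scheme — with the stricter all-groups variant available as
`mode="all"`.  Retained areas are row-normalized to one; all-zero samples
are excluded with a log entry.  On a noise-free rendered cohort the
normalized matrix reproduces the true abundances to < 0.1% per entry.

## 6. Statistics

Rank-sum comparisons use the exact null distribution for combined
n ≤ 25 without ties, otherwise the normal approximation with tie and
continuity correction; a comparison with no rank information returns
p = 1.  The significance threshold is α/m (default 0.05/82 = 6.10E-4).
Replication requires significance in both cohorts with the same
direction of the median difference — sign-discordant "replication" is
biologically meaningless and is excluded by construction.  Treatment
response is a reconstruction with explicit thresholds: responsive iff
untreated-vs-HC significant at α/m, untreated-vs-treated p < 0.05 (raw),
and treated-vs-HC not significant at α/m.

Associations are per-trait logistic (binary flags) or linear (severity,
C4, C1-INH) regressions on the standardized trait, unadjusted and without
multiple-testing correction, mirroring how such screens are usually
presented; complete separation is reported as non-convergence, not as an
estimate.  Single-trait ROC is empirical with trapezoidal AUC, oriented
so AUC ≥ 0.5 (orientation recorded), with the Youden-J cut-off; the AUC
equals the rank-sum U/(n1·n2) identically.

Family-wise error at the Bonferroni threshold, measured over 500
simulated null studies of 82 traits, is ≈ 0.01–0.02 — conservative, as
expected from Bonferroni plus the discreteness of the rank-sum test.

## 7. MCCV-SVM biomarker models

Each of the (default 100) runs draws a class-balanced subsample without
replacement, trains on 2/3 and validates on 1/3.  Feature importance is
the absolute weight of a linear SVM (C = 1) on train-standardized traits,
recomputed inside every run so no information leaks from the held-out
third; ties break by univariate AUC, then input order.  One SVM per model
size (default {2,3,5,8} capped at the trait count) is fitted on the
top-ranked traits; class probabilities come from a logistic calibration
of the SVM decision values fitted on the training fold.  Held-out
probabilities are averaged per sample across runs; the averaged ROC/AUC
and the accuracy at the 0.5 probability boundary summarize each size.
With balanced subsampling the boundary is 0.5 by symmetry: flipping every
label maps each averaged probability p to 1 − p (verified to < 0.01,
limited only by solver tolerances).  A linear kernel is the default
because weight-based importance requires it; the run count and cost
parameter are conventional choices for this design.  For external
validation the selected-feature model is refit on the whole discovery
cohort and applied unchanged to the validation cohort.

A subtlety worth knowing: under the null (permuted labels) the AUC of
averaged held-out probabilities is highly variable across datasets
(≈ 0.25–0.65 at n = 60) with the usual slight pessimism of
cross-validation; its mean over permutations sits at 0.5 − ε.

## 8. Problem sizes used by the tests and the acceptance script

Oracle and identity checks run at full precision in under a second.
Simulation-based checks use: 3 + 3 samples for noise-free extraction
fidelity; 500 studies × 82 traits (n = 20/group) for the family-wise
error rate; two cohorts of 100 + 100 (true-abundance route) for the
univariate replication property, where ≈1-SD shifts have essentially
full Bonferroni power; and two rendered cohorts of 40 + 40 (+4 QC) for
the end-to-end biomarker study, where the model sweep and the
transferred final model both reach AUC ≥ 0.9.  At 40 + 40 the per-trait
Bonferroni power for a 1-SD shift is only ≈ 0.8, so univariate recovery
of all eight planted traits in both cohorts is not expected at that size
— the multivariate models are the appropriate instrument there.

## 9. Known limitations

* Structure inference from composition is heuristic; isomers and
  uncommon topologies (e.g. LacdiNAc, antenna-fucosylation) are outside
  the rule set and would need registry annotations.
* The trait registry is a conventional enumeration, not a transcription
  of any published formula table; explicit overrides exist for exactness.
* The forward model omits suppression, saturation and batch effects, so
  quantitative fidelity results are upper bounds on real-data behaviour.
* Association models are unadjusted (no age/sex covariates) by default.
* Profile-mode spectra only; centroided input is not supported.
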