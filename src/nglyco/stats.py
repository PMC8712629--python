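"""Univariate screening, cross-cohort replication, clinical association,
single-trait ROC and treatment-response classification.

Group comparisons of derived traits use the two-sided
Mann-Whitney-Wilcoxon rank-sum test (glycan trait distributions are
typically non-normal), with the significance threshold Bonferroni-adjusted
to alpha / m for m traits (0.05 / 82 = 6.10E-4 for the default registry).
A trait *replicates* when it is significant in both cohorts with the same
direction of change.  Associations with clinical covariates are per-trait
logistic (binary outcome) or linear (continuous outcome) regressions on
the standardized trait.  Single-trait diagnostic performance is the
empirical ROC; its AUC obeys the rank-sum identity AUC = U / (n1 * n2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = ["bonferroni_threshold", "mwu_compare", "replicate_filter",
           "AssociationResult", "associate", "RocResult", "roc_single",
           "treatment_response"]


def bonferroni_threshold(alpha: float = 0.05, m: int = 82) -> float:
    """Adjusted per-trait significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p-value and U statistic.

    Exact null distribution for combined n <= 25 without ties; otherwise
    the normal approximation with tie and continuity correction.  A
    comparison with no rank information at all (every pooled value
    identical) has p = 1.
    """
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0, x.size * y.size / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue), float(res.statistic)


def mwu_compare(traits: pd.DataFrame, groups: pd.Series, group_a: str,
                group_b: str, alpha: float = 0.05,
                m: int | None = None) -> pd.DataFrame:
    """Rank-sum comparison of every trait between two groups.

    Missing (undefined) trait values are dropped pairwise per trait.
    ``direction`` is the sign of median(group_a) - median(group_b); a
    trait is ``significant`` when p < alpha / m (m defaults to the number
    of traits).  Traits without at least two values per group are marked
    not evaluable (p = NaN).
    """
    groups = pd.Series(groups)
    if m is None:
        m = traits.shape[1]
    threshold = bonferroni_threshold(alpha, m)
    ids_a = groups.index[groups == group_a]
    ids_b = groups.index[groups == group_b]
    rows = []
    for trait in traits.columns:
        x = traits.loc[traits.index.intersection(ids_a), trait].dropna().to_numpy()
        y = traits.loc[traits.index.intersection(ids_b), trait].dropna().to_numpy()
        row = {"trait": trait, "n_a": x.size, "n_b": y.size,
               "median_a": float(np.median(x)) if x.size else np.nan,
               "median_b": float(np.median(y)) if y.size else np.nan,
               "iqr_a": _iqr(x), "iqr_b": _iqr(y)}
        if x.size < 2 or y.size < 2:
            row.update({"p": np.nan, "direction": 0, "significant": False,
                        "evaluable": False})
        else:
            p, _ = _mwu_p(x, y)
            row.update({"p": p,
                        "direction": int(np.sign(row["median_a"] - row["median_b"])),
                        "significant": bool(p < threshold), "evaluable": True})
        rows.append(row)
    out = pd.DataFrame(rows).set_index("trait")
    out.attrs["alpha"] = alpha
    out.attrs["m"] = m
    out.attrs["threshold"] = threshold
    return out


def _iqr(v: np.ndarray) -> str:
    if v.size == 0:
        return ""
    q1, q3 = np.percentile(v, [25, 75])
    return f"{q1:.4g}-{q3:.4g}"


def replicate_filter(results_a: pd.DataFrame, results_b: pd.DataFrame) -> list:
    """Traits significant in both cohorts with a consistent direction."""
    if set(results_a.index) != set(results_b.index):
        raise ValueError("cohorts were screened over different trait registries")
    b = results_b.reindex(results_a.index)
    mask = (results_a["significant"] & b["significant"]
            & (results_a["direction"] == b["direction"])
            & (results_a["direction"] != 0))
    return results_a.index[mask].tolist()


@dataclass(frozen=True)
class AssociationResult:
    trait: str
    outcome: str
    kind: str                    # "logistic" | "linear"
    estimate: float              # log-odds (logistic) or slope (linear) per trait SD
    p_value: float
    converged: bool
    n: int


def associate(values: pd.Series, outcome: pd.Series, kind: str,
              trait_name: str = "", outcome_name: str = "") -> AssociationResult:
    """Per-trait association with one clinical outcome.

    The trait is standardized (zero mean, unit SD) before fitting, so the
    estimate reads per trait SD.  Complete separation of a logistic fit is
    reported via ``converged=False`` rather than a divergent estimate.
    """
    if kind not in ("logistic", "linear"):
        raise ValueError("kind must be 'logistic' or 'linear'")
    df = pd.DataFrame({"x": pd.to_numeric(values, errors="coerce"),
                       "y": pd.to_numeric(outcome, errors="coerce")}).dropna()
    if df["y"].nunique() < 2:
        raise ValueError("outcome is constant")
    sd = df["x"].std(ddof=1)
    if not sd > 0:
        raise ValueError("trait is constant")
    z = (df["x"] - df["x"].mean()) / sd
    X = sm.add_constant(z.to_numpy())
    y = df["y"].to_numpy(dtype=float)
    converged = True
    try:
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            if kind == "logistic":
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                converged = bool(fit.mle_retvals.get("converged", True))
            else:
                fit = sm.OLS(y, X).fit()
            est = float(fit.params[1])
            p = float(fit.pvalues[1])
        if not np.isfinite(est) or not np.isfinite(p) or abs(est) > 50:
            converged, est, p = False, float("nan"), float("nan")
    except Exception:
        converged, est, p = False, float("nan"), float("nan")
    return AssociationResult(trait=trait_name, outcome=outcome_name, kind=kind,
                             estimate=est if converged else float("nan"),
                             p_value=p if converged else float("nan"),
                             converged=converged, n=len(df))


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    cutoff: float                # Youden-J-maximizing threshold
    sensitivity: float
    specificity: float
    flipped: bool                # orientation inverted so that AUC >= 0.5


def roc_single(values: pd.Series, labels: pd.Series, positive=None) -> RocResult:
    """Empirical single-trait ROC with the Youden-optimal cut-off.

    ``positive`` names the positive class (default: the lexically larger
    label).  The orientation is chosen so AUC >= 0.5, with the inversion
    recorded in ``flipped``.
    """
    from sklearn.metrics import roc_curve, auc as sk_auc

    df = pd.DataFrame({"v": values, "y": labels}).dropna()
    classes = sorted(df["y"].unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if positive is None:
        positive = classes[-1]
    y = (df["y"] == positive).to_numpy()
    if y.all() or not y.any():
        raise ValueError("one class is empty")
    v = df["v"].to_numpy(dtype=float)
    flipped = False
    fpr, tpr, thr = roc_curve(y, v)
    area = sk_auc(fpr, tpr)
    if area < 0.5:
        flipped = True
        fpr, tpr, thr = roc_curve(y, -v)
        area = sk_auc(fpr, tpr)
        thr = -thr
    j = int(np.argmax(tpr - fpr))
    return RocResult(fpr=fpr, tpr=tpr, auc=float(area), cutoff=float(thr[j]),
                     sensitivity=float(tpr[j]), specificity=float(1 - fpr[j]),
                     flipped=flipped)


def treatment_response(untreated_vs_hc: pd.DataFrame,
                       untreated_vs_treated: pd.DataFrame,
                       treated_vs_hc: pd.DataFrame,
                       alpha: float = 0.05, m: int | None = None,
                       raw_alpha: float = 0.05) -> pd.DataFrame:
    """Classify each trait as responsive or non-responsive to therapy.

    Responsive means: (i) significantly different untreated-vs-HC at
    alpha/m, (ii) untreated-vs-treated p < ``raw_alpha``, and (iii)
    treated-vs-HC *not* significant at alpha/m (returned to near-normal
    levels).  A trait missing any of the three comparisons is marked not
    evaluable.
    """
    if m is None:
        m = untreated_vs_hc.shape[0]
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    for trait in untreated_vs_hc.index:
        row = {"trait": trait}
        try:
            c1 = untreated_vs_hc.loc[trait]
            c2 = untreated_vs_treated.loc[trait]
            c3 = treated_vs_hc.loc[trait]
        except KeyError:
            row.update({"response": "not-evaluable", "responsive": False})
            rows.append(row)
            continue
        if not (c1.get("evaluable", True) and c2.get("evaluable", True)
                and c3.get("evaluable", True)):
            row.update({"response": "not-evaluable", "responsive": False})
        else:
            responsive = (c1["p"] < threshold and c2["p"] < raw_alpha
                          and not c3["p"] < threshold)
            row.update({"response": "responsive" if responsive else "non-responsive",
                        "responsive": bool(responsive)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")
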