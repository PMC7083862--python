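"""Statistical toolbox: normality-driven test selection, multiplicity
corrections, exact 2x2 tests, group comparisons and logistic regression of
heteroplasmy presence on clinical covariates."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClinicalRecord",
    "select_paired_test",
    "holm_adjust",
    "bh_adjust",
    "fisher_2x2",
    "logistic_hp_model",
    "group_capacity_compare",
]


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    age: float
    psa_total: float
    fpsa_pct: float
    gleason: int
    stage: Literal["pT2", "pT3", "pT4"]
    has_hp: bool
    has_nonsyn_hp: bool

    def __post_init__(self):
        if not (6 <= self.gleason <= 10):
            raise ValueError(f"Gleason score out of range: {self.gleason}")
        if not (0 < self.fpsa_pct < 100):
            raise ValueError(f"fPSA%% out of range: {self.fpsa_pct}")


def select_paired_test(
    x: Sequence[float],
    y: Sequence[float],
    alpha_normality: float = 0.05,
) -> dict:
    """Paired comparison with Shapiro-Wilk-driven test selection.

    Shapiro-Wilk is run on the pairwise differences; if normality is not
    rejected (p > ``alpha_normality``) a paired-samples t-test is used,
    otherwise the Wilcoxon signed-rank test.  Two-sided throughout.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing values are not allowed in paired vectors")
    d = x - y
    if np.allclose(d, d[0]):
        # constant differences: Shapiro is undefined; degenerate case
        if d[0] == 0:
            return {"test": "paired_t", "statistic": 0.0, "p": 1.0,
                    "shapiro_p": np.nan}
        sw_p = 0.0
    else:
        sw_p = float(stats.shapiro(d).pvalue)
    if np.isnan(sw_p) or sw_p > alpha_normality:
        res = stats.ttest_rel(x, y)
        return {"test": "paired_t", "statistic": float(res.statistic),
                "p": float(res.pvalue), "shapiro_p": sw_p}
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=False)
    return {"test": "wilcoxon_signed_rank", "statistic": float(res.statistic),
            "p": float(res.pvalue), "shapiro_p": sw_p}


def _check_pvalues(p: np.ndarray) -> None:
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    _check_pvalues(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (step-up, monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    _check_pvalues(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj


def fisher_2x2(table: Sequence[Sequence[float]]) -> dict:
    """Fisher's exact test for a 2x2 table.

    Two-sided p uses the point-probability rule (sum of hypergeometric
    probabilities <= that of the observed table).  Two odds-ratio estimators
    are reported: the sample (cross-product) OR and the conditional maximum
    likelihood OR underlying the exact test.  Tables with a zero margin are
    degenerate: p = 1 and the ORs are undefined (NaN).
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    a, b, c, d = t.ravel()
    if min(a + b, c + d, a + c, b + d) == 0:
        return {"sample_or": np.nan, "conditional_mle_or": np.nan, "p_two_sided": 1.0}
    res = stats.fisher_exact(t, alternative="two-sided")
    sample_or = np.inf if b * c == 0 else (a * d) / (b * c)
    cond = stats.contingency.odds_ratio(t.astype(int), kind="conditional")
    return {
        "sample_or": float(sample_or),
        "conditional_mle_or": float(cond.statistic),
        "p_two_sided": float(res.pvalue),
    }


def logistic_hp_model(
    clinical: Sequence[ClinicalRecord],
    outcome: Literal["has_hp", "has_nonsyn_hp"] = "has_hp",
    predictors: Sequence[str] = ("age", "fpsa_pct", "stage"),
) -> dict:
    """Multivariate logistic regression of heteroplasmy presence on clinical
    covariates, with per-predictor likelihood-ratio tests.

    Stage enters as an ordered integer (pT2 = 2 ... pT4 = 4).  Each predictor's
    p-value comes from the deviance difference between the full model and the
    model with that predictor removed (chi-squared, 1 df for a numeric
    predictor).  Perfect separation triggers an L2-penalized fallback fit and
    a flag in the result.
    """
    import statsmodels.api as sm

    if len(clinical) < 20:
        raise ValueError("need at least 20 subjects")
    df = pd.DataFrame(
        {
            "age": [r.age for r in clinical],
            "psa_total": [r.psa_total for r in clinical],
            "fpsa_pct": [r.fpsa_pct for r in clinical],
            "gleason": [r.gleason for r in clinical],
            "stage": [int(r.stage[2]) for r in clinical],
            "has_hp": [int(r.has_hp) for r in clinical],
            "has_nonsyn_hp": [int(r.has_nonsyn_hp) for r in clinical],
        }
    )
    y = df[outcome].to_numpy()
    if y.min() == y.max():
        raise ValueError(f"outcome {outcome} is constant")

    def fit(cols: Sequence[str]):
        X = sm.add_constant(df[list(cols)].astype(float), has_constant="add")
        model = sm.Logit(y, X)
        separated = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=0, maxiter=200)
                if not res.mle_retvals.get("converged", True) or np.any(
                    np.abs(res.params) > 50
                ):
                    raise sm.tools.sm_exceptions.PerfectSeparationError
            except Exception:
                separated = True
                res = model.fit_regularized(alpha=1.0, disp=0, maxiter=500)
        return res, separated

    full, separated = fit(predictors)
    coefs = {k: float(v) for k, v in full.params.items() if k != "const"}
    lrt_p = {}
    for pred in predictors:
        reduced, _ = fit([p for p in predictors if p != pred])
        lr = 2.0 * (full.llf - reduced.llf)
        lrt_p[pred] = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return {
        "coefficients": coefs,
        "lrt_p": lrt_p,
        "separation_flagged": separated,
        "n": int(len(df)),
    }


def group_capacity_compare(
    values: Sequence[float],
    groups: Sequence[str],
    min_group_size: int = 3,
) -> dict:
    """Compare a capacity measure (e.g. GM_P/NS_E) across mutation-category
    groups.

    Three or more groups: one-way ANOVA with Tukey HSD pairwise adjusted
    p-values.  Exactly two groups: Wilcoxon rank-sum (Mann-Whitney).  Empty or
    undersized groups are dropped with a warning entry in the result.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups, dtype=object)
    dropped = []
    keep_labels = []
    for g in pd.unique(groups):
        n = int(np.sum(groups == g))
        if n < min_group_size:
            dropped.append((str(g), n))
        else:
            keep_labels.append(g)
    if len(keep_labels) < 2:
        raise ValueError("need at least two groups with enough members")
    samples = [values[groups == g] for g in keep_labels]

    if len(keep_labels) == 2:
        res = stats.ranksums(samples[0], samples[1])
        return {
            "method": "wilcoxon_rank_sum",
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "groups": [str(g) for g in keep_labels],
            "dropped": dropped,
        }

    f, p = stats.f_oneway(*samples)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    mask = np.isin(groups, keep_labels)
    tk = pairwise_tukeyhsd(values[mask], groups[mask].astype(str))
    pairwise = [
        {
            "group1": str(r[0]),
            "group2": str(r[1]),
            "meandiff": float(r[2]),
            "p_adj": float(r[3]),
        }
        for r in tk.summary().data[1:]
    ]
    return {
        "method": "anova_tukey",
        "anova_F": float(f),
        "p": float(p),
        "pairwise": pairwise,
        "groups": [str(g) for g in keep_labels],
        "dropped": dropped,
    }
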