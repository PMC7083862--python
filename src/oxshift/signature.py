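"""Severe-respiratory-phenotype classification, metagene extraction and
scoring, optimal survival cut-point search, Kaplan-Meier / hazard-ratio
analysis and Harrell's concordance.

The respiratory phenotype of a tumor is summarized by its relative
glutamate&malate OXPHOS capacity (GM_P normalized to the maximal ET capacity
NS_E).  Samples at or below the threshold (default 0.27, the cohort mean)
are "severe", above it "mild".  Genes whose expression correlates with the
severe indicator form a metagene set; its mean z-score per subject scores
external expression cohorts, which are then dichotomized at an optimal
cut-point searched over the inner 80% of scores and assessed by Kaplan-Meier
curves, hazard ratios and the stratified log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stats_assoc import bh_adjust

__all__ = [
    "PhenotypeLabel",
    "SurvivalCohort",
    "MetageneSet",
    "classify_phenotype",
    "extract_metagenes",
    "metagene_score",
    "optimal_cutpoint",
    "km_logrank_hr",
    "harrells_c",
    "cox_covariates",
]

GM_THRESHOLD_DEFAULT = 0.27


@dataclass(frozen=True)
class PhenotypeLabel:
    sample_id: str
    gm_fcr: float
    label: Literal["severe", "mild"]
    flagged_above_one: bool = False


@dataclass
class SurvivalCohort:
    """Expression matrix (genes x subjects) with time-to-event annotations."""

    expression: pd.DataFrame  # index: gene names; columns: subject ids
    time: pd.Series  # per subject, > 0
    event: pd.Series  # 1 = event, 0 = censored
    endpoint: Literal["OS", "DFS", "BCR"] = "DFS"
    is_log_transformed: bool = False
    name: str = "cohort"

    def __post_init__(self):
        self.time = self.time.astype(float)
        self.event = self.event.astype(int)
        if list(self.expression.columns) != list(self.time.index) or list(
            self.expression.columns
        ) != list(self.event.index):
            raise ValueError("expression columns and survival index must match")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(self.event.unique()) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if self.expression.index.duplicated().any():
            raise ValueError("gene names must be unique")

    def log_expression(self) -> pd.DataFrame:
        if self.is_log_transformed:
            return self.expression
        return np.log2(self.expression + 1.0)


@dataclass
class MetageneSet:
    genes: list[str]
    correlations: dict[str, float]
    adjusted_p: dict[str, float]
    r_min: float
    alpha: float
    skipped_constant: list[str] = field(default_factory=list)


def classify_phenotype(
    sample_id: str, gm_fcr: float, threshold: float = GM_THRESHOLD_DEFAULT
) -> PhenotypeLabel:
    """Severe iff relative GM capacity <= threshold."""
    if gm_fcr < 0:
        raise ValueError("relative GM capacity cannot be negative")
    if gm_fcr > 1.5:
        raise ValueError(f"implausible relative capacity {gm_fcr} (> 1.5)")
    return PhenotypeLabel(
        sample_id=sample_id,
        gm_fcr=gm_fcr,
        label="severe" if gm_fcr <= threshold else "mild",
        flagged_above_one=gm_fcr > 1.0,
    )


def extract_metagenes(
    expression: pd.DataFrame,
    labels: Sequence[str],
    candidate_genes: Optional[Sequence[str]] = None,
    r_min: float = 0.4,
    alpha: float = 0.05,
    is_log_transformed: bool = False,
) -> MetageneSet:
    """Select genes whose expression correlates with the severe phenotype.

    ``labels`` gives "severe"/"mild" per expression column.  For each
    candidate gene the Pearson (point-biserial) correlation of log2
    expression with the severe indicator (severe = 1) is tested; genes with
    r > ``r_min`` and Benjamini-Hochberg-adjusted p < ``alpha`` are kept.
    ``candidate_genes`` restricts the tested universe (e.g. genes
    overexpressed in the severe group from an external differential
    analysis).
    """
    labels = list(labels)
    if len(labels) != expression.shape[1]:
        raise ValueError("one label per expression column required")
    y = np.array([1.0 if l == "severe" else 0.0 for l in labels])
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least two samples per phenotype")
    X = expression if is_log_transformed else np.log2(expression + 1.0)
    genes = list(candidate_genes) if candidate_genes is not None else list(X.index)
    missing = [g for g in genes if g not in X.index]
    if missing:
        raise KeyError(f"candidate genes absent from matrix: {missing[:5]}...")
    rs, ps, tested, skipped = {}, [], [], []
    for g in genes:
        v = X.loc[g].to_numpy(dtype=float)
        if np.allclose(v, v[0]):
            skipped.append(g)
            warnings.warn(f"gene {g} is constant; skipped", stacklevel=2)
            continue
        r, p = stats.pearsonr(v, y)
        rs[g] = float(r)
        ps.append(float(p))
        tested.append(g)
    q = bh_adjust(ps) if ps else np.array([])
    adj = dict(zip(tested, map(float, q)))
    selected = [g for g in tested if rs[g] > r_min and adj[g] < alpha]
    return MetageneSet(
        genes=selected,
        correlations={g: rs[g] for g in selected},
        adjusted_p={g: adj[g] for g in selected},
        r_min=r_min,
        alpha=alpha,
        skipped_constant=skipped,
    )


def metagene_score(
    cohort: SurvivalCohort, genes: Sequence[str] | MetageneSet,
    method: Literal["mean_z", "pc1"] = "mean_z",
) -> pd.Series:
    """Per-subject signature score.

    Default: mean of gene-wise z-scores of log2 expression within the cohort
    (scale- and gene-order-invariant).  ``pc1`` projects instead on the first
    principal component of the signature submatrix (sign-aligned with the
    mean-z score).  At least half the signature genes must be present.
    """
    gene_list = genes.genes if isinstance(genes, MetageneSet) else list(genes)
    if not gene_list:
        raise ValueError("empty signature")
    X = cohort.log_expression()
    present = [g for g in gene_list if g in X.index]
    missing = sorted(set(gene_list) - set(present))
    if len(present) < 0.5 * len(gene_list):
        raise ValueError(
            f"fewer than half of the signature genes present; missing: {missing}"
        )
    sub = X.loc[present].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    mean_z = z.mean(axis=0)
    if method == "mean_z":
        score = mean_z
    elif method == "pc1":
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        pc1 = vt[0] * s[0] / np.sqrt(z.shape[0])
        if np.corrcoef(pc1, mean_z)[0, 1] < 0:
            pc1 = -pc1
        score = pc1
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return pd.Series(score, index=cohort.expression.columns, name="metagene_score")


def _logrank_fast(time, event, mask):
    """Two-group log-rank chi-squared statistic and p (unstratified)."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    g = np.asarray(mask, bool)
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    n = len(t)
    # distinct event times
    obs_minus_exp = 0.0
    var = 0.0
    i = 0
    n_at_risk = n
    n1_at_risk = int(g.sum())
    while i < n:
        j = i
        d = d1 = 0
        while j < n and t[j] == t[i]:
            if e[j]:
                d += 1
                d1 += int(g[j])
            j += 1
        if d > 0 and 0 < n1_at_risk < n_at_risk:
            exp1 = d * n1_at_risk / n_at_risk
            v = (
                d
                * (n1_at_risk / n_at_risk)
                * (1 - n1_at_risk / n_at_risk)
                * (n_at_risk - d)
                / max(n_at_risk - 1, 1)
            )
            obs_minus_exp += d1 - exp1
            var += v
        elif d > 0:
            pass  # one group exhausted: no information
        n1_at_risk -= int(g[i:j].sum())
        n_at_risk -= j - i
        i = j
    if var <= 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _stratified_logrank(time, event, mask, strata):
    """Stratified log-rank: sums O-E and variance over strata."""
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    g = np.asarray(mask, bool)
    s = np.asarray(strata)
    total_oe = 0.0
    total_var = 0.0
    for lev in np.unique(s):
        sel = s == lev
        chi2, _ = _logrank_fast(t[sel], e[sel], g[sel])
        # recover signed O-E and var by recomputation
        oe, var = _logrank_components(t[sel], e[sel], g[sel])
        total_oe += oe
        total_var += var
    if total_var <= 0:
        return 0.0, 1.0
    chi2 = total_oe**2 / total_var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _logrank_components(t, e, g):
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    n = len(t)
    oe = var = 0.0
    i = 0
    n_at_risk = n
    n1 = int(g.sum())
    while i < n:
        j = i
        d = d1 = 0
        while j < n and t[j] == t[i]:
            if e[j]:
                d += 1
                d1 += int(g[j])
            j += 1
        if d > 0 and 0 < n1 < n_at_risk:
            oe += d1 - d * n1 / n_at_risk
            var += (
                d * (n1 / n_at_risk) * (1 - n1 / n_at_risk)
                * (n_at_risk - d) / max(n_at_risk - 1, 1)
            )
        n1 -= int(g[i:j].sum())
        n_at_risk -= j - i
        i = j
    return oe, var


def optimal_cutpoint(
    scores: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    inner_fraction: float = 0.8,
    correction: Literal["bh", "none"] = "bh",
    ordering: Literal["p_then_c", "c_then_p"] = "p_then_c",
) -> dict:
    """Optimal survival cut-point on a risk score.

    Candidate cuts are the observed score values within the central
    ``inner_fraction`` quantile band.  Each candidate dichotomizes the cohort
    (high = score > cut); its log-rank p is computed, the candidate set is
    multiplicity-corrected (Benjamini-Hochberg by default, mirroring the
    selection pressure of scanning many cuts), and the cut with minimal
    corrected p is selected, ties broken by maximal Harrell's C of the
    dichotomy.  Candidates leaving a group without events are skipped.
    Returns the selection plus the full audit table of all candidates.
    """
    s = np.asarray(scores, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if not (len(s) == len(t) == len(e)):
        raise ValueError("scores/time/event must have equal length")
    if len(s) < 20:
        raise ValueError("need at least 20 subjects")
    if e.sum() < 5:
        raise ValueError("need at least 5 events")
    lo_q = (1.0 - inner_fraction) / 2.0
    lo, hi = np.quantile(s, [lo_q, 1.0 - lo_q])
    cand = np.unique(s[(s >= lo) & (s < hi)])
    if cand.size == 0:
        raise ValueError("no candidate cuts within the inner band")
    rows = []
    for cut in cand:
        mask = s > cut
        if mask.all() or (~mask).all():
            continue
        chi2, p = _logrank_fast(t, e, mask)
        ok_events = e[mask].sum() > 0 and e[~mask].sum() > 0
        c = harrells_c((s > cut).astype(float), t, e)
        rows.append({"cut": float(cut), "logrank_chi2": chi2, "p": p,
                     "harrells_c": c, "both_groups_have_events": ok_events,
                     "n_high": int(mask.sum())})
    audit = pd.DataFrame(rows)
    if correction == "bh":
        audit["corrected_p"] = bh_adjust(audit["p"].to_numpy())
    else:
        audit["corrected_p"] = audit["p"]
    usable = audit[audit["both_groups_have_events"]]
    if usable.empty:
        raise ValueError("no candidate cut leaves events in both groups")
    # concordance is direction-free for selection: use distance from 0.5
    usable = usable.assign(c_sep=(usable["harrells_c"] - 0.5).abs())
    if ordering == "p_then_c":
        best = usable.sort_values(
            ["corrected_p", "c_sep"], ascending=[True, False], kind="stable"
        ).iloc[0]
    else:
        best = usable.sort_values(
            ["c_sep", "corrected_p"], ascending=[False, True], kind="stable"
        ).iloc[0]
    cut = float(best["cut"])
    return {
        "cut": cut,
        "corrected_p": float(best["corrected_p"]),
        "p": float(best["p"]),
        "harrells_c": float(best["harrells_c"]),
        "groups": np.where(s > cut, "high", "low"),
        "audit": audit.drop(columns=["both_groups_have_events"]),
        "band": (float(lo), float(hi)),
    }


def km_logrank_hr(
    time: Sequence[float],
    event: Sequence[int],
    groups: Sequence[str],
    strata: Optional[Sequence] = None,
) -> dict:
    """Kaplan-Meier curves, hazard ratio and (stratified) log-rank test for a
    two-group comparison.

    The HR is for the second group (sorted label order) versus the first,
    from a Cox proportional-hazards fit on the group indicator, stratified
    when ``strata`` is given.  A group without events flags the HR as
    unbounded."""
    from lifelines import CoxPHFitter, KaplanMeierFitter

    t = np.asarray(time, float)
    e = np.asarray(event, int)
    g = np.asarray(groups)
    levels = sorted(pd.unique(g))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    mask = g == levels[1]

    curves = {}
    for lev in levels:
        kmf = KaplanMeierFitter()
        kmf.fit(t[g == lev], e[g == lev], label=str(lev))
        curves[str(lev)] = kmf.survival_function_

    no_events = [lev for lev in levels if e[g == lev].sum() == 0]
    df = pd.DataFrame({"T": t, "E": e, "x": mask.astype(float)})
    if strata is not None:
        df["stratum"] = np.asarray(strata)
    hr = ci_low = ci_high = np.nan
    if not no_events:
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="T",
                event_col="E",
                strata=["stratum"] if strata is not None else None,
            )
        hr = float(np.exp(cph.params_["x"]))
        ci = cph.confidence_intervals_.loc["x"]
        ci_low, ci_high = float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))
    if strata is not None:
        chi2, p = _stratified_logrank(t, e, mask, strata)
    else:
        chi2, p = _logrank_fast(t, e, mask)
    return {
        "km_curves": curves,
        "hr": hr,
        "ci95": (ci_low, ci_high),
        "logrank_chi2": chi2,
        "logrank_p": p,
        "reference": str(levels[0]),
        "comparison": str(levels[1]),
        "hr_unbounded": bool(no_events),
    }


def plot_km(km_result: dict, path: str, title: str = "") -> None:
    """Write the Kaplan-Meier curves of a :func:`km_logrank_hr` result to an
    SVG/PNG/PDF file (format from the extension)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in km_result["km_curves"].items():
        ax.step(curve.index, curve.iloc[:, 0], where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    hr = km_result.get("hr")
    sub = f"HR={hr:.2f}, log-rank p={km_result['logrank_p']:.3g}" \
        if hr == hr else f"log-rank p={km_result['logrank_p']:.3g}"
    ax.set_title(title or sub)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def harrells_c(
    scores: Sequence[float], time: Sequence[float], event: Sequence[int]
) -> float:
    """Harrell's concordance index.

    A pair is usable when the subject with the shorter time has an event.
    Concordant: the higher score belongs to the shorter survival; ties in
    score count 0.5.  Returns concordant fraction among usable pairs, so 1.0
    means higher score = earlier event.
    """
    s = np.asarray(scores, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if len(s) < 2:
        raise ValueError("need at least two subjects")
    # usable pair (i, j): t_i < t_j and subject i had the event
    shorter = t[:, None] < t[None, :]
    usable = shorter & (e[:, None] == 1)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no usable (comparable) pairs")
    higher = s[:, None] > s[None, :]
    tied = s[:, None] == s[None, :]
    concordant = (usable & higher).sum() + 0.5 * (usable & tied).sum()
    return float(concordant / n_usable)


def cox_covariates(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence[int],
    covariates: Optional[pd.DataFrame] = None,
) -> dict:
    """Uni- and multivariate Cox regression of survival on the dichotomized
    signature group plus binary clinical covariates.

    Returns per-covariate hazard ratios with 95% CIs for the univariate
    models and the joint multivariate model.  Constant covariates are dropped
    with a warning; monotone-likelihood problems are flagged.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if e.sum() < 10:
        raise ValueError("need at least 10 events")
    df = pd.DataFrame({"T": t, "E": e, "group": np.asarray(group, float)})
    dropped = []
    if covariates is not None:
        for col in covariates.columns:
            v = covariates[col].to_numpy(dtype=float)
            if np.allclose(v, v[0]):
                dropped.append(col)
                warnings.warn(f"covariate {col} is constant; dropped",
                              stacklevel=2)
            else:
                df[col] = v
    terms = [c for c in df.columns if c not in ("T", "E")]

    def hr_table(fit, cols):
        out = {}
        for c in cols:
            ci = fit.confidence_intervals_.loc[c]
            out[c] = {
                "hr": float(np.exp(fit.params_[c])),
                "ci95": (float(np.exp(ci.iloc[0])), float(np.exp(ci.iloc[1]))),
                "p": float(fit.summary.loc[c, "p"]),
            }
        return out

    flagged = False
    uni = {}
    multi = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for c in terms:
            cph = CoxPHFitter()
            try:
                cph.fit(df[["T", "E", c]], "T", "E")
                uni.update(hr_table(cph, [c]))
            except ConvergenceError:
                flagged = True
                uni[c] = {"hr": np.nan, "ci95": (np.nan, np.nan), "p": np.nan}
        cph = CoxPHFitter(penalizer=0.0)
        try:
            cph.fit(df, "T", "E")
            multi = hr_table(cph, terms)
        except ConvergenceError:
            flagged = True
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, "T", "E")
            multi = hr_table(cph, terms)
    return {
        "univariate": uni,
        "multivariate": multi,
        "dropped": dropped,
        "monotone_likelihood_flagged": flagged,
    }
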