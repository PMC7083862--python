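"""Phenotype classification, metagene extraction/scoring, cut-point search,
survival statistics and concordance."""

import numpy as np
import pandas as pd
import pytest

from oxshift.signature import (
    SurvivalCohort,
    classify_phenotype,
    extract_metagenes,
    harrells_c,
    km_logrank_hr,
    metagene_score,
    optimal_cutpoint,
    cox_covariates,
    _logrank_fast,
)
from oxshift.synthetic_data import ExpressionSurvivalSpec, gen_expression_survival


class TestClassifyPhenotype:
    @pytest.mark.parametrize(
        "gm,expected", [(0.27, "severe"), (0.271, "mild"), (0.0, "severe")]
    )
    def test_threshold_boundary(self, gm, expected):
        assert classify_phenotype("s", gm).label == expected

    def test_above_one_flagged(self):
        lab = classify_phenotype("s", 1.2)
        assert lab.flagged_above_one

    def test_implausible_rejected(self):
        with pytest.raises(ValueError):
            classify_phenotype("s", 1.6)


class TestExtractMetagenes:
    def _matrix(self, rng, n=16, g=40):
        genes = [f"G{i}" for i in range(g)]
        X = pd.DataFrame(rng.normal(8, 1, (g, n)), index=genes,
                         columns=[f"S{i}" for i in range(n)])
        labels = ["severe"] * (n // 2) + ["mild"] * (n - n // 2)
        return X, labels

    def test_gene_equal_to_label_selected_with_r_one(self, rng):
        X, labels = self._matrix(rng)
        X.loc["G0"] = [10.0 if l == "severe" else 2.0 for l in labels]
        res = extract_metagenes(X, labels, is_log_transformed=True)
        assert "G0" in res.genes
        assert res.correlations["G0"] == pytest.approx(1.0)

    def test_null_false_selection_controlled(self):
        """With label-independent genes the expected number of selections is
        controlled by the BH step at alpha (plus the r > 0.4 filter)."""
        n_sel = []
        for rep in range(50):
            rng = np.random.default_rng(rep)
            X, labels = self._matrix(rng, n=16, g=100)
            res = extract_metagenes(X, labels, is_log_transformed=True)
            n_sel.append(len(res.genes))
        assert np.mean(n_sel) < 0.05 * 100

    def test_planted_recovery(self):
        """>= 9 of 11 planted genes recovered in >= 90% of replicates at
        r_true ~ 0.7, n = 16, with candidates restricted to genes
        overexpressed in the severe group (the extraction procedure's
        documented precondition; a one-sided Welch test stands in for the
        external differential-expression analysis)."""
        from scipy import stats as sps

        hits = 0
        n_reps = 50
        for rep in range(n_reps):
            out = gen_expression_survival(
                ExpressionSurvivalSpec(
                    n_subjects=16, n_genes=200, n_planted=11,
                    effect_size=2.0, noise_sd=1.0, seed=3000 + rep,
                )
            )
            X = out["cohort"].expression
            y = np.array([l == "severe" for l in out["labels"]])
            cand = []
            for g in X.index:
                v = X.loc[g].to_numpy()
                t, p = sps.ttest_ind(v[y], v[~y], equal_var=False)
                if t > 0 and p / 2 < 0.05:
                    cand.append(g)
            res = extract_metagenes(
                X, out["labels"], candidate_genes=cand, is_log_transformed=True
            )
            if len(set(res.genes) & set(out["planted_genes"])) >= 9:
                hits += 1
        assert hits >= 0.90 * n_reps

    def test_constant_gene_skipped_with_warning(self, rng):
        X, labels = self._matrix(rng)
        X.loc["G1"] = 5.0
        with pytest.warns(UserWarning, match="G1"):
            res = extract_metagenes(X, labels, is_log_transformed=True)
        assert "G1" in res.skipped_constant


class TestMetageneScore:
    def _cohort(self, X):
        n = X.shape[1]
        return SurvivalCohort(
            expression=X,
            time=pd.Series(np.arange(1.0, n + 1), index=X.columns),
            event=pd.Series(np.ones(n, dtype=int), index=X.columns),
            is_log_transformed=True,
        )

    def test_subject_at_cohort_mean_scores_zero(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (5, 11)),
                         index=[f"G{i}" for i in range(5)],
                         columns=[f"S{i}" for i in range(11)])
        X.iloc[:, 0] = X.iloc[:, 1:].mean(axis=1)
        # center so that column 0 is exactly the cohort mean
        c = self._cohort(X)
        scores = metagene_score(c, list(X.index))
        assert scores.iloc[0] == pytest.approx(
            ((X.iloc[:, 0] - X.mean(axis=1)) / X.std(axis=1, ddof=0)).mean()
        )

    def test_one_sd_shift_scores_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(0, 1, (6, 50)),
                         index=[f"G{i}" for i in range(6)],
                         columns=[f"S{i}" for i in range(50)])
        mu = X.mean(axis=1)
        sd = X.std(axis=1, ddof=0)
        X["Sx"] = mu + sd  # +1 SD on every gene
        c = self._cohort(X)
        # z-scores are recomputed including Sx, so compute expectation directly
        sub = X.to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        assert metagene_score(c, list(X.index))["Sx"] == pytest.approx(
            z[:, -1].mean()
        )

    def test_gene_order_and_affine_invariance(self, rng):
        X = pd.DataFrame(rng.normal(8, 2, (8, 30)),
                         index=[f"G{i}" for i in range(8)],
                         columns=[f"S{i}" for i in range(30)])
        c = self._cohort(X)
        s1 = metagene_score(c, [f"G{i}" for i in range(8)])
        s2 = metagene_score(c, [f"G{i}" for i in reversed(range(8))])
        assert np.allclose(s1, s2)
        # gene-wise affine rescale leaves z-scores unchanged
        X2 = X.mul(pd.Series(rng.uniform(0.5, 3, 8), index=X.index), axis=0)
        X2 = X2.add(pd.Series(rng.normal(0, 5, 8), index=X.index), axis=0)
        s3 = metagene_score(self._cohort(X2), list(X.index))
        assert np.allclose(s1, s3)

    def test_missing_genes_error(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (3, 10)),
                         index=["A", "B", "C"],
                         columns=[f"S{i}" for i in range(10)])
        with pytest.raises(ValueError, match="missing"):
            metagene_score(self._cohort(X), ["A", "X", "Y", "Z"])

    def test_pc1_correlates_with_mean_z(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (6, 40)),
                         index=[f"G{i}" for i in range(6)],
                         columns=[f"S{i}" for i in range(40)])
        c = self._cohort(X)
        a = metagene_score(c, list(X.index), method="mean_z")
        b = metagene_score(c, list(X.index), method="pc1")
        assert np.corrcoef(a, b)[0, 1] > 0


class TestLogrankAndKm:
    def test_fast_logrank_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test

        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        g = rng.integers(0, 2, 80).astype(bool)
        chi2, p = _logrank_fast(t, e, g)
        ref = logrank_test(t[g], t[~g], e[g], e[~g])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)

    def test_identical_groups_hr_one(self):
        t = np.tile(np.array([5.0, 8.0, 11.0, 14.0, 20.0, 30.0]), 2)
        e = np.tile(np.array([1, 1, 0, 1, 1, 0]), 2)
        g = ["a"] * 6 + ["b"] * 6
        res = km_logrank_hr(t, e, g)
        assert res["hr"] == pytest.approx(1.0, abs=1e-6)
        assert res["logrank_p"] == pytest.approx(1.0)

    def test_km_hand_example(self):
        # 6 subjects, one group: events at 2, 4 (n at risk 6, 5);
        # censor at 5; event at 7 (n at risk 3); censor at 9, 11
        t = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 11.0])
        e = np.array([1, 1, 0, 1, 0, 0])
        res = km_logrank_hr(
            np.concatenate([t, [100.0]]), np.concatenate([e, [0]]),
            ["a"] * 6 + ["b"],
        )
        km = res["km_curves"]["a"]["a"]
        assert km.loc[2.0] == pytest.approx(5 / 6)
        assert km.loc[4.0] == pytest.approx(5 / 6 * 4 / 5)
        assert km.loc[7.0] == pytest.approx(5 / 6 * 4 / 5 * 2 / 3)

    def test_km_curve_monotone_from_one(self, rng):
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        g = ["a"] * 25 + ["b"] * 25
        res = km_logrank_hr(t, e, g)
        for curve in res["km_curves"].values():
            vals = curve.iloc[:, 0].to_numpy()
            assert vals[0] <= 1.0 + 1e-12
            assert np.all(np.diff(vals) <= 1e-12)
            assert curve.index[0] == 0.0

    def test_true_hr_recovered(self):
        """Exponential survival with true HR 0.5 at n = 500: the estimate
        falls in [0.40, 0.62] in >= 90% of replicates."""
        hits = 0
        n_reps = 60
        for rep in range(n_reps):
            rng = np.random.default_rng(5000 + rep)
            n = 500
            grp = rng.random(n) < 0.5
            lam = np.where(grp, 0.05, 0.10)  # group b hazard halved
            t = rng.exponential(1 / lam)
            c = rng.uniform(0, 40, n)
            time = np.minimum(t, c)
            e = (t <= c).astype(int)
            res = km_logrank_hr(time, e, np.where(grp, "b", "a"))
            if 0.40 <= res["hr"] <= 0.62:
                hits += 1
        assert hits >= 0.90 * n_reps

    def test_no_events_in_group_flagged(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 0])
        res = km_logrank_hr(t, e, ["a", "a", "b", "b"])
        assert res["hr_unbounded"]


class TestHarrellsC:
    def test_perfect_anti_order(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        s = np.array([4.0, 3.0, 2.0, 1.0])  # higher score, earlier event
        assert harrells_c(s, t, e) == 1.0

    def test_random_score_near_half(self, rng):
        t = rng.exponential(10, 2000)
        e = np.ones(2000, dtype=int)
        s = rng.normal(0, 1, 2000)
        assert harrells_c(s, t, e) == pytest.approx(0.5, abs=0.03)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            t = np.round(rng.exponential(10, n), 1)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                continue
            s = np.round(rng.normal(0, 1, n), 2)
            conc = usable = 0.0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    # i has the shorter time and an event: pair is usable
                    if t[i] < t[j] and e[i] == 1:
                        usable += 1
                        if s[i] > s[j]:
                            conc += 1
                        elif s[i] == s[j]:
                            conc += 0.5
                    elif t[i] == t[j] and i < j and e[i] + e[j] >= 1:
                        # tied times: usable when not both censored; lifelines
                        # counts event-vs-censored pairs
                        pass
            if usable == 0:
                continue
            assert harrells_c(s, t, e) == pytest.approx(conc / usable, abs=1e-12)

    def test_agrees_with_lifelines_on_tie_free_data(self, rng):
        from lifelines.utils import concordance_index

        n = 200
        t = rng.exponential(10, n)  # continuous: no tied times
        e = rng.integers(0, 2, n)
        s = rng.normal(0, 1, n)
        # lifelines convention: higher prediction ~ longer survival
        assert harrells_c(s, t, e) == pytest.approx(
            concordance_index(t, -s, e), abs=1e-12
        )


class TestOptimalCutpoint:
    def _planted(self, rng, n=60, hr=4.0):
        grp = rng.random(n) < 0.5
        scores = np.where(grp, rng.normal(2, 0.3, n), rng.normal(-2, 0.3, n))
        lam = np.where(grp, 0.2, 0.2 / hr)
        t = rng.exponential(1 / lam)
        c = rng.uniform(0, 30, n)
        return scores, np.minimum(t, c), (t <= c).astype(int), grp

    def test_separated_groups_cut_between(self):
        rng = np.random.default_rng(311)
        scores, t, e, grp = self._planted(rng)
        res = optimal_cutpoint(scores, t, e)
        assert -1.5 < res["cut"] < 1.5
        assert (res["groups"] == "high").sum() == grp.sum()

    def test_cut_always_inside_inner_band(self):
        rng = np.random.default_rng(313)
        for _ in range(200):
            n = 40
            s = rng.normal(0, 1, n)
            t = rng.exponential(10, n)
            e = rng.integers(0, 2, n)
            if e.sum() < 5:
                continue
            res = optimal_cutpoint(s, t, e)
            lo, hi = np.quantile(s, [0.1, 0.9])
            assert lo <= res["cut"] <= hi

    def test_audit_equals_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(325)
        scores, t, e, _ = self._planted(rng, n=30)
        res = optimal_cutpoint(scores, t, e)
        lo, hi = np.quantile(scores, [0.1, 0.9])
        expected_cuts = np.unique(scores[(scores >= lo) & (scores < hi)])
        audit = res["audit"]
        assert list(audit["cut"]) == list(expected_cuts)
        for _, row in audit.iterrows():
            chi2, p = _logrank_fast(t, e, scores > row["cut"])
            assert row["p"] == pytest.approx(p)

    def test_null_error_control(self):
        """Score independent of survival: the corrected minimal p is < 0.05
        in at most ~7% of replicates (the correction defeats the
        multiple-cut selection)."""
        n_reps = 500
        false_pos = 0
        for rep in range(n_reps):
            rng = np.random.default_rng(7000 + rep)
            n = 40
            s = rng.normal(0, 1, n)
            t = rng.exponential(10, n)
            c = rng.uniform(0, 25, n)
            time = np.minimum(t, c)
            e = (t <= c).astype(int)
            if e.sum() < 5:
                continue
            res = optimal_cutpoint(s, time, e)
            if res["corrected_p"] < 0.05:
                false_pos += 1
        assert false_pos <= 0.075 * n_reps


class TestCoxCovariates:
    def test_group_only_model_matches_km_hr(self, rng):
        n = 200
        grp = rng.random(n) < 0.5
        lam = np.where(grp, 0.05, 0.1)
        t = rng.exponential(1 / lam)
        c = rng.uniform(0, 40, n)
        time = np.minimum(t, c)
        e = (t <= c).astype(int)
        res = cox_covariates(time, e, grp.astype(int))
        km = km_logrank_hr(time, e, np.where(grp, "b", "a"))
        assert res["univariate"]["group"]["hr"] == pytest.approx(km["hr"], rel=1e-6)

    def test_planted_covariate_recovered_within_ci(self):
        hits = 0
        n_reps = 30
        for rep in range(n_reps):
            rng = np.random.default_rng(8000 + rep)
            n = 300
            grp = (rng.random(n) < 0.5).astype(int)
            age_hi = (rng.random(n) < 0.5).astype(int)
            lam = 0.05 * np.exp(0.7 * grp + 0.5 * age_hi)
            t = rng.exponential(1 / lam)
            c = rng.uniform(0, 60, n)
            time = np.minimum(t, c)
            e = (t <= c).astype(int)
            res = cox_covariates(
                time, e, grp, covariates=pd.DataFrame({"age_hi": age_hi})
            )
            lo, hi = res["multivariate"]["age_hi"]["ci95"]
            if lo <= np.exp(0.5) <= hi:
                hits += 1
        assert hits >= 0.90 * n_reps

    def test_constant_covariate_dropped(self, rng):
        n = 100
        t = rng.exponential(10, n)
        e = np.ones(n, dtype=int)
        with pytest.warns(UserWarning, match="const"):
            res = cox_covariates(
                t, e, rng.integers(0, 2, n),
                covariates=pd.DataFrame({"const": np.ones(n)}),
            )
        assert res["dropped"] == ["const"]


def test_end_to_end_signature_recovery():
    """Full chain on synthetic cohorts: extract metagenes from a small
    discovery cohort, score an independent validation cohort, dichotomize at
    the optimal cut-point and measure the hazard ratio: the mild-like group
    does better (HR < 1) with corrected p < 0.05 in >= 80% of replicates."""
    n_reps = 25
    hits = 0
    for rep in range(n_reps):
        disc = gen_expression_survival(
            ExpressionSurvivalSpec(n_subjects=16, n_genes=300, seed=9000 + rep)
        )
        sig = extract_metagenes(
            disc["cohort"].expression, disc["labels"], is_log_transformed=True
        )
        if not sig.genes:
            continue
        val = gen_expression_survival(
            ExpressionSurvivalSpec(n_subjects=500, n_genes=300,
                                   hr_mild_vs_severe=0.5, seed=9500 + rep)
        )
        scores = metagene_score(val["cohort"], sig)
        res = optimal_cutpoint(
            scores.to_numpy(), val["cohort"].time.to_numpy(),
            val["cohort"].event.to_numpy(),
        )
        km = km_logrank_hr(
            val["cohort"].time.to_numpy(), val["cohort"].event.to_numpy(),
            np.where(scores.to_numpy() > res["cut"], "high", "low"),
        )
        # orient the HR as mild-like (low score) vs severe-like (high score)
        hr_low_vs_high = km["hr"] if km["comparison"] == "low" else 1 / km["hr"]
        if hr_low_vs_high < 1 and res["corrected_p"] < 0.05:
            hits += 1
    assert hits >= 0.80 * n_reps


def test_plot_km_writes_figure(tmp_path, rng):
    from oxshift.signature import km_logrank_hr, plot_km

    t = rng.exponential(10, 40)
    e = rng.integers(0, 2, 40)
    res = km_logrank_hr(t, e, ["a"] * 20 + ["b"] * 20)
    out = tmp_path / "km.svg"
    plot_km(res, str(out))
    assert out.stat().st_size > 0
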