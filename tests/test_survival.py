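import numpy as np
import pandas as pd
import pytest

from codep import survival, synthetic_data as sd
from codep.errors import (DegenerateInputError, DegenerateSplitWarning,
                          GeneNotFoundError, GroupError, HorizonError,
                          NoEventsError, ValidationError)


class TestComputeLP:
    def test_sample_at_cohort_mean_scores_zero(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [10.0, 20.0, 30.0]],
            index=["SRC", "ACSL4"], columns=["a", "b", "c"])
        lp = survival.compute_lp(expr, ["SRC", "ACSL4"])
        assert lp.scores["b"] == pytest.approx(0.0, abs=1e-12)

    def test_affine_rescale_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(2, 30)),
                            index=["SRC", "ACSL4"],
                            columns=[f"s{i}" for i in range(30)])
        lp_a = survival.compute_lp(expr, ["SRC", "ACSL4"])
        scaled = expr.copy()
        scaled.loc["SRC"] = 4.0 * scaled.loc["SRC"] - 7.0
        lp_b = survival.compute_lp(scaled, ["SRC", "ACSL4"])
        assert np.allclose(lp_a.scores, lp_b.scores, atol=1e-10)

    def test_hand_computed_zscores(self):
        expr = pd.DataFrame([[2.0, 4.0, 6.0, 8.0, 10.0],
                             [1.0, 1.0, 3.0, 5.0, 5.0]],
                            index=["g1", "g2"],
                            columns=list("abcde"))
        lp = survival.compute_lp(expr, ["g1", "g2"])
        z1 = (expr.loc["g1"] - 6.0) / expr.loc["g1"].std(ddof=1)
        z2 = (expr.loc["g2"] - 3.0) / expr.loc["g2"].std(ddof=1)
        assert np.allclose(lp.scores, z1 + z2, atol=1e-12)

    def test_missing_gene(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["a", "b"])
        with pytest.raises(GeneNotFoundError):
            survival.compute_lp(expr, ["g1", "nope"])

    def test_constant_gene(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0]], index=["g1"],
                            columns=list("abc"))
        with pytest.raises(DegenerateInputError):
            survival.compute_lp(expr, ["g1"])

    def test_scores_mean_zero_with_unit_weights(self, rng):
        expr = pd.DataFrame(rng.normal(size=(2, 50)),
                            index=["SRC", "ACSL4"],
                            columns=[f"s{i}" for i in range(50)])
        lp = survival.compute_lp(expr, ["SRC", "ACSL4"])
        assert abs(lp.scores.mean()) < 1e-10


class TestMedianSplit:
    def test_even_split_distinct(self, rng):
        scores = pd.Series(rng.permutation(140).astype(float))
        lp = survival.LinearPredictor(("g",), (1.0,), scores)
        labels = survival.median_split(lp)
        assert (labels == "high").sum() == 70
        assert (labels == "low").sum() == 70

    def test_all_equal_warns(self):
        lp = survival.LinearPredictor(("g",), (1.0,),
                                      pd.Series([1.0] * 10))
        with pytest.warns(DegenerateSplitWarning):
            labels = survival.median_split(lp)
        assert (labels == "low").all()

    def test_tie_to_low_rule_n5(self):
        lp = survival.LinearPredictor(("g",), (1.0,),
                                      pd.Series([1.0, 2, 3, 4, 5]))
        labels = survival.median_split(lp)
        assert (labels == "high").sum() == 2
        assert (labels == "low").sum() == 3


class TestKMandLogrank:
    def test_hand_product_limit_oracle(self):
        # classic 6-subject toy: times 1,2+,3,4,4,5+ (+ = censored)
        times = np.array([1.0, 2, 3, 4, 4, 5])
        events = np.array([1, 0, 1, 1, 1, 0])
        curve = survival.km_estimate(times, events)["all"]
        # hand product-limit: S(1)=5/6, S(3)=5/6*3/4, S(4)=...*(1/3)
        assert np.allclose(curve.times, [1, 3, 4])
        assert curve.survival[0] == pytest.approx(5 / 6)
        assert curve.survival[1] == pytest.approx(5 / 6 * 3 / 4)
        assert curve.survival[2] == pytest.approx(5 / 6 * 3 / 4 * 1 / 3)
        assert list(curve.at_risk) == [6, 4, 3]

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(100, size=50) + 1
        events = np.ones(50)
        curve = survival.km_estimate(times, events)["all"]
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_identical_groups_chi2_zero(self, rng):
        times = np.concatenate([rng.exponential(50, 30) + 1] * 2)
        events = np.concatenate([rng.integers(0, 2, 30)] * 2).astype(float)
        if events.sum() == 0:
            events[0] = events[30] = 1
        groups = np.array(["a"] * 30 + ["b"] * 30)
        chi2, p = survival.logrank(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_no_events_raises(self):
        with pytest.raises(NoEventsError):
            survival.logrank([1.0, 2, 3, 4], [0, 0, 0, 0],
                             ["a", "a", "b", "b"])

    def test_km_no_events_flat(self):
        curve = survival.km_estimate([1.0, 2, 3], [0, 0, 0])["all"]
        assert len(curve.times) == 0  # flat at 1.0

    def test_empty_group_raises(self):
        with pytest.raises(GroupError):
            survival.km_estimate([1.0, 2], [1, 1], None) and \
                survival.logrank([1.0, 2], [1, 1], ["a", "a"])

    def test_label_relabeling_invariance(self, rng):
        times = rng.exponential(50, 60) + 1
        events = rng.integers(0, 2, 60).astype(float)
        events[0] = 1
        groups = np.array(["a"] * 30 + ["b"] * 30)
        chi2_a, _ = survival.logrank(times, events, groups)
        swapped = np.where(groups == "a", "b", "a")
        chi2_b, _ = survival.logrank(times, events, swapped)
        assert chi2_a == pytest.approx(chi2_b, abs=1e-10)

    def test_matches_lifelines_logrank(self, rng):
        from lifelines.statistics import logrank_test
        times = rng.exponential(60, 80) + 1
        events = rng.integers(0, 2, 80).astype(float)
        events[:5] = 1
        groups = np.array(["a"] * 40 + ["b"] * 40)
        chi2, p = survival.logrank(times, events, groups)
        ref = logrank_test(times[:40], times[40:], events[:40], events[40:])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)


class TestCoxFit:
    def test_null_covariate_calibration(self):
        inside = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.normal(size=n)
            times = rng.exponential(100, size=n)
            events = np.ones(n)
            fit = survival.cox_fit(times, events, x[:, None])
            if abs(fit.coef[0]) < 2 * fit.se[0]:
                inside += 1
        assert inside >= 93

    def test_recovery_of_planted_log_hr(self):
        betas = []
        for seed in range(60):
            spec = sd.CohortSpec(n_samples=1000,
                                 true_log_hr_per_lp_unit=float(np.log(1.27)),
                                 censoring_rate=0.3, seed=seed)
            cohort, _ = sd.simulate_cohort(spec)
            lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
            fit = survival.cox_fit(cohort.clinical["os_time"],
                                   cohort.clinical["os_event"],
                                   lp.scores.to_frame("lp"))
            betas.append(fit.coef[0])
        assert np.mean(betas) == pytest.approx(np.log(1.27), abs=0.03)

    def test_matches_lifelines_two_covariates(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(31)
        n = 300
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, size=n).astype(float)
        hazard = 0.01 * np.exp(0.5 * x1 - 0.3 * x2)
        t_event = rng.exponential(1 / hazard)
        cens = rng.exponential(150, size=n)
        times = np.minimum(t_event, cens)
        # duplicate some times to exercise the Efron tie path
        times = np.round(times, 0) + 1
        events = (t_event <= cens).astype(float)
        fit = survival.cox_fit(times, events,
                               pd.DataFrame({"x1": x1, "x2": x2}))
        df = pd.DataFrame({"t": times, "e": events, "x1": x1, "x2": x2})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert fit.coef[0] == pytest.approx(cph.params_["x1"], abs=1e-6)
        assert fit.coef[1] == pytest.approx(cph.params_["x2"], abs=1e-6)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x1"],
                                          abs=1e-5)

    def test_separation_detected(self):
        times = np.array([1.0, 2, 3, 10, 20, 30])
        events = np.ones(6)
        x = np.array([1.0, 1, 1, 0, 0, 0])  # early deaths perfectly split
        with pytest.raises((survival.SeparationError, Exception)):
            survival.cox_fit(times, events, x[:, None])

    def test_ci_contains_hr(self, small_cohort):
        cohort, _ = small_cohort
        lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
        fit = survival.cox_fit(cohort.clinical["os_time"],
                               cohort.clinical["os_event"],
                               lp.scores.to_frame("lp"))
        assert fit.ci_low[0] <= fit.hazard_ratio[0] <= fit.ci_high[0]
        assert fit.n_events <= fit.n


class TestMultivariableSuite:
    def test_ladder_runs_and_reports_n(self, small_cohort):
        cohort, _ = small_cohort
        lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
        fits = survival.multivariable_suite(cohort, lp)
        names = [n for n, _ in fits]
        assert names == ["lp", "lp_age", "lp_age_cyto", "lp_age_molecular",
                         "lp_age_molecular_idh"]
        ns = [f.n for _, f in fits]
        assert all(n2 <= n1 for n1, n2 in zip(ns, ns[1:]))
        # lp coefficient present in every model
        for _, fit in fits:
            assert "lp" in fit.covariates

    def test_lp_hr_stable_when_covariates_independent(self, small_cohort):
        cohort, _ = small_cohort
        lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
        fits = dict(survival.multivariable_suite(cohort, lp))
        base = fits["lp"]
        i = base.covariates.index("lp")
        for name in ("lp_age", "lp_age_molecular"):
            other = fits[name]
            j = other.covariates.index("lp")
            assert abs(other.coef[j] - base.coef[i]) < base.se[i] + other.se[j]

    def test_constant_mutation_dropped(self, small_cohort):
        cohort, _ = small_cohort
        cohort.mutations.loc["TP53"] = 0.0
        lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
        fits = dict(survival.multivariable_suite(cohort, lp))
        assert "TP53" not in fits["lp_age_molecular"].covariates

    def test_zero_missingness_constant_n(self, small_cohort):
        cohort, _ = small_cohort
        lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
        fits = survival.multivariable_suite(cohort, lp)
        assert len({f.n for _, f in fits}) == 1  # no missingness planted


class TestTimedepAUC:
    def test_perfect_marker(self, rng):
        times = rng.exponential(400, size=300) + 1.0
        events = np.ones(300)
        marker = -times  # earlier death = higher marker: perfect
        aucs = survival.timedep_auc(times, events, marker, [0.5, 1.0])
        for v in aucs.values():
            assert v == pytest.approx(1.0, abs=1e-12)

    def test_null_marker(self, rng):
        times = rng.exponential(800, size=1000) + 1.0
        events = rng.integers(0, 2, 1000).astype(float)
        marker = rng.normal(size=1000)
        aucs = survival.timedep_auc(times, events, marker, [1, 2, 3])
        for v in aucs.values():
            assert 0.45 < v < 0.55

    def test_monotone_transform_invariance(self, rng):
        times = rng.exponential(700, size=300) + 1.0
        events = rng.integers(0, 2, 300).astype(float)
        marker = rng.normal(size=300)
        a = survival.timedep_auc(times, events, marker, [1])
        b = survival.timedep_auc(times, events, np.exp(3 * marker), [1])
        assert a[1.0] == pytest.approx(b[1.0], abs=1e-12)

    def test_horizon_beyond_followup(self, rng):
        times = rng.uniform(1, 300, size=50)
        with pytest.raises(HorizonError):
            survival.timedep_auc(times, np.ones(50), times, [5])

    def test_matches_sksurv_uno_estimator(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv
        times = rng.exponential(600, size=400) + 1.0
        events = rng.integers(0, 2, 400).astype(bool)
        events[:20] = True
        marker = (0.6 * -np.log(times) + rng.normal(size=400))
        y = Surv.from_arrays(events, times)
        horizon_days = 365.25
        ref_auc, _ = cumulative_dynamic_auc(y, y, marker,
                                            np.array([horizon_days]))
        ours = survival.timedep_auc(times, events.astype(float), marker, [1])
        assert ours[1.0] == pytest.approx(float(ref_auc[0]), abs=5e-3)

    def test_combined_marker_dominates_components(self):
        wins = 0
        for seed in range(20):
            spec = sd.CohortSpec(n_samples=600,
                                 true_log_hr_per_lp_unit=0.35,
                                 age_log_hr=0.5, censoring_rate=0.2,
                                 seed=seed + 10)
            cohort, _ = sd.simulate_cohort(spec)
            lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
            times = cohort.clinical["os_time"].to_numpy()
            events = cohort.clinical["os_event"].to_numpy()
            age = cohort.clinical["age"].to_numpy()
            fit = survival.cox_fit(times, events, pd.DataFrame(
                {"lp": lp.scores.to_numpy(), "age": age}))
            combined = fit.coef[0] * lp.scores.to_numpy() + fit.coef[1] * age
            h = [1.0]
            auc_lp = survival.timedep_auc(times, events,
                                          lp.scores.to_numpy(), h)[1.0]
            auc_age = survival.timedep_auc(times, events, age, h)[1.0]
            auc_comb = survival.timedep_auc(times, events, combined, h)[1.0]
            if auc_comb >= max(auc_lp, auc_age) - 1e-9:
                wins += 1
        assert wins >= 18  # >= 90%


class TestMutationContrast:
    def test_planted_shift_detected(self):
        hits = 0
        for seed in range(20):
            spec = sd.CohortSpec(
                n_samples=600,
                mutation_genes=(("IDH1", 0.08, -0.9), ("FLT3", 0.2, 0.0)),
                seed=seed + 40)
            cohort, _ = sd.simulate_cohort(spec)
            lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
            table, _ = survival.mutation_contrast(
                lp.scores, cohort.mutations, ["IDH1", "FLT3"])
            row = table.set_index("gene").loc["IDH1"]
            if row["q"] < 0.05 and row["median_mut"] < row["median_wt"]:
                hits += 1
        assert hits >= 18  # >= 90%

    def test_no_shift_no_hits(self):
        false_hits = 0
        for seed in range(20):
            spec = sd.CohortSpec(
                n_samples=400, mutation_genes=(("NPM1", 0.3, 0.0),),
                seed=seed + 80)
            cohort, _ = sd.simulate_cohort(spec)
            lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
            table, _ = survival.mutation_contrast(lp.scores, cohort.mutations,
                                                  ["NPM1"])
            if (table["q"] < 0.05).any():
                false_hits += 1
        assert false_hits <= 3

    def test_too_few_mutants_skipped(self, small_cohort):
        cohort, _ = small_cohort
        muts = cohort.mutations.copy()
        muts.loc["RARE"] = 0.0
        muts.iloc[-1, 0] = 1.0
        lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
        table, skipped = survival.mutation_contrast(lp.scores, muts, ["RARE"])
        assert "RARE" in skipped

    def test_all_missing_warns_empty(self, small_cohort):
        cohort, _ = small_cohort
        muts = pd.DataFrame([[np.nan] * len(cohort.samples)], index=["X"],
                            columns=cohort.samples)
        lp = survival.compute_lp(cohort.expression, ["SRC", "ACSL4"])
        with pytest.warns(UserWarning):
            table, skipped = survival.mutation_contrast(lp.scores, muts,
                                                        ["X"])
        assert len(table) == 0
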