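import itertools

import numpy as np
import pandas as pd
import pytest

from regionsig import (
    ConvergenceError,
    SignatureModel,
    SyntheticCohortSpec,
    ValidationError,
    concordance_index,
    fit_cox,
    km_logrank,
    meta_fixed_effect,
    mixed_effects_trend,
    pseudo_single_biopsy_bootstrap,
    pve_over_time,
    score_cohort,
    simulate_multiregion_expression,
    simulate_survival,
)
from regionsig.survival import cox_univariable


def _clinical(times, events, **covariates):
    n = len(times)
    data = {"os_time": times, "os_event": events}
    data.update(covariates)
    return pd.DataFrame(data, index=[f"p{i}" for i in range(n)])


def _sim_clinical(n, beta, seed, censor_rate=0.03):
    spec = SyntheticCohortSpec(
        n_patients=n, latent_beta=beta, censor_rate=censor_rate, seed=seed
    )
    rng = np.random.default_rng(seed)
    z = pd.Series(rng.standard_normal(n), index=[f"p{i}" for i in range(n)])
    clin = simulate_survival(z, spec)
    clin["z"] = z
    return clin


class TestFitCox:
    def test_null_effect_ci_coverage(self):
        covered = 0
        reps = 30
        for rep in range(reps):
            clin = _sim_clinical(500, beta=0.0, seed=100 + rep)
            table = fit_cox(clin, "os", ["z"])
            row = table.loc["z"]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered / reps >= 0.87  # nominal 95%, small-rep slack

    def test_parameter_recovery(self):
        clin = _sim_clinical(1000, beta=np.log(2), seed=42)
        table = fit_cox(clin, "os", ["z"])
        assert table.loc["z", "hr"] == pytest.approx(2.0, rel=0.10)

    def test_reference_level_hr_one(self):
        clin = _sim_clinical(200, beta=0.0, seed=3)
        table = fit_cox(clin, "os", ["z", "sex", "stage"])
        assert table.loc["sex[male]", "hr"] == 1.0
        assert table.loc["sex[male]", "reference"]
        assert table.loc["stage[I]", "reference"]
        assert not table.loc["stage[II]", "reference"]

    def test_no_events_errors(self):
        clin = _clinical([1.0, 2.0], [0, 0], z=[0.1, 0.2])
        with pytest.raises(ValidationError, match="events"):
            fit_cox(clin, "os", ["z"])

    def test_complete_cases_only(self):
        clin = _sim_clinical(100, beta=0.0, seed=5)
        clin.loc[clin.index[:20], "z"] = np.nan
        table = fit_cox(clin, "os", ["z"])
        assert table.attrs["n"] == 80

    def test_missing_endpoint_errors(self):
        clin = _clinical([1.0], [1], z=[0.0])
        with pytest.raises(ValidationError, match="dfs_time"):
            fit_cox(clin, "dfs", ["z"])


class TestKMLogrank:
    def test_identical_groups_p_one(self):
        base = _sim_clinical(60, beta=0.0, seed=9)
        dup = pd.concat([base, base.set_index(base.index + "_copy")])
        groups = pd.Series(
            ["a"] * len(base) + ["b"] * len(base), index=dup.index
        )
        res = km_logrank(dup, "os", groups)
        assert res.p == pytest.approx(1.0)

    def test_single_group_errors(self):
        clin = _sim_clinical(20, beta=0.0, seed=2)
        groups = pd.Series("only", index=clin.index)
        with pytest.raises(ValidationError):
            km_logrank(clin, "os", groups)

    def test_median_not_reached(self):
        clin = _clinical([5.0, 6.0, 7.0, 1.0, 1.5, 2.0],
                         [0, 0, 0, 1, 1, 1])
        groups = pd.Series(["good"] * 3 + ["bad"] * 3, index=clin.index)
        res = km_logrank(clin, "os", groups)
        assert res.medians["good"] is None
        assert res.median_display("good") == "not reached"
        assert res.medians["bad"] is not None

    def test_extreme_separation_matches_permutation_oracle(self):
        # group A has all events before any event in B, no censoring
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 11.0, 12.0, 13.0, 14.0])
        events = np.ones(10, dtype=int)
        clin = _clinical(times, events)
        labels = np.array(["A"] * 5 + ["B"] * 5)
        res = km_logrank(clin, "os", pd.Series(labels, index=clin.index))

        # exact enumeration oracle over all 5-of-10 label assignments
        from lifelines.statistics import multivariate_logrank_test

        stats_null = []
        for combo in itertools.combinations(range(10), 5):
            lab = np.array(["B"] * 10)
            lab[list(combo)] = "A"
            r = multivariate_logrank_test(times, lab, events)
            stats_null.append(r.test_statistic)
        stats_null = np.array(stats_null)
        p_exact = float(np.mean(stats_null >= res.test_statistic - 1e-9))
        assert res.p < 0.01
        assert p_exact == pytest.approx(2 / 252)  # observed split is the most extreme
        assert abs(res.p - p_exact) < 0.02


class TestCoxUnivariable:
    def test_matches_lifelines(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(1 / (0.1 * np.exp(0.5 * x)))
            # force some ties
            t = np.round(t, 1) + 0.1
            e = rng.random(n) < 0.8
            beta, se = cox_univariable(x, t, e)
            from lifelines import CoxPHFitter

            df = pd.DataFrame({"t": t, "e": e.astype(int), "x": x})
            cph = CoxPHFitter().fit(df, "t", "e")
            # lifelines stops on its own looser tolerance; agree to ~1e-4
            assert beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
            assert se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_no_events_errors(self):
        with pytest.raises(ValidationError):
            cox_univariable([1.0, 2.0], [1.0, 2.0], [0, 0])


def _bootstrap_inputs(n_patients=200, sigma2=0.05, beta=0.8, seed=0):
    spec = SyntheticCohortSpec(
        n_patients=n_patients,
        regions_per_patient=3,
        n_genes=30,
        signature_size=10,
        tau2=0.0,
        sigma2=sigma2,
        latent_loading=1.0 / np.sqrt(10),  # unit between-patient score variance
        latent_beta=beta,
        baseline_hazard=0.15,
        censor_rate=0.02,
        seed=seed,
    )
    cohort, truth = simulate_multiregion_expression(spec)
    sig = truth["signature"]
    profile = score_cohort(cohort, sig, batch_correct=False)
    patient_score = profile.patient_summary["mean_score"]
    clinical = simulate_survival(patient_score, spec)
    return profile, clinical


class TestPseudoSingleBiopsyBootstrap:
    def test_single_region_patients_zero_width_ci(self):
        spec = SyntheticCohortSpec(
            n_patients=150, regions_per_patient=1, n_genes=20, signature_size=5,
            tau2=1.0, sigma2=0.0, latent_beta=0.5, seed=4,
        )
        cohort, truth = simulate_multiregion_expression(spec)
        profile = score_cohort(cohort, truth["signature"], batch_correct=False)
        clinical = simulate_survival(profile.patient_summary["mean_score"], spec)
        res = pseudo_single_biopsy_bootstrap(profile, clinical, "os", n_iter=20, seed=1)
        assert np.allclose(res.log_hr_draws, res.log_hr_draws[0])
        assert res.hr_ci[0] == pytest.approx(res.hr_ci[1])

    def test_seed_reproducible(self):
        profile, clinical = _bootstrap_inputs()
        a = pseudo_single_biopsy_bootstrap(profile, clinical, "os", n_iter=25, seed=7)
        b = pseudo_single_biopsy_bootstrap(profile, clinical, "os", n_iter=25, seed=7)
        assert np.array_equal(a.log_hr_draws, b.log_hr_draws)

    def test_region_order_invariance(self):
        profile, clinical = _bootstrap_inputs()
        shuffled = profile.region_scores.sample(frac=1.0, random_state=5)
        from dataclasses import replace

        prof2 = replace(profile, region_scores=shuffled)
        a = pseudo_single_biopsy_bootstrap(profile, clinical, "os", n_iter=25, seed=7)
        b = pseudo_single_biopsy_bootstrap(prof2, clinical, "os", n_iter=25, seed=7)
        assert np.array_equal(a.log_hr_draws, b.log_hr_draws)

    def test_default_n_iter_is_1000(self):
        import inspect

        sig = inspect.signature(pseudo_single_biopsy_bootstrap)
        assert sig.parameters["n_iter"].default == 1000

    def test_recovers_planted_log_hr(self):
        profile, clinical = _bootstrap_inputs(n_patients=400, seed=11)
        res = pseudo_single_biopsy_bootstrap(profile, clinical, "os", n_iter=120, seed=3)
        assert res.mean_log_hr == pytest.approx(0.8, rel=0.25)


class TestConcordanceIndex:
    @staticmethod
    def _oracle(scores, time, event):
        n = len(scores)
        num = 0.0
        den = 0
        for i in range(n):
            for j in range(n):
                if time[i] < time[j] and event[i]:
                    den += 1
                    if scores[i] > scores[j]:
                        num += 1.0
                    elif scores[i] == scores[j]:
                        num += 0.5
        return num / den

    def test_perfect_ranking(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        s = np.array([4.0, 3.0, 2.0, 1.0])
        assert concordance_index(s, t, np.ones(4)) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1, 3000)
        s = rng.normal(size=3000)
        c = concordance_index(s, t, np.ones(3000))
        assert c == pytest.approx(0.5, abs=0.03)

    def test_four_patient_fixture_matches_oracle(self):
        s = np.array([2.0, 2.0, 1.0, 5.0])
        t = np.array([3.0, 1.0, 4.0, 2.0])
        e = np.array([1, 1, 0, 0])
        assert concordance_index(s, t, e) == self._oracle(s, t, e)

    def test_matches_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            s = rng.choice([0.0, 1.0, 2.5, 7.0], size=n)  # force score ties
            t = np.round(rng.exponential(2, n), 1)
            e = rng.random(n) < 0.7
            if not (e & (t[:, None] > t[None, :]).any(axis=1)).any():
                continue
            assert concordance_index(s, t, e) == self._oracle(s, t, e)

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValidationError):
            concordance_index([1.0, 2.0], [1.0, 1.0], [1, 1])


class TestPveOverTime:
    def test_independent_biomarker_near_zero(self):
        rng = np.random.default_rng(1)
        n = 2000
        clin = _clinical(rng.exponential(3, n), rng.random(n) < 0.8)
        bm = pd.DataFrame({"noise": rng.normal(size=n)}, index=clin.index)
        pve = pve_over_time(bm, clin, "os", years=[2])
        assert pve.loc[2, "noise"] < 0.01

    def test_deterministic_threshold_capped_at_one(self):
        n = 300
        x = np.linspace(-2, 2, n)
        died = x > 0
        clin = _clinical(np.where(died, 0.5, 10.0), died.astype(int))
        bm = pd.DataFrame({"x": x}, index=clin.index)
        with np.errstate(all="ignore"):
            pve = pve_over_time(bm, clin, "os", years=[1])
        assert pve.loc[1, "x"] == pytest.approx(1.0, abs=1e-6)

    def test_censored_before_horizon_excluded(self):
        # 5 patients: one censored at 0.5 (excluded at year 1), others known
        clin = _clinical([0.5, 0.4, 2.0, 3.0, 0.9],
                         [0, 1, 0, 1, 1])
        keep = ~((clin["os_event"] == 0) & (clin["os_time"] < 1))
        assert keep.sum() == 4  # hand count
        bm = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0, 1.0]}, index=clin.index)
        pve = pve_over_time(bm, clin, "os", years=[1])
        assert np.isfinite(pve.loc[1, "x"])

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        n = 400
        x = rng.normal(size=n)
        death_prob = 1 / (1 + np.exp(-x))
        died = rng.random(n) < death_prob
        clin = _clinical(np.where(died, 0.5, 10.0), died.astype(int))
        bm1 = pd.DataFrame({"x": x}, index=clin.index)
        bm2 = pd.DataFrame({"x": 100 * x - 3}, index=clin.index)
        p1 = pve_over_time(bm1, clin, "os", years=[1])
        p2 = pve_over_time(bm2, clin, "os", years=[1])
        assert p1.loc[1, "x"] == pytest.approx(p2.loc[1, "x"], abs=1e-6)

    def test_requires_death_and_survivor(self):
        clin = _clinical([0.2, 0.3], [1, 1])
        bm = pd.DataFrame({"x": [0.0, 1.0]}, index=clin.index)
        with pytest.raises(ValidationError):
            pve_over_time(bm, clin, "os", years=[1])


class TestMetaFixedEffect:
    def test_single_cohort_identity(self):
        res = meta_fixed_effect([0.7], [0.2])
        assert res.pooled_log_hr == pytest.approx(0.7)
        assert res.se == pytest.approx(0.2)

    def test_equal_se_average(self):
        res = meta_fixed_effect([0.4, 0.8], [0.3, 0.3])
        assert res.pooled_log_hr == pytest.approx(0.6)

    def test_three_cohort_hand_computation(self):
        betas = [0.5, 0.9, 0.2]
        ses = [0.1, 0.25, 0.4]
        w = [1 / s**2 for s in ses]
        expected = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
        expected_se = (1 / sum(w)) ** 0.5
        res = meta_fixed_effect(betas, ses)
        assert abs(res.pooled_log_hr - expected) < 1e-12
        assert abs(res.se - expected_se) < 1e-12

    def test_pooled_variance_never_larger(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(1, 6))
            betas = rng.normal(size=k)
            ses = rng.uniform(0.05, 1.0, size=k)
            res = meta_fixed_effect(betas, ses)
            assert res.se**2 <= ses.min() ** 2 + 1e-15

    def test_zero_se_errors(self):
        with pytest.raises(ValidationError):
            meta_fixed_effect([0.1], [0.0])


class TestMixedEffectsTrend:
    def _make(self, delta, re_sd, n_groups=40, per_group=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(n_groups):
            u = rng.normal(0, re_sd)
            for r in range(per_group):
                label = "late" if r % 2 else "early"
                y = u + (delta if label == "late" else 0.0) + rng.normal(0, 0.5)
                rows.append((f"g{g}_s{r}", y, label, f"g{g}"))
        df = pd.DataFrame(rows, columns=["sample", "y", "label", "group"]).set_index("sample")
        return df

    def test_null_contrast_near_zero(self):
        df = self._make(delta=0.0, re_sd=0.5, n_groups=80, seed=1)
        res = mixed_effects_trend(df["y"], df["label"], df["group"])
        assert abs(res.loc["late", "estimate"]) < 0.15

    def test_planted_shift_recovery(self):
        df = self._make(delta=1.0, re_sd=0.5, n_groups=100, seed=2)
        res = mixed_effects_trend(df["y"], df["label"], df["group"])
        assert res.loc["late", "estimate"] == pytest.approx(1.0, rel=0.15)
        assert res.loc["late", "p"] < 0.001

    def test_zero_random_variance_matches_ols(self):
        import statsmodels.api as sm

        df = self._make(delta=0.8, re_sd=0.0, n_groups=60, seed=3)
        res = mixed_effects_trend(df["y"], df["label"], df["group"])
        X = sm.add_constant((df["label"] == "late").astype(float))
        ols = sm.OLS(df["y"], X).fit()
        assert res.loc["late", "estimate"] == pytest.approx(ols.params.iloc[1], abs=0.02)

    def test_reference_level_configurable(self):
        df = self._make(delta=1.0, re_sd=0.3, n_groups=40, seed=4)
        res = mixed_effects_trend(df["y"], df["label"], df["group"], reference="late")
        assert res.loc["early", "estimate"] == pytest.approx(-1.0, rel=0.3)

    def test_single_category_errors(self):
        df = self._make(delta=0.0, re_sd=0.3, n_groups=10)
        df["label"] = "only"
        with pytest.raises(ValidationError):
            mixed_effects_trend(df["y"], df["label"], df["group"])
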