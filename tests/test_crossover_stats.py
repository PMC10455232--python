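"""Mixed-model fits, gatekeeping, signed-rank test, and summary table."""

import itertools
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cathflow.crossover_stats import (
    fit_binary_glmm,
    fit_count_glmm,
    fit_lmm,
    gatekeep,
    percent_reduction,
    summarize_trial,
    wilcoxon_signed_rank,
    within_subject_differences,
)
from cathflow.errors import DataError
from cathflow.synth import EndpointModel, TrialSimConfig, simulate_trial


def crossover_frame(values_by_subject):
    """Small crossover frame: subject -> {(visit, device): value}."""
    rows = []
    for subj, cells in values_by_subject.items():
        for (visit, device), val in cells.items():
            rows.append(
                {"subject": subj, "visit": visit, "device": device, "y": val,
                 "medical_history": "non-neurogenic"}
            )
    return pd.DataFrame(rows)


def balanced_trial(rng, endpoint_models, n=42, dropout=0.0):
    cfg = TrialSimConfig(n_subjects=n, endpoints=endpoint_models, dropout_rate=dropout)
    return simulate_trial(cfg, rng)


class TestFitLMM:
    def test_noiseless_device_effect_recovered_exactly(self):
        # y = 100 + subject + 10*(device==CEC), zero residual error
        data = {}
        for i in range(8):
            subj = 100 + 5 * i
            first = "MHZC" if i % 2 else "CEC"
            second = "CEC" if first == "MHZC" else "MHZC"
            data[f"S{i}"] = {
                (1, first): subj + (10.0 if first == "CEC" else 0.0),
                (2, second): subj + (10.0 if second == "CEC" else 0.0),
            }
        fit = fit_lmm(crossover_frame(data), "y")
        assert fit.effect == pytest.approx(10.0, abs=1e-6)
        assert fit.p_value < 1e-10

    def test_simulated_effect_recovered_in_mean_over_replicates(self):
        rng = np.random.default_rng(1)
        models = (EndpointModel("y", "gaussian", mu=39.4, device_effect=-34.3,
                                sigma_subject=20.0, sigma_resid=45.8),)
        est = [fit_lmm(balanced_trial(rng, models), "y").effect for _ in range(60)]
        # MC error ~ 10/sqrt(60): the mean should sit near the true 34.3
        assert np.mean(est) == pytest.approx(34.3, abs=4.0)

    def test_degenerate_limit_matches_ols(self):
        rng = np.random.default_rng(2)
        models = (EndpointModel("y", "gaussian", mu=10.0, device_effect=-3.0,
                                sigma_subject=0.0, sigma_resid=5.0),)
        df = balanced_trial(rng, models, n=20)
        mixed = fit_lmm(df, "y")
        ols = fit_lmm(df, "y", force_zero_variance=True)
        assert mixed.effect == pytest.approx(ols.effect, abs=1e-4)

    def test_device_label_permutation_flips_difference_sign(self):
        rng = np.random.default_rng(3)
        models = (EndpointModel("y", "gaussian", mu=20.0, device_effect=-8.0,
                                sigma_subject=5.0, sigma_resid=10.0),)
        df = balanced_trial(rng, models, n=20)
        flipped = df.assign(device=df.device.map({"MHZC": "CEC", "CEC": "MHZC"}))
        assert fit_lmm(flipped, "y").effect == pytest.approx(-fit_lmm(df, "y").effect,
                                                             abs=1e-6)

    def test_all_missing_endpoint_is_a_data_error(self):
        df = crossover_frame({"S1": {(1, "MHZC"): np.nan, (2, "CEC"): np.nan}})
        with pytest.raises(DataError):
            fit_lmm(df, "y")


class TestCountGLMM:
    def test_equal_counts_under_both_devices_give_unit_rate_ratio(self):
        data = {}
        counts = [0, 1, 2, 3, 1, 0, 2, 1]
        for i, c in enumerate(counts):
            first = "MHZC" if i % 2 else "CEC"
            second = "CEC" if first == "MHZC" else "MHZC"
            data[f"S{i}"] = {(1, first): c, (2, second): c}
        df = crossover_frame(data).rename(columns={"y": "n"})
        fit = fit_count_glmm(df, "n")
        assert fit.effect == pytest.approx(1.0, abs=1e-3)

    def test_zero_variance_data_matches_plain_poisson_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        models = (EndpointModel("n", "poisson", mu=np.log(1.1),
                                device_effect=np.log(0.4), sigma_subject=0.0),)
        df = balanced_trial(rng, models, n=30)
        fit = fit_count_glmm(df, "n", fixed_sigma=1e-6)
        X = np.column_stack([
            np.ones(len(df)),
            (df.device == "MHZC").to_numpy(float),
            (df.visit == 2).to_numpy(float),
        ])
        glm = sm.GLM(df["n"].to_numpy(float), X, family=sm.families.Poisson()).fit()
        assert np.log(fit.effect) == pytest.approx(glm.params[1], abs=1e-4)

    def test_rate_ratio_recovery_median_within_window(self):
        rng = np.random.default_rng(5)
        models = (EndpointModel("n", "poisson", mu=np.log(1.09),
                                device_effect=np.log(0.16), sigma_subject=0.6),)
        est = [
            fit_count_glmm(balanced_trial(rng, models, dropout=1 / 42), "n").effect
            for _ in range(80)
        ]
        assert 0.12 <= np.median(est) <= 0.21

    def test_device_label_permutation_reciprocates_ratio(self):
        rng = np.random.default_rng(6)
        models = (EndpointModel("n", "poisson", mu=np.log(1.0),
                                device_effect=np.log(0.5), sigma_subject=0.4),)
        df = balanced_trial(rng, models, n=24)
        flipped = df.assign(device=df.device.map({"MHZC": "CEC", "CEC": "MHZC"}))
        assert fit_count_glmm(flipped, "n").effect == pytest.approx(
            1.0 / fit_count_glmm(df, "n").effect, rel=1e-3
        )

    def test_all_zero_arm_reports_profile_interval_with_warning(self):
        data = {}
        for i in range(10):
            first = "MHZC" if i % 2 else "CEC"
            second = "CEC" if first == "MHZC" else "MHZC"
            data[f"S{i}"] = {
                (1, first): 0 if first == "MHZC" else 2,
                (2, second): 0 if second == "MHZC" else 2,
            }
        df = crossover_frame(data).rename(columns={"y": "n"})
        fit = fit_count_glmm(df, "n")
        assert any("profile" in n for n in fit.notes)
        assert fit.effect_ci[0] <= fit.effect
        assert np.isfinite(fit.effect_ci[1])

    def test_agrees_with_lme4_quadrature_fit(self, tmp_path):
        """Independent oracle: glmer(..., nAGQ=15) on the same data."""
        rng = np.random.default_rng(7)
        models = (EndpointModel("n", "poisson", mu=np.log(1.2),
                                device_effect=np.log(0.3), sigma_subject=0.5),)
        df = balanced_trial(rng, models, n=30)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$device <- factor(d$device, levels=c("CEC","MHZC"))
            m <- glmer(n ~ device + factor(visit) + (1|subject),
                       data=d, family=poisson, nAGQ=15)
            cat(fixef(m)["deviceMHZC"])
        """)
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        lme4_coef = float(res.stdout.strip().split()[-1])
        fit = fit_count_glmm(df, "n")
        assert np.log(fit.effect) == pytest.approx(lme4_coef, abs=2e-3)


class TestBinaryGLMM:
    def test_identical_outcomes_per_device_give_unit_odds_ratio(self):
        data = {}
        outcomes = [0, 1, 0, 0, 1, 1, 0, 1, 0, 0]
        for i, y in enumerate(outcomes):
            first = "MHZC" if i % 2 else "CEC"
            second = "CEC" if first == "MHZC" else "MHZC"
            data[f"S{i}"] = {(1, first): y, (2, second): y}
        df = crossover_frame(data).rename(columns={"y": "haem"})
        fit = fit_binary_glmm(df, "haem")
        assert fit.effect == pytest.approx(1.0, abs=1e-2)

    def test_unadjusted_marginal_rates_imply_similar_odds_ratio(self):
        # two-proportion check: (0.10/0.90)/(0.29/0.71) ~ 0.27
        crude = (0.10 / 0.90) / (0.29 / 0.71)
        assert crude == pytest.approx(0.272, abs=0.001)
        assert abs(crude - 0.26) < 0.05  # same order as an adjusted estimate

    def test_odds_ratio_recovery_median_within_window(self):
        rng = np.random.default_rng(8)
        models = (EndpointModel("h", "bernoulli", mu=np.log(0.29 / 0.71),
                                device_effect=np.log(0.26), sigma_subject=1.0),)
        est = [
            fit_binary_glmm(balanced_trial(rng, models, dropout=1 / 42), "h").effect
            for _ in range(80)
        ]
        assert 0.18 <= np.median(est) <= 0.36

    def test_zero_variance_data_matches_plain_logistic_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        models = (EndpointModel("h", "bernoulli", mu=-0.5,
                                device_effect=-1.0, sigma_subject=0.0),)
        df = balanced_trial(rng, models, n=40)
        fit = fit_binary_glmm(df, "h", fixed_sigma=1e-6)
        X = np.column_stack([
            np.ones(len(df)),
            (df.device == "MHZC").to_numpy(float),
            (df.visit == 2).to_numpy(float),
        ])
        glm = sm.GLM(df["h"].astype(float).to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        assert np.log(fit.effect) == pytest.approx(glm.params[1], abs=1e-4)

    def test_medical_history_covariate_accepted(self):
        rng = np.random.default_rng(10)
        models = (EndpointModel("h", "bernoulli", mu=-0.8,
                                device_effect=-1.2, sigma_subject=0.8),)
        df = balanced_trial(rng, models, n=30)
        fit = fit_binary_glmm(df, "h", covariates=("medical_history",))
        assert "medical_history" in fit.covariates
        assert 0 < fit.effect


class TestGatekeeping:
    def _fit(self, name, p):
        from cathflow.crossover_stats import ModelFit

        return ModelFit(
            endpoint=name, family="gaussian", effect_type="difference",
            effect=1.0, effect_ci=(0.5, 1.5), p_value=p,
            mean_mhzc=0.0, mean_mhzc_ci=(0, 0), mean_cec=1.0, mean_cec_ci=(1, 1),
            n_obs=84, n_subjects=42,
        )

    def test_both_small_p_values_pass(self):
        g = gatekeep([self._fit("rv1", 0.001), self._fit("stops", 0.001)])
        assert g.decisions == ("rejected", "rejected")
        assert g.overall_pass

    def test_first_failure_blocks_later_tests(self):
        g = gatekeep([self._fit("rv1", 0.2), self._fit("stops", 0.001)])
        assert g.decisions == ("retained", "not tested")
        assert not g.overall_pass

    def test_middle_failure_leaves_tail_untested(self):
        g = gatekeep([self._fit("a", 0.01), self._fit("b", 0.7), self._fit("c", 0.001)])
        assert g.decisions == ("rejected", "retained", "not tested")

    def test_empty_fit_list_rejected(self):
        with pytest.raises(DataError):
            gatekeep([])


class TestWilcoxonSignedRank:
    def test_all_positive_five_differences_exact_one_sided(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], alternative="greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 32)

    def test_antisymmetric_pair_has_p_one(self):
        res = wilcoxon_signed_rank([-2, 2])
        assert res.p_value == pytest.approx(1.0)

    def test_zero_differences_dropped_and_all_zero_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0 and res.method == "degenerate"
        res2 = wilcoxon_signed_rank([0.0, 1.0, -2.0, 0.0])
        assert res2.n_used == 2

    def test_exact_distribution_matches_full_enumeration(self, rng):
        """Brute force over all 2^n sign assignments, with ties."""
        for d in ([1.5, 2.5, 2.5, 4.0, 1.0, 3.0], [1, 1, 2, 2, 3, 4, 5]):
            d = np.asarray(d, float)
            ranks = stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            ge = eq_le = ge_n = 0
            n = len(d)
            total = 0
            le = 0
            for signs in itertools.product([0, 1], repeat=n):
                w = sum(r for s, r in zip(signs, ranks) if s)
                total += 1
                if w >= w_obs - 1e-12:
                    ge += 1
                if w <= w_obs + 1e-12:
                    le += 1
            expected_two = min(1.0, 2 * min(ge / total, le / total))
            res = wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(expected_two, abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            d = rng.normal(0.3, 1.0, size=12)
            ours = wilcoxon_signed_rank(d)
            ref = stats.wilcoxon(d, mode="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_moderate_n(self, rng):
        # same data, both routes: exact (n<=25) vs the large-sample formula
        for _ in range(10):
            d = rng.normal(0.4, 1.0, size=15)
            exact = wilcoxon_signed_rank(d).p_value
            big = np.concatenate([d] * 2)  # n=30 forces the approximation
            approx_same = stats.wilcoxon(d, mode="approx", correction=True).pvalue
            assert abs(exact - approx_same) < 0.02
            assert wilcoxon_signed_rank(big).method == "normal-approx"

    def test_within_subject_differences_orientation(self):
        df = crossover_frame({
            "S1": {(1, "CEC"): 10.0, (2, "MHZC"): 4.0},
            "S2": {(1, "MHZC"): 2.0, (2, "CEC"): 9.0},
        })
        d = within_subject_differences(df, "y")
        np.testing.assert_allclose(np.sort(d), [6.0, 7.0])


class TestSummaries:
    def _ratio_fit(self, name, ratio, effect_type="rate_ratio"):
        from cathflow.crossover_stats import ModelFit

        return ModelFit(
            endpoint=name, family="poisson", effect_type=effect_type,
            effect=ratio, effect_ci=(ratio / 2, ratio * 2), p_value=0.001,
            mean_mhzc=0.17, mean_mhzc_ci=(0.06, 0.45),
            mean_cec=1.09, mean_cec_ci=(0.75, 1.60),
            n_obs=83, n_subjects=42,
        )

    def test_percent_reduction_lines_for_ratios(self):
        summ = summarize_trial([
            self._ratio_fit("n_flow_stops", 0.16),
            self._ratio_fit("haematuria", 0.26, "odds_ratio"),
        ])
        assert percent_reduction(0.16) == pytest.approx(84.0)
        assert percent_reduction(0.26) == pytest.approx(74.0)
        assert any("84% less likely" in h for h in summ.headlines)
        assert any("74% less likely" in h for h in summ.headlines)

    def test_difference_headline_from_device_means(self):
        from cathflow.crossover_stats import ModelFit

        fit = ModelFit(
            endpoint="rv1", family="gaussian", effect_type="difference",
            effect=34.30, effect_ci=(14.69, 53.91), p_value=0.001,
            mean_mhzc=5.10, mean_mhzc_ci=(2.79, 7.42),
            mean_cec=39.40, mean_cec_ci=(19.92, 58.89),
            n_obs=83, n_subjects=42,
        )
        summ = summarize_trial([fit])
        assert fit.mean_cec - fit.mean_mhzc == pytest.approx(34.30)
        assert "34.30" in summ.headlines[0]
        md = summ.to_markdown()
        assert "rv1" in md and "34.30" in md
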