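import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from dnbkit import (
    ScoreModel,
    SurvivalSimConfig,
    build_score_model,
    cox_multivariate,
    cox_univariate,
    de_filter,
    fraction_correlation,
    generate_survival_cohort,
    km_logrank,
    median_stratify,
    response_cutoff,
    response_table,
    score_subjects,
)


def breslow_partial_loglik(beta: float, times, events, x) -> float:
    """Brute-force Breslow partial log-likelihood (independent oracle)."""
    order = np.argsort(times)
    times, events, x = (np.asarray(v)[order] for v in (times, events, x))
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestDeFilter:
    def test_identical_distributions_not_selected(self, survival_cohort):
        cohort, _ = survival_cohort
        cohort = type(cohort)(
            survival=cohort.survival,
            expression=cohort.expression.copy(),
            tissue=cohort.tissue,
        )
        # make one gene literally identical across tissues
        cohort.expression.loc["G010"] = 1.5
        out = de_filter(cohort)
        assert not out.loc["G010", "selected"]

    def test_clean_separation_is_extreme_and_selected(self):
        """All tumor values above all normal values at n=10+10: the
        rank-sum statistic sits at its enumeration maximum (U = 100)."""
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            {f"T{i}": [5.0 + rng.random()] for i in range(10)}
            | {f"N{i}": [0.0 + rng.random()] for i in range(10)},
            index=["g1"],
        )
        surv = pd.DataFrame(
            {"time": np.arange(1, 11.0), "event": 1},
            index=pd.Index([f"T{i}" for i in range(10)], name="subject_id"),
        )
        from dnbkit.io import SurvivalCohort

        cohort = SurvivalCohort(
            survival=surv, expression=expr,
            tissue=pd.Series(["tumor"] * 10 + ["normal"] * 10, index=expr.columns),
        )
        out = de_filter(cohort)
        assert out.loc["g1", "stat"] == 100.0  # max of the U enumeration
        assert out.loc["g1", "selected"]

    def test_fdr_and_power_at_synthetic_design(self):
        """de_shift = 2 at n = 100+100: >= 95% of shifted genes selected
        and empirical FDR <= 7% over 20 seeds."""
        power, fdr_num, fdr_den = [], 0, 0
        for seed in range(20):
            cfg = SurvivalSimConfig(
                n_subjects=100, n_normal=100, n_genes=100,
                true_betas=[0.0] * 100, de_genes=list(range(20)),
                de_shift=2.0, censor_rate=0.0, seed=seed,
            )
            cohort, truth = generate_survival_cohort(cfg)
            out = de_filter(cohort)
            selected = set(out.index[out["selected"]])
            de = set(truth["de_genes"])
            power.append(len(selected & de) / len(de))
            fdr_num += len(selected - de)
            fdr_den += max(len(selected), 1)
        assert np.mean(power) >= 0.95
        assert fdr_num / fdr_den <= 0.07


class TestCoxUnivariate:
    def test_constant_covariate_gives_zero_beta(self, survival_cohort):
        cohort, _ = survival_cohort
        cohort.expression.loc["G015"] = 2.0
        res = cox_univariate(cohort, "G015")
        assert res.beta == 0.0 and res.p == 1.0

    def test_toy_matches_grid_search_oracle(self, toy_cox_cohort):
        """Six untied deaths: the fitted beta equals brute-force
        maximisation of the Breslow partial likelihood to 1e-4."""
        res = cox_univariate(toy_cox_cohort, "gX")
        surv = toy_cox_cohort.survival
        x = toy_cox_cohort.expression.loc["gX", surv.index].to_numpy()
        opt = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, surv["time"], surv["event"], x),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-8},
        )
        assert res.beta == pytest.approx(opt.x, abs=1e-4)

    def test_recovers_true_beta_at_n1000(self):
        cfg = SurvivalSimConfig(
            n_subjects=1000, n_genes=1, true_betas=[0.7], censor_rate=0.005, seed=30
        )
        cohort, _ = generate_survival_cohort(cfg)
        res = cox_univariate(cohort, "G000")
        assert abs(res.beta - 0.7) <= 0.15


class TestScoreModel:
    def test_filter_composition(self):
        """Panel of 3: one gene passes both filters, one fails DE, one
        fails Cox -> model retains exactly one gene."""
        cfg = SurvivalSimConfig(
            n_subjects=300, n_genes=3, true_betas=[1.0, 1.0, 0.0],
            de_genes=[0, 2], de_shift=3.0, censor_rate=0.005, seed=5,
        )
        cohort, _ = generate_survival_cohort(cfg)
        model = build_score_model(cohort, ["G000", "G001", "G002"])
        assert model.genes == ["G000"]

    def test_true_signal_genes_retained(self):
        """Genes with both a hazard effect and a DE shift are kept at
        >= 90% rate (n = 600, 20 seeds)."""
        kept = 0
        for seed in range(20):
            cfg = SurvivalSimConfig(
                n_subjects=600, n_genes=10,
                true_betas=[0.7, 0.5, -0.6] + [0.0] * 7,
                de_shift=2.0, censor_rate=0.005, seed=seed,
            )
            cohort, truth = generate_survival_cohort(cfg)
            model = build_score_model(cohort, list(cohort.expression.index))
            signal = [g for g, b in truth["betas"].items() if b != 0]
            kept += sum(g in model.genes for g in signal) / len(signal)
        assert kept / 20 >= 0.90

    def test_round_trip(self, tmp_path):
        model = ScoreModel(
            genes=["a", "b"], betas={"a": 0.123456789, "b": -1.5},
            provenance={"alpha_cox": 0.05},
        )
        model.to_files(tmp_path / "m.csv", tmp_path / "m.json")
        back = ScoreModel.from_files(tmp_path / "m.csv", tmp_path / "m.json")
        assert back.genes == model.genes
        assert back.betas == model.betas

    def test_score_arithmetic_and_linearity(self):
        model = ScoreModel(genes=["g1", "g2"], betas={"g1": 0.5, "g2": -0.2})
        expr = pd.DataFrame({"s1": [2.0, 1.0]}, index=["g1", "g2"])
        assert score_subjects(model, expr)["s1"] == pytest.approx(0.8)
        doubled = score_subjects(model, expr * 2)
        assert doubled["s1"] == pytest.approx(1.6)

    def test_zero_betas_zero_scores(self):
        model = ScoreModel(genes=["g1"], betas={"g1": 0.0})
        expr = pd.DataFrame({"s1": [3.0], "s2": [-1.0]}, index=["g1"])
        assert (score_subjects(model, expr) == 0).all()

    def test_missing_gene_raises(self):
        model = ScoreModel(genes=["g1", "g9"], betas={"g1": 0.5, "g9": 1.0})
        expr = pd.DataFrame({"s1": [2.0]}, index=["g1"])
        with pytest.raises(KeyError, match="g9"):
            score_subjects(model, expr)

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=8, unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gene_order_invariance(self, values):
        genes = [f"g{i}" for i in range(len(values))]
        betas = {g: 0.1 * i for i, g in enumerate(genes)}
        model_fwd = ScoreModel(genes=genes, betas=betas)
        model_rev = ScoreModel(genes=genes[::-1], betas=betas)
        expr = pd.DataFrame({"s": values}, index=genes)
        assert score_subjects(model_fwd, expr)["s"] == pytest.approx(
            score_subjects(model_rev, expr)["s"]
        )


class TestMedianStratify:
    def test_even_split(self):
        groups = median_stratify(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert list(groups) == ["low", "low", "high", "high"]

    def test_subject_at_median_goes_low(self):
        """"High" is strictly above the median, so the middle subject of an
        odd-sized cohort is low."""
        groups = median_stratify(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert groups["b"] == "low"
        assert (groups == "low").sum() == 2

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_stratify(pd.Series([5.0, 5.0, 5.0]))

    @given(st.lists(st.integers(-1000, 1000), min_size=2, max_size=40, unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_groups_partition_and_balance(self, values):
        scores = pd.Series(
            [float(v) for v in values], index=[f"s{i}" for i in range(len(values))]
        )
        groups = median_stratify(scores)
        n_low, n_high = (groups == "low").sum(), (groups == "high").sum()
        assert n_low + n_high == len(values)
        # with unique scores the median split is balanced to within one
        assert abs(n_low - n_high) <= 1


class TestKmLogrank:
    def test_identical_groups_null(self):
        times = pd.Series([1.0, 2, 3, 4, 1, 2, 3, 4])
        events = pd.Series([1, 1, 0, 1, 1, 1, 0, 1])
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        _, chi2, p = km_logrank(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_product_limit_values(self):
        """Hand-computed product-limit: deaths at 1,2,4,6 and censorings at
        3,5 give S = 5/6, 2/3, 4/9, 0."""
        times = pd.Series([1.0, 2, 3, 4, 5, 6, 10, 11])
        events = pd.Series([1, 1, 0, 1, 0, 1, 1, 1])
        groups = pd.Series(["a"] * 6 + ["b"] * 2)
        tables, _, _ = km_logrank(times, events, groups)
        surv = tables["a"].set_index("time")["survival"]
        assert surv[1.0] == pytest.approx(5 / 6)
        assert surv[2.0] == pytest.approx(2 / 3)
        assert surv[4.0] == pytest.approx(4 / 9)
        assert surv[6.0] == pytest.approx(0.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(3)
        times = pd.Series(rng.exponential(10, 40).round(3))
        events = pd.Series(np.ones(40, dtype=int))
        groups = pd.Series(["a"] * 20 + ["b"] * 20)
        tables, _, _ = km_logrank(times, events, groups)
        for label, mask in (("a", groups == "a"), ("b", groups == "b")):
            table = tables[label]
            t_grp = times[mask]
            for _, row in table.iterrows():
                if row["time"] > 0:
                    emp = (t_grp > row["time"]).mean()
                    assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_km_survival_monotone_nonincreasing(self):
        times = pd.Series([3.0, 1, 4, 1, 5, 9, 2, 6])
        events = pd.Series([1, 0, 1, 1, 0, 1, 1, 1])
        groups = pd.Series(["a"] * 4 + ["b"] * 4)
        tables, _, _ = km_logrank(times, events, groups)
        for table in tables.values():
            surv = table["survival"].to_numpy()
            assert (np.diff(surv) <= 1e-12).all()
            assert ((surv >= 0) & (surv <= 1)).all()


class TestCoxMultivariate:
    def test_score_effect_isolated_from_null_covariates(self):
        """When the score group drives the hazard and age/stage are noise,
        the score HR is significantly away from 1 and covariate HRs sit
        near 1 (n = 600)."""
        cfg = SurvivalSimConfig(
            n_subjects=600, n_genes=2, true_betas=[0.9, 0.0],
            censor_rate=0.005, seed=14,
        )
        cohort, _ = generate_survival_cohort(cfg)
        model = ScoreModel(genes=["G000"], betas={"G000": 0.9})
        scores = score_subjects(model, cohort.expression[cohort.tumor_subjects])
        groups = median_stratify(scores)
        table = cox_multivariate(cohort, groups).set_index("term")
        assert table.loc["score_high", "p"] < 0.001
        assert table.loc["score_high", "HR"] > 1.5
        for cov in ("age", "stage"):
            assert 0.8 < table.loc[cov, "HR"] < 1.25

    def test_collinear_covariates_rejected(self, survival_cohort):
        cohort, _ = survival_cohort
        cohort = type(cohort)(
            survival=cohort.survival.assign(age2=cohort.survival["age"]),
            expression=cohort.expression,
            tissue=cohort.tissue,
        )
        groups = pd.Series("low", index=cohort.survival.index)
        groups.iloc[::2] = "high"
        with pytest.raises(ValueError, match="collinear"):
            cox_multivariate(cohort, groups, covariates=("age", "age2"))


class TestResponseCutoff:
    def test_perfect_separation(self):
        scores = pd.Series([0.1, 0.2, 0.3, 1.1, 1.2, 1.3], index=list("abcdef"))
        labels = pd.Series(
            ["PR", "PR", "PR", "non-PR", "non-PR", "non-PR"], index=list("abcdef")
        )
        out = response_cutoff(scores, labels)
        assert out["auc"] == pytest.approx(1.0)
        assert 0.3 <= out["cutoff"] < 1.1
        assert (out["groups"][list("abc")] == "low").all()

    def test_null_labels_auc_near_half(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(size=200))
        labels = pd.Series(np.where(rng.random(200) < 0.3, "PR", "non-PR"))
        out = response_cutoff(scores, labels)
        # oriented AUC folds the null to >= 0.5; binomial band at n=200
        assert 0.5 <= out["auc"] < 0.62

    def test_single_class_rejected(self):
        scores = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError, match="both response classes"):
            response_cutoff(scores, pd.Series(["PR", "PR"]))

    def test_printed_validation_tabulation(self):
        """21 subjects, 14 low with 5 PR, 7 high with 0 PR: PR rates
        35.7% / 0% and 23.8% overall."""
        groups = pd.Series(["low"] * 14 + ["high"] * 7)
        labels = pd.Series(["PR"] * 5 + ["non-PR"] * 9 + ["non-PR"] * 7)
        table = response_table(groups, labels).set_index("group")
        assert table.loc["low", "pr_rate_pct"] == 35.7
        assert table.loc["high", "pr_rate_pct"] == 0.0
        assert table.loc["overall", "pr_rate_pct"] == 23.8


class TestFractionCorrelation:
    def test_monotone_transform_gives_rho_one(self):
        scores = pd.Series([0.5, 1.5, 0.1, 2.2, 0.9], index=list("abcde"))
        fractions = pd.DataFrame([np.exp(scores)], index=["CAF"])
        out = fraction_correlation(scores, fractions)
        assert out.loc["CAF", "rho"] == pytest.approx(1.0)

    def test_perfect_anti_monotone(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        fractions = pd.DataFrame([[5.0, 4, 3, 2, 1]], columns=list("abcde"), index=["NK"])
        out = fraction_correlation(scores, fractions)
        assert out.loc["NK", "rho"] == pytest.approx(-1.0)

    def test_null_fractions_uniform_p(self):
        """Independent fractions: |rho| small on average and p-values
        roughly uniform over 200 simulated cell types."""
        rng = np.random.default_rng(9)
        scores = pd.Series(rng.normal(size=60), index=[f"s{i}" for i in range(60)])
        fractions = pd.DataFrame(
            rng.normal(size=(200, 60)),
            index=[f"ct{i}" for i in range(200)],
            columns=scores.index,
        )
        out = fraction_correlation(scores, fractions)
        assert out["rho"].abs().mean() < 0.2
        # uniformity: roughly 10% of p-values below 0.1
        frac_small = (out["p"] < 0.1).mean()
        assert 0.03 < frac_small < 0.2

    def test_insufficient_overlap_rejected(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        fractions = pd.DataFrame([[0.1, 0.2]], columns=["a", "b"], index=["CAF"])
        with pytest.raises(ValueError, match="overlap"):
            fraction_correlation(scores, fractions)
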