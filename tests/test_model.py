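import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dosegap.model import (
    Covariate,
    SelectionThresholds,
    SeparationError,
    StepwiseResult,
    covariates_from_schema,
    fit_logistic,
    lr_pvalue,
    significance_stars,
    stepwise_select,
    table2_report,
)
from dosegap.model import _build_design, _complete_mask, _fit_on


def two_by_two_frame(n11, n01, n10, n00) -> pd.DataFrame:
    """Outcome y vs binary x with cells (y=1,x=1), (y=0,x=1), (y=1,x=0), (y=0,x=0)."""
    rows = (
        [{"y": 1, "x": 1}] * n11
        + [{"y": 0, "x": 1}] * n01
        + [{"y": 1, "x": 0}] * n10
        + [{"y": 0, "x": 0}] * n00
    )
    return pd.DataFrame(rows)


def simulate_logistic(rng, n, prevalences, betas, intercept) -> pd.DataFrame:
    data = {"_eta": np.full(n, float(intercept))}
    for name, prev in prevalences.items():
        x = (rng.random(n) < prev).astype(int)
        data[name] = x
        data["_eta"] = data["_eta"] + betas.get(name, 0.0) * x
    p = 1 / (1 + np.exp(-data.pop("_eta")))
    data["y"] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(data)


class TestFitLogistic:
    def test_closed_form_or_from_2x2(self):
        """One binary covariate: the MLE odds ratio is the cross-product ratio."""
        frame = two_by_two_frame(70, 31, 341, 111)
        fit = _fit_on(frame, "y", [Covariate("x")])
        expected = (70 * 111) / (31 * 341)
        assert math.exp(fit.params[1]) == pytest.approx(expected, rel=1e-6)
        assert fit.converged

    def test_intercept_only_matches_log_odds(self):
        frame = pd.DataFrame({"y": [1] * 30 + [0] * 70})
        fit = _fit_on(frame, "y", [])
        assert fit.params[0] == pytest.approx(math.log(30 / 70), rel=1e-8)

    def test_constant_outcome_rejected(self):
        frame = pd.DataFrame({"y": [1, 1, 1], "x": [0, 1, 0]})
        with pytest.raises(ValueError, match="single class"):
            _fit_on(frame, "y", [Covariate("x")])

    def test_perfect_separation_detected(self):
        frame = pd.DataFrame({"y": [0] * 20 + [1] * 20, "x": [0] * 20 + [1] * 20})
        with pytest.raises(SeparationError):
            _fit_on(frame, "y", [Covariate("x")])

    def test_rank_deficient_design_rejected(self):
        y = np.array([0, 1, 0, 1])
        X = np.array([[1.0, 2.0, 4.0]] * 4)
        with pytest.raises((ValueError, SeparationError)):
            fit_logistic(y, X, ["a", "b", "c"])

    def test_matches_statsmodels(self):
        """Independent route: same MLE as statsmodels GLM on random data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        frame = simulate_logistic(
            rng, 500, {"a": 0.4, "b": 0.6}, {"a": -0.8, "b": 0.5}, intercept=0.3
        )
        fit = _fit_on(frame, "y", [Covariate("a"), Covariate("b")])
        X = sm.add_constant(frame[["a", "b"]].to_numpy(dtype=float))
        ref = sm.GLM(frame["y"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert fit.params == pytest.approx(ref.params, abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        assert np.sqrt(np.diag(fit.cov_params)) == pytest.approx(ref.bse, abs=1e-5)


class TestLrPvalue:
    def test_identical_models_give_p_one(self):
        frame = two_by_two_frame(20, 10, 15, 15)
        fit = _fit_on(frame, "y", [Covariate("x")])
        assert lr_pvalue(fit, fit) == 1.0

    def test_non_nested_rejected(self):
        frame = pd.DataFrame(
            {"y": [0, 1] * 20, "a": [0, 1, 1, 0] * 10, "b": [1, 1, 0, 0] * 10}
        )
        fit_a = _fit_on(frame, "y", [Covariate("a")])
        fit_b = _fit_on(frame, "y", [Covariate("b")])
        with pytest.raises(ValueError, match="nested"):
            lr_pvalue(fit_a, fit_b)

    def test_different_n_rejected(self):
        frame = two_by_two_frame(20, 10, 15, 15)
        fit_all = _fit_on(frame, "y", [Covariate("x")])
        fit_half = _fit_on(frame.iloc[::2], "y", [Covariate("x")])
        with pytest.raises(ValueError, match="observations"):
            lr_pvalue(fit_half, fit_all)

    def test_null_covariate_p_uniform(self):
        """Under H0 the LR p-value is Uniform(0,1): KS sanity check."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            frame = simulate_logistic(rng, 400, {"x": 0.5}, {}, intercept=0.4)
            small = _fit_on(frame, "y", [])
            large = _fit_on(frame, "y", [Covariate("x")])
            pvals.append(lr_pvalue(small, large))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_covariate_tiny_p(self):
        """True OR 0.3 at n=2000: p < 1e-6 in at least 99% of replicates."""
        rng = np.random.default_rng(12)
        tiny = 0
        n_rep = 100
        for _ in range(n_rep):
            frame = simulate_logistic(rng, 2000, {"x": 0.5}, {"x": math.log(0.3)}, intercept=0.5)
            small = _fit_on(frame, "y", [])
            large = _fit_on(frame, "y", [Covariate("x")])
            if lr_pvalue(small, large) < 1e-6:
                tiny += 1
        assert tiny >= 0.99 * n_rep


class TestStepwiseSelect:
    def test_empty_candidates_intercept_only(self):
        frame = pd.DataFrame({"y": [0, 1, 1, 0, 1]})
        result = stepwise_select(frame, "y", [])
        assert result.selected == ()
        assert result.trace == ()
        assert result.fit is not None and result.fit.term_names == ("(intercept)",)

    def test_single_strong_covariate_selected(self):
        rng = np.random.default_rng(21)
        frame = simulate_logistic(rng, 2000, {"x": 0.5}, {"x": math.log(0.5)}, intercept=1.0)
        result = stepwise_select(frame, "y", [Covariate("x")])
        assert result.selected == ("x",)
        assert result.trace[0].action == "enter"
        assert result.trace[0].p_value <= 0.25

    def test_null_entry_rate_matches_threshold(self):
        """A single null candidate enters in ~25% of replicates (p_enter=0.25)."""
        rng = np.random.default_rng(22)
        n_rep = 200
        entered = 0
        for _ in range(n_rep):
            frame = simulate_logistic(rng, 400, {"x": 0.5}, {}, intercept=0.6)
            result = stepwise_select(frame, "y", [Covariate("x")])
            entered += "x" in result.selected
        rate = entered / n_rep
        assert abs(rate - 0.25) <= 4 * math.sqrt(0.25 * 0.75 / n_rep)

    def test_parameter_recovery_single_candidate(self):
        """True OR 0.5 at n=2000: selected in >=99% of replicates, mean OR within 15%."""
        rng = np.random.default_rng(23)
        n_rep = 100
        selected = 0
        ors = []
        for _ in range(n_rep):
            frame = simulate_logistic(rng, 2000, {"x": 0.4}, {"x": math.log(0.5)}, intercept=1.2)
            result = stepwise_select(frame, "y", [Covariate("x")])
            if "x" in result.selected:
                selected += 1
                ors.append(math.exp(result.coefficients["x"]))
        assert selected >= 0.99 * n_rep
        assert abs(np.mean(ors) - 0.5) <= 0.15 * 0.5

    def test_determinism(self):
        rng = np.random.default_rng(24)
        frame = simulate_logistic(
            rng, 800, {"a": 0.5, "b": 0.3, "c": 0.4},
            {"a": -0.7, "b": 0.4}, intercept=0.8,
        )
        cands = [Covariate("a"), Covariate("b"), Covariate("c")]
        r1 = stepwise_select(frame, "y", cands)
        r2 = stepwise_select(frame, "y", cands)
        assert r1.selected == r2.selected
        assert r1.trace == r2.trace
        assert np.array_equal(r1.fit.params, r2.fit.params)

    def test_selected_covariates_satisfy_stay_threshold(self):
        rng = np.random.default_rng(25)
        frame = simulate_logistic(
            rng, 600, {"a": 0.5, "b": 0.3, "c": 0.4, "d": 0.6},
            {"a": -0.9}, intercept=0.8,
        )
        cands = [Covariate(n) for n in "abcd"]
        result = stepwise_select(frame, "y", cands)
        # refit dropping each selected covariate: its stay p must be <= 0.3
        rows = frame.loc[_complete_mask(frame, result.covariates)]
        full = _fit_on(rows, "y", list(result.covariates))
        for cov in result.covariates:
            small = _fit_on(rows, "y", [c for c in result.covariates if c is not cov])
            assert lr_pvalue(small, full) <= 0.3 + 1e-12

    def test_trace_replay_reproduces_model(self):
        rng = np.random.default_rng(26)
        frame = simulate_logistic(
            rng, 700, {"a": 0.5, "b": 0.3, "c": 0.4},
            {"a": -0.8, "c": 0.5}, intercept=0.5,
        )
        cands = {n: Covariate(n) for n in "abc"}
        result = stepwise_select(frame, "y", list(cands.values()))
        replayed: list[Covariate] = []
        for step in result.trace:
            if step.action == "enter":
                replayed.append(cands[step.covariate])
            else:
                replayed = [c for c in replayed if c.name != step.covariate]
        rows = frame.loc[_complete_mask(frame, replayed)]
        refit = _fit_on(rows, "y", replayed)
        assert tuple(c.name for c in replayed) == result.selected
        assert np.array_equal(refit.params, result.fit.params)

    def test_iterative_complete_cases_grow_when_missing_covariate_dropped(self):
        """N1 is recomputed from the selected covariates only."""
        rng = np.random.default_rng(27)
        frame = simulate_logistic(rng, 900, {"a": 0.5, "b": 0.4}, {"a": -1.0}, intercept=0.7)
        frame.loc[frame.index[:300], "b"] = np.nan  # b missing for a third of patients
        result = stepwise_select(frame, "y", [Covariate("a"), Covariate("b")])
        if "b" not in result.selected:
            assert result.n_complete_cases == 900
        else:
            assert result.n_complete_cases == 600

    def test_categorical_block_entry(self):
        rng = np.random.default_rng(28)
        n = 1500
        level = rng.choice(["lo", "mid", "hi"], size=n, p=[0.4, 0.35, 0.25])
        eta = 0.8 - 1.2 * (level == "hi")
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        frame = pd.DataFrame({"y": y, "g": level})
        cov = Covariate("g", kind="categorical", levels=("lo", "mid", "hi"))
        result = stepwise_select(frame, "y", [cov])
        assert result.selected == ("g",)
        assert set(result.fit.term_names) == {"(intercept)", "g[mid]", "g[hi]"}

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            SelectionThresholds(p_enter=0.0)
        with pytest.raises(ValueError):
            SelectionThresholds(p_stay=1.0)


class TestTable2Report:
    def test_counts_and_stars(self):
        frame = two_by_two_frame(70, 31, 341, 111)
        result = stepwise_select(frame, "y", [Covariate("x")])
        report = table2_report(frame, "y", result)
        by_level = {(r["covariate"], r["level"]): r for _, r in report.iterrows()}
        ref = by_level[("x", "0")]
        assert ref["is_reference"] and ref["stars"] == ""
        assert ref["n_persistent"] == 341 and ref["n1"] == 452
        assert ref["percent"] == 75.4
        yes = by_level[("x", "1")]
        assert yes["n_persistent"] == 70 and yes["n1"] == 101
        assert yes["percent"] == 69.3

    @pytest.mark.parametrize(
        "p, stars",
        [(0.2, ""), (0.05, "*"), (0.01, "**"), (0.001, "***"), (0.04, "*"), (1e-9, "***")],
    )
    def test_star_legend(self, p, stars):
        assert significance_stars(p) == stars

    def test_reference_never_starred(self):
        rng = np.random.default_rng(31)
        frame = simulate_logistic(rng, 1000, {"x": 0.5}, {"x": -2.0}, intercept=1.0)
        result = stepwise_select(frame, "y", [Covariate("x")])
        report = table2_report(frame, "y", result)
        assert (report.loc[report["is_reference"], "stars"] == "").all()
        assert (report.loc[~report["is_reference"], "wald_p"] < 0.05).all()


def test_covariates_from_schema():
    schema = {
        "covariates": [
            {"name": "b", "type": "binary"},
            {"name": "c", "type": "categorical", "levels": ["x", "y", "z"]},
            {"name": "n", "type": "number"},
        ]
    }
    covs = covariates_from_schema(schema)
    assert [c.name for c in covs] == ["b", "c"]
    assert covs[1].levels == ("x", "y", "z")
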