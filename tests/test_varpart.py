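"""Covariate preparation, REML mixed models, Nakagawa R² decomposition."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from microcontam import varpart
from microcontam.errors import FitError, InputError
from microcontam.varpart import LmmSpec, LMMFit, ModelFrame


def _frame(data, response="y", continuous=(), categorical=(),
           group="donor_id"):
    return ModelFrame(data=data, response=response,
                      continuous=list(continuous),
                      categorical=list(categorical), group=group)


class TestPrepareCovariates:
    def _meta(self):
        return pd.DataFrame({
            "donor_id": ["d1", "d1", "d2", "d2"] * 10,
            "cell_type": ["Sst Hspe Sema3c", "Sst Hspe Sema3c",
                          "Pvalb Reln Itm2a", "Pvalb Reln Itm2a"] * 10,
            "recording_time": [10.0, 11.5, 9.0, 12.0] * 10,
            "age": np.r_[np.full(20, 30.0), np.full(20, 50.0)],
            "sex": ["M", "M", "F", "F"] * 10,
            "iba1_score": [1.0, 1.5, 0.5, 2.0] * 10,
            "score": np.linspace(0, 1, 40),
        }, index=[f"c{i}" for i in range(40)])

    def test_breakin_from_recording_times(self):
        frame = varpart.prepare_covariates(
            self._meta(), response="score", time_col="recording_time",
            continuous=("break_in_time",), categorical=("sex",),
            histology_cols=(), min_cells_per_type=1)
        raw = self._meta()
        bt = raw["recording_time"] - raw.groupby("donor_id")[
            "recording_time"].transform("min")
        assert bt.loc["c1"] == 1.5 and bt.loc["c0"] == 0.0
        # scaled column keeps the ordering and is standardized
        col = frame.data["break_in_time"]
        assert abs(col.mean()) < 1e-8 and abs(col.std(ddof=1) - 1) < 1e-8

    def test_histology_binned_at_one(self):
        frame = varpart.prepare_covariates(
            self._meta(), response="score", continuous=("age",),
            categorical=(), histology_cols=("iba1_score",),
            min_cells_per_type=1)
        bins = frame.data["iba1_bin"]
        assert bins.loc["c0"] == "low" and bins.loc["c1"] == "high"

    def test_ttype_collapsed_to_two_tokens(self):
        assert varpart.collapse_ttype("Sst Hspe Sema3c") == "Sst Hspe"
        frame = varpart.prepare_covariates(
            self._meta(), response="score", continuous=(), categorical=(),
            histology_cols=(), min_cells_per_type=1)
        assert set(frame.data["ttype"]) == {"Sst Hspe", "Pvalb Reln"}

    def test_small_types_filtered(self):
        meta = self._meta()
        meta.loc["c0", "cell_type"] = "Vip Rare Type"
        frame = varpart.prepare_covariates(
            meta, response="score", continuous=(), categorical=(),
            histology_cols=(), min_cells_per_type=5)
        assert "Vip Rare" not in set(frame.data["ttype"])

    def test_missing_values_dropped_and_counted(self):
        meta = self._meta()
        meta.loc["c3", "age"] = np.nan
        frame = varpart.prepare_covariates(
            meta, response="score", continuous=("age",), categorical=(),
            histology_cols=(), min_cells_per_type=1)
        assert frame.n_dropped == 1 and "c3" not in frame.data.index

    def test_missing_donor_column_rejected(self):
        with pytest.raises(InputError):
            varpart.prepare_covariates(self._meta().drop(columns="donor_id"))


def _balanced_one_way(n_groups=20, n_per=10, sd_b=0.7, sd_e=0.5, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.repeat([f"d{i}" for i in range(n_groups)], n_per)
    effects = rng.normal(0, sd_b, n_groups)
    y = np.repeat(effects, n_per) + rng.normal(0, sd_e, len(groups))
    return pd.DataFrame({"y": y, "donor_id": groups})


class TestFitLmm:
    def test_zero_group_variance_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        n = 400
        data = pd.DataFrame({
            "x": rng.normal(size=n),
            "donor_id": rng.choice([f"d{i}" for i in range(10)], n),
        })
        data["y"] = 2.0 + 0.5 * data["x"] + rng.normal(0, 1, n)
        fit = varpart.fit_lmm(LmmSpec("y", ["x"], ["donor_id"]),
                              _frame(data, continuous=["x"]))
        ols = sm.OLS(data["y"], sm.add_constant(data["x"])).fit()
        assert fit.re_variances["donor_id"] < 0.05
        np.testing.assert_allclose(
            fit.fe_params.to_numpy(), ols.params.to_numpy(), atol=0.02)

    def test_reml_matches_anova_moment_estimator(self):
        # balanced one-way: REML between-group variance = (MSB - MSW) / n
        data = _balanced_one_way()
        fit = varpart.fit_lmm(LmmSpec("y", [], ["donor_id"]), _frame(data))
        stacked = data.pivot_table(index="donor_id", values="y",
                                   aggfunc=["mean", "count"])
        n_per = int(stacked[("count", "y")].iloc[0])
        grand = data["y"].mean()
        msb = n_per * ((stacked[("mean", "y")] - grand) ** 2).sum() / (
            len(stacked) - 1)
        msw = data.groupby("donor_id")["y"].apply(
            lambda g: ((g - g.mean()) ** 2).sum()).sum() / (
            len(data) - len(stacked))
        expected = max((msb - msw) / n_per, 0.0)
        assert fit.re_variances["donor_id"] == pytest.approx(expected,
                                                             rel=1e-3)

    def test_variance_components_recovered_across_seeds(self):
        # donor SD 0.5, residual SD 0.5, 50 donors x 20 cells
        ests_b, ests_e = [], []
        for seed in range(50):
            data = _balanced_one_way(n_groups=50, n_per=20, sd_b=0.5,
                                     sd_e=0.5, seed=seed)
            fit = varpart.fit_lmm(LmmSpec("y", [], ["donor_id"]),
                                  _frame(data))
            ests_b.append(fit.re_variances["donor_id"])
            ests_e.append(fit.resid_var)
        assert abs(np.mean(ests_b) - 0.25) / 0.25 < 0.2
        assert abs(np.mean(ests_e) - 0.25) / 0.25 < 0.2

    def test_aliased_term_dropped_with_record(self):
        data = _balanced_one_way()
        data["x"] = 1.0  # constant, aliased with the intercept
        fit = varpart.fit_lmm(LmmSpec("y", ["x"], ["donor_id"]),
                              _frame(data, continuous=["x"]))
        assert fit.dropped_terms == ["x"]

    def test_single_level_random_factor_rejected(self):
        data = _balanced_one_way(n_groups=1)
        with pytest.raises(InputError):
            varpart.fit_lmm(LmmSpec("y", [], ["donor_id"]), _frame(data))


class TestNakagawaR2:
    def _fit(self, var_f, var_a, var_e, n=101):
        rng = np.random.default_rng(0)
        fitted = rng.normal(size=n)
        fitted = fitted / fitted.std(ddof=1) * np.sqrt(var_f)
        return LMMFit(fe_params=pd.Series(dtype=float),
                      fe_bse=pd.Series(dtype=float),
                      re_variances={"donor_id": var_a}, resid_var=var_e,
                      fitted_fixed=fitted, llf=0.0, converged=True, n_obs=n,
                      spec=LmmSpec("y", [], ["donor_id"]))

    def test_direct_substitution(self):
        r2m, r2c = varpart.nakagawa_r2(self._fit(2.0, 1.0, 1.0))
        assert (r2m, r2c) == pytest.approx((0.5, 0.75))

    def test_intercept_only_marginal_is_zero(self):
        fit = self._fit(0.0, 1.0, 1.0)
        fit.fitted_fixed = np.full(101, 3.0)  # intercept only
        r2m, r2c = varpart.nakagawa_r2(fit)
        assert r2m == 0.0 and r2c == pytest.approx(0.5)

    def test_nonconverged_fit_refused(self):
        fit = self._fit(1.0, 1.0, 1.0)
        fit.converged = False
        with pytest.raises(FitError):
            varpart.nakagawa_r2(fit)

    def test_all_zero_variance_undefined(self):
        with pytest.raises(FitError):
            varpart.nakagawa_r2(self._fit(0.0, 0.0, 0.0))


class TestPartitionVariance:
    def test_single_factor_share_matches_anova_r2(self):
        rng = np.random.default_rng(5)
        n = 1000
        factor = rng.choice(list("ABC"), n)
        effect = pd.Series({"A": -0.5, "B": 0.0, "C": 0.7})
        donors = rng.choice([f"d{i}" for i in range(20)], n)
        y = effect.loc[factor].to_numpy() + rng.normal(0, 0.8, n)
        data = pd.DataFrame({"y": y, "factor": factor, "donor_id": donors})
        part = varpart.partition_variance(
            LmmSpec("y", ["factor"], ["donor_id"]),
            _frame(data, categorical=["factor"]))
        anova_r2 = sm.OLS.from_formula("y ~ C(factor)", data).fit().rsquared
        assert part.shares["factor"] == pytest.approx(anova_r2, abs=0.02)
        assert part.donor_share < 0.02

    def test_donor_share_is_conditional_minus_marginal(self):
        data = _balanced_one_way(n_groups=15, n_per=15, sd_b=0.8, sd_e=0.4,
                                 seed=3)
        rng = np.random.default_rng(3)
        data["x"] = rng.normal(size=len(data))
        data["y"] = data["y"] + 0.3 * data["x"]
        part = varpart.partition_variance(
            LmmSpec("y", ["x"], ["donor_id"]), _frame(data, continuous=["x"]))
        assert part.donor_share == pytest.approx(
            part.r2_conditional - part.r2_marginal)
        assert part.donor_share >= 0.0
        assert part.shares["x"] >= 0.0

    def test_continuous_factor_uses_quintile_random_intercept(self):
        rng = np.random.default_rng(7)
        n = 600
        data = pd.DataFrame({
            "x": rng.normal(size=n),
            "donor_id": rng.choice([f"d{i}" for i in range(12)], n),
        })
        data["y"] = 0.8 * data["x"] + rng.normal(0, 0.6, n)
        part = varpart.partition_variance(
            LmmSpec("y", ["x"], ["donor_id"]), _frame(data, continuous=["x"]))
        # a strong continuous effect must claim a large share
        assert part.shares["x"] > 0.3
        assert not part.failed
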