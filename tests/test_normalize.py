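import numpy as np
import pandas as pd
import pytest

from ctnorm import (CtTable, DeltaCtNormalizer, GlobalMeanNormalizer,
                    MeanCtRegressionNormalizer, MultipleRegressionNormalizer,
                    PerGeneRegressionNormalizer, delta_ct_normalize,
                    global_mean_normalize, make_normalizer,
                    mean_ct_regression_normalize,
                    multiple_regression_normalize,
                    per_gene_regression_normalize, reference_summary)
from ctnorm.exceptions import (CollinearityError, ConfigurationError,
                               FallbackWarning, OverfitError)
from ctnorm.normalize import FALLBACK_APPLIED, REGRESSION_APPLIED

from conftest import make_linear_table


def simple_table(ref, targets, extra_roles=None):
    cols = {"REF": list(ref)}
    roles = {"REF": "reference"}
    for name, vals in targets.items():
        cols[name] = list(vals)
        roles[name] = "target"
    samples = [f"S{i}" for i in range(len(ref))]
    return CtTable(pd.DataFrame(cols, index=samples), pd.Series(roles))


class TestReferenceSummary:
    def test_mean_and_geometric_mean_coincide_on_ct_scale(self, small_table):
        # geometric mean of 2^-Ct, mapped back to Ct, is the arithmetic
        # mean of Ct — an algebraic identity
        mean = reference_summary(small_table, "mean")
        geo = reference_summary(small_table, "geometric_mean")
        assert np.allclose(mean, geo)
        assert mean["S1"] == pytest.approx((20.0 + 18.0) / 2)

    def test_three_reference_example(self):
        t = simple_table([18.0, 19, 20], {"T1": [25.0, 26, 27]})
        t.values["REF2"] = [20.0, 21, 22]
        t.values["REF3"] = [22.0, 23, 24]
        roles = t.roles.copy()
        roles["REF2"] = roles["REF3"] = "reference"
        t = CtTable(t.values, roles)
        assert reference_summary(t, "mean")["S0"] == pytest.approx(20.0)
        assert reference_summary(t, "geomean")["S0"] == pytest.approx(20.0)

    def test_single_mode_returns_that_gene_unchanged(self, small_table):
        s = reference_summary(small_table, "single:REFB")
        assert s.equals(small_table.values["REFB"])

    def test_single_mode_rejects_non_reference(self, small_table):
        with pytest.raises(ConfigurationError):
            reference_summary(small_table, "single:T1")

    def test_all_references_missing_gives_missing_summary(self, small_table):
        vals = small_table.values.copy()
        vals.loc["S1", ["REFA", "REFB"]] = np.nan
        t = CtTable(vals, small_table.roles)
        assert np.isnan(reference_summary(t, "mean")["S1"])


class TestDeltaCt:
    def test_plain_subtraction(self):
        t = simple_table([20.0, 21, 19, 22], {"T1": [25.0, 26, 24, 27]})
        out = delta_ct_normalize(t)
        assert out.values["T1"].tolist() == [5.0, 5.0, 5.0, 5.0]

    def test_missing_target_stays_missing(self, small_table):
        out = delta_ct_normalize(small_table)
        assert np.isnan(out.values.at["S2", "T3"])
        assert out.values.notna().sum().sum() == 14

    def test_equals_slope_pinned_regression_exactly(self):
        # forcing every per-gene slope to 1 must reproduce ΔCt to 1e-12
        rng = np.random.default_rng(5)
        for seed in range(5):
            t = make_linear_table(b=rng.uniform(0.2, 1.5, 3), seed=seed,
                                  n=30)
            norm = PerGeneRegressionNormalizer(drop_outliers=False).fit(t)
            norm.slopes_ = pd.Series(1.0, index=norm.slopes_.index)
            pinned = norm.transform(t)
            dct = DeltaCtNormalizer(drop_outliers=False).fit_transform(t)
            assert np.nanmax(np.abs(pinned.values.to_numpy()
                                    - dct.values.to_numpy())) < 1e-12


class TestPerGeneRegression:
    def test_perfect_fit_example(self):
        # ref {1..}, target = 2*ref - 1: normalized = Ct - 2*ref = -1
        t = simple_table([1.0, 2, 3], {"T1": [1.0, 3, 5]})
        with pytest.warns(UserWarning):  # zero-residual fit
            out = per_gene_regression_normalize(t, drop_outliers=False)
        assert np.allclose(out.values["T1"], [-1.0, -1.0, -1.0])
        assert (out.flags == REGRESSION_APPLIED).all()

    def test_true_slope_one_reproduces_delta_ct(self):
        t = make_linear_table(b=1.0, sigma=0.0, seed=3, n_targets=1, n=20)
        with pytest.warns(UserWarning):
            out = per_gene_regression_normalize(t, drop_outliers=False)
        dct = delta_ct_normalize(t, drop_outliers=False)
        assert np.allclose(out.values, dct.values, atol=1e-9)

    def test_insignificant_slope_with_fallback_none_leaves_ct(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(25, 1, 20)
        tgt = rng.normal(30, 1, 20)  # independent of ref
        t = simple_table(ref, {"T1": tgt})
        out = per_gene_regression_normalize(t, fallback="none",
                                            drop_outliers=False)
        assert out.flags["T1"] == FALLBACK_APPLIED
        assert np.allclose(out.values["T1"], tgt)

    def test_insignificant_slope_with_delta_ct_fallback_subtracts(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(25, 1, 20)
        tgt = rng.normal(30, 1, 20)
        t = simple_table(ref, {"T1": tgt})
        out = per_gene_regression_normalize(t, fallback="delta_ct",
                                            drop_outliers=False)
        assert out.flags["T1"] == FALLBACK_APPLIED
        assert np.allclose(out.values["T1"], tgt - ref)

    def test_per_gene_fit_failure_falls_back_with_warning(self):
        t = simple_table([20.0, 21, 22, 23],
                         {"T1": [25.0, np.nan, np.nan, 26.0],  # 2 pairs
                          "T2": [25.0, 26, 27, 28]})
        with pytest.warns(FallbackWarning):
            out = per_gene_regression_normalize(t, drop_outliers=False)
        assert out.flags["T1"] == FALLBACK_APPLIED
        assert out.flags["T2"] == REGRESSION_APPLIED

    def test_dropped_samples_are_still_normalized(self):
        # an outlying sample is excluded from fitting but transformed
        ref = [20.0, 20.2, 19.8, 20.1, 19.9, 35.0]
        t = simple_table(ref, {"T1": [25.0, 25.1, 24.9, 25.0, 25.1, 30.0]})
        t2 = CtTable(t.values.assign(REF2=ref), pd.Series(
            {"REF": "reference", "REF2": "reference", "T1": "target"}))
        norm = PerGeneRegressionNormalizer(fallback="delta_ct").fit(t2)
        assert norm.fitting_samples_ == [f"S{i}" for i in range(5)]
        out = norm.transform(t2)
        assert not np.isnan(out.values.at["S5", "T1"])

    def test_transform_is_missing_where_reference_missing(self):
        t = make_linear_table(b=0.5, seed=1, n_targets=1, n=20)
        vals = t.values.copy()
        vals.loc["S000", "REF"] = np.nan
        t2 = CtTable(vals, t.roles)
        norm = PerGeneRegressionNormalizer(drop_outliers=False)
        out = norm.fit_transform(t2)
        assert np.isnan(out.values.at["S000", "T1"])


class TestMeanCtRegression:
    def test_targets_equal_summary_give_slope_one_zero_output(self):
        ref = [20.0, 21, 22, 23]
        t = simple_table(ref, {"T1": ref, "T2": ref})
        with pytest.warns(UserWarning):
            out = mean_ct_regression_normalize(t, drop_outliers=False)
        assert out.model.effective_coefficients.iloc[0, 0] == pytest.approx(1.0)
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_recovers_common_slope_noise_free(self):
        t = make_linear_table(b=0.5, sigma=0.0, seed=2, n_targets=3, n=30)
        with pytest.warns(UserWarning):
            norm = MeanCtRegressionNormalizer(drop_outliers=False).fit(t)
        assert norm.shared_slope_ == pytest.approx(0.5, abs=1e-10)
        out = norm.transform(t)
        # with the exact slope removed only the intercept a = 5 remains
        assert np.allclose(out.values, 5.0, atol=1e-8)

    def test_noisy_shared_slope_decorrelates_the_mean_profile(self):
        t = make_linear_table(b=0.5, sigma=0.3, seed=14, n_targets=3, n=60)
        norm = MeanCtRegressionNormalizer(drop_outliers=False).fit(t)
        assert norm.shared_slope_ == pytest.approx(0.5, abs=0.05)
        out = norm.transform(t)
        # OLS residual property applies to the fitted profile, i.e. the
        # per-sample mean of the normalized values
        profile = out.values.mean(axis=1)
        r = np.corrcoef(profile, t.values["REF"])[0, 1]
        assert abs(r) < 1e-8

    def test_group_mean_differences_shift_delta_ct_by_one_constant(self):
        t = make_linear_table(b=[0.4, 0.7, 1.1], seed=9, n=40)
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=t.samples)
        t = CtTable(t.values, t.roles, groups)
        mreg = mean_ct_regression_normalize(t, drop_outliers=False)
        dct = delta_ct_normalize(t, drop_outliers=False)

        def gmd(norm):
            a = norm.values.loc[groups == "a"].mean()
            b = norm.values.loc[groups == "b"].mean()
            return b - a

        diff = gmd(mreg) - gmd(dct)
        assert np.ptp(diff.to_numpy()) < 1e-10  # gene-independent constant


class TestMultipleRegression:
    def two_ref_table(self, seed=0, n=40, b1=1.0, b2=0.0, noise=0.1):
        rng = np.random.default_rng(seed)
        r1 = rng.normal(20, 2, n)
        r2 = rng.normal(18, 2, n)
        tgt = 5 + b1 * r1 + b2 * r2 + rng.normal(0, noise, n)
        values = pd.DataFrame({"R1": r1, "R2": r2, "T1": tgt},
                              index=[f"S{i}" for i in range(n)])
        roles = pd.Series({"R1": "reference", "R2": "reference",
                           "T1": "target"})
        return CtTable(values, roles)

    def test_single_reference_reduces_to_per_gene(self):
        t = make_linear_table(b=0.6, seed=4, n_targets=2, n=40)
        multi = multiple_regression_normalize(t, drop_outliers=False)
        per = per_gene_regression_normalize(t, mode="single:REF",
                                            drop_outliers=False)
        assert np.allclose(multi.values, per.values, atol=1e-10)

    def test_residuals_orthogonal_to_every_reference(self):
        t = self.two_ref_table(seed=6, b1=0.7, b2=0.3)
        out = multiple_regression_normalize(t, drop_outliers=False)
        for ref in ("R1", "R2"):
            r = np.corrcoef(out.values["T1"], t.values[ref])[0, 1]
            assert abs(r) < 1e-8

    def test_inactive_reference_gets_near_zero_coefficient(self):
        t = self.two_ref_table(seed=7, b1=1.0, b2=0.0)
        out = multiple_regression_normalize(t, drop_outliers=False)
        coefs = out.model.effective_coefficients.loc["T1"]
        assert coefs["R1"] == pytest.approx(1.0, abs=0.05)
        assert coefs["R2"] == pytest.approx(0.0, abs=0.05)

    def test_collinear_references_raise_naming_genes(self):
        t = self.two_ref_table(seed=8)
        vals = t.values.copy()
        vals["R2"] = vals["R1"] * 2.0
        t2 = CtTable(vals, t.roles)
        with pytest.raises(CollinearityError):
            multiple_regression_normalize(t2, drop_outliers=False)

    def test_too_few_samples_overfit_error(self):
        t = self.two_ref_table(seed=9, n=3)  # n = k + 1
        with pytest.raises(OverfitError):
            multiple_regression_normalize(t, drop_outliers=False)

    def test_does_not_force_equal_sample_means(self):
        t = self.two_ref_table(seed=10)
        multi = multiple_regression_normalize(t, drop_outliers=False)
        gm = global_mean_normalize(t)
        # global mean centers each sample exactly; multiple regression not
        assert np.allclose(gm.values.mean(axis=1), 0.0, atol=1e-12)
        assert np.ptp(multi.values.mean(axis=1).to_numpy()) > 1e-6


class TestGlobalMean:
    def test_per_sample_centering_on_complete_data(self, small_table):
        vals = small_table.values.fillna(23.0)
        t = CtTable(vals, small_table.roles)
        out = global_mean_normalize(t)
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-12)


class TestEstimatorSurface:
    def test_get_set_params_round_trip(self):
        norm = PerGeneRegressionNormalizer(alpha=0.1, fallback="delta_ct")
        params = norm.get_params()
        assert params["alpha"] == 0.1
        norm.set_params(alpha=0.01)
        assert norm.alpha == 0.01

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone
        norm = MeanCtRegressionNormalizer(reference_mode="single:REF")
        cloned = clone(norm)
        assert cloned.get_params() == norm.get_params()

    def test_make_normalizer_rejects_unknown_method(self):
        with pytest.raises(ConfigurationError):
            make_normalizer("quantile")

    def test_transform_before_fit_raises(self, small_table):
        from ctnorm.exceptions import CtNormError
        with pytest.raises(CtNormError):
            DeltaCtNormalizer().transform(small_table)
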