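import numpy as np
import pandas as pd
import pytest

from ctnorm import (CtTable, GroupDesign, compare_normalizations,
                    simulate_ct_dataset, wilcoxon_de, SimScenario)
from ctnorm.exceptions import DesignError

from conftest import make_linear_table


def norm_like(values: pd.DataFrame):
    """Wrap a plain frame so wilcoxon_de sees 'normalized' values."""
    obj = type("_Norm", (), {})()
    obj.values = values
    return obj


def two_group_design(index, n1):
    labels = ["g1"] * n1 + ["g2"] * (len(index) - n1)
    return GroupDesign(pd.Series(labels, index=index),
                       group1="g1", group2="g2")


class TestWilcoxon:
    def test_exact_p_one_third_for_full_separation_of_two_vs_two(self):
        values = pd.DataFrame({"G": [1.0, 2.0, 3.0, 4.0]},
                              index=list("abcd"))
        design = two_group_design(values.index, 2)
        out = wilcoxon_de(norm_like(values), design)
        # full separation of {1,2} vs {3,4}: 2 of C(4,2)=6 assignments are
        # as extreme, two-sided p = 1/3
        assert out.loc["G", "p"] == pytest.approx(1 / 3, abs=1e-12)
        assert out.loc["G", "test"] == "exact"

    def test_identical_distributions_give_p_one(self):
        values = pd.DataFrame({"G": [1.0, 2.0, 1.0, 2.0]},
                              index=list("abcd"))
        design = two_group_design(values.index, 2)
        out = wilcoxon_de(norm_like(values), design)
        assert out.loc["G", "p"] == pytest.approx(1.0)

    def test_ddct_sign_and_fold_change(self):
        # group means 5 and 7: ΔΔCt = +2 (case higher Ct = lower
        # expression), fold change 2^-2 = 0.25
        values = pd.DataFrame({"G": [4.0, 6.0, 6.5, 7.5]},
                              index=list("abcd"))
        design = two_group_design(values.index, 2)
        out = wilcoxon_de(norm_like(values), design)
        assert out.loc["G", "delta_delta_ct"] == pytest.approx(2.0)
        assert out.loc["G", "fold_change"] == pytest.approx(0.25)

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame({"G": rng.normal(0, 1, 40)},
                              index=[f"s{i}" for i in range(40)])
        out = wilcoxon_de(norm_like(values),
                          two_group_design(values.index, 20))
        assert out.loc["G", "test"] == "asymptotic"
        assert 0 <= out.loc["G", "p"] <= 1

    def test_p_invariant_to_common_shift(self):
        rng = np.random.default_rng(1)
        base = pd.DataFrame({"G": rng.normal(0, 1, 20)},
                            index=[f"s{i}" for i in range(20)])
        design = two_group_design(base.index, 10)
        p0 = wilcoxon_de(norm_like(base), design).loc["G", "p"]
        p1 = wilcoxon_de(norm_like(base + 3.7), design).loc["G", "p"]
        assert p0 == p1  # rank test: exact invariance

    def test_min_per_group_gives_missing_p(self):
        values = pd.DataFrame({"G": [1.0, np.nan, 3.0, 4.0]},
                              index=list("abcd"))
        out = wilcoxon_de(norm_like(values),
                          two_group_design(values.index, 2))
        assert np.isnan(out.loc["G", "p"])
        assert out.loc["G", "test"] == "insufficient_n"

    def test_complete_only_drops_genes_with_missing(self):
        values = pd.DataFrame({"G1": [1.0, 2, 3, 4],
                               "G2": [1.0, np.nan, 3, 4]},
                              index=list("abcd"))
        out = wilcoxon_de(norm_like(values),
                          two_group_design(values.index, 2),
                          complete_only=True)
        assert list(out.index) == ["G1"]

    def test_bh_adjustment_column(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.normal(0, 1, (20, 4)),
                              columns=list("ABCD"),
                              index=[f"s{i}" for i in range(20)])
        out = wilcoxon_de(norm_like(values),
                          two_group_design(values.index, 10),
                          adjust="fdr_bh")
        assert "p_adj" in out.columns
        assert (out["p_adj"] >= out["p"] - 1e-12).all()

    def test_design_validation(self):
        with pytest.raises(DesignError):
            GroupDesign(pd.Series(["a", "b", "c"], index=list("xyz")))
        with pytest.raises(DesignError):
            GroupDesign(pd.Series(["a", "a"], index=list("xy")),
                        group1="a", group2="a")


class TestCompareNormalizations:
    def grouped_table(self, b, seed, n=40, delta_ref=0.0):
        scenario = SimScenario(n1=n // 2, n2=n // 2, b=b, delta_ref=delta_ref,
                               effect=0.0, sigma_ref=0.5, sigma_target=0.3,
                               n_target_genes=4, seed=seed, n_reps=1)
        return simulate_ct_dataset(scenario)

    def test_mean_regression_fold_changes_shift_delta_ct_by_constant(self):
        table, design = self.grouped_table(b=0.5, seed=31, delta_ref=1.0)
        _, summary, _ = compare_normalizations(
            table, design, ["delta_ct", "mean_ct_regression"],
            drop_outliers=False)
        diff = summary["ddct_mean_ct_regression"] - summary["ddct_delta_ct"]
        assert np.ptp(diff.to_numpy()) < 1e-10

    def test_per_gene_regression_shrinks_spurious_fold_changes(self):
        # with b = 0.5 and a reference group shift, ΔCt manufactures a
        # group difference; the regression method removes it
        table, design = self.grouped_table(b=0.5, seed=32, n=60,
                                           delta_ref=2.0)
        _, summary, _ = compare_normalizations(
            table, design, ["delta_ct", "per_gene_regression"],
            drop_outliers=False)
        assert (summary["ddct_per_gene_regression"].abs()
                < summary["ddct_delta_ct"].abs()).all()

    def test_methods_agree_when_slope_is_one(self):
        table, design = self.grouped_table(b=1.0, seed=33, delta_ref=0.0)
        results, summary, n_sig = compare_normalizations(
            table, design,
            ["delta_ct", "mean_ct_regression", "per_gene_regression"],
            drop_outliers=False)
        # estimated slopes are ≈1, so ΔΔCt estimates nearly coincide
        spread = (summary[[c for c in summary.columns
                           if c.startswith("ddct_")]]
                  .apply(np.ptp, axis=1))
        assert (spread < 0.2).all()
        assert set(n_sig.index) == set(results)
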