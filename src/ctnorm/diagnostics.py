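"""Normalization-bias diagnostics.

If ΔCt normalization were unbiased, the mean normalized target value of a
sample would be uncorrelated with that sample's reference-gene Ct.  In
practice the raw target mean is *positively* correlated with each reference
(loading differences), and after plain subtraction the ΔCt mean is
*negatively* correlated whenever the true target-on-reference slope is below
1 — the signature of over-correction.  These diagnostics compute the Pearson
correlation (with its two-sided t test) of the per-sample target mean — raw
and, if supplied, normalized — against each reference gene and against the
reference summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, InsufficientDataError
from .io import CtTable
from .normalize import NormalizedTable, reference_summary
from .qc import drop_outlier_samples, flag_reference_outliers

__all__ = ["CorrelationDiagnostic", "pearson_test", "target_mean_profile",
           "diagnose_bias", "diagnostics_frame"]


@dataclass
class CorrelationDiagnostic:
    """Pearson correlation between a reference series and a target profile."""

    x_label: str
    y_label: str
    r: float
    p: float
    n: int


def pearson_test(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationDiagnostic:
    """Pearson r between paired series, with a two-sided test of r = 0.

    Pairs with a missing member are dropped; at least 3 complete pairs and
    nonzero variance on both sides are required.  The p-value is the
    two-sided t test with t = r·sqrt((n−2)/(1−r²)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(
            f"Pearson test needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in one of the series")
    res = stats.pearsonr(x, y)
    return CorrelationDiagnostic(x_label, y_label,
                                 float(res.statistic), float(res.pvalue), n)


def target_mean_profile(table: CtTable | NormalizedTable) -> pd.Series:
    """Per-sample mean of the non-missing target (or normalized) values."""
    values = table.targets if isinstance(table, CtTable) else table.values
    return values.mean(axis=1, skipna=True)


def diagnose_bias(table: CtTable,
                  normalized: NormalizedTable | None = None,
                  mode: str = "mean",
                  restrict_to_fitting: bool = True) -> list[CorrelationDiagnostic]:
    """Correlate target-mean profiles against each reference gene and summary.

    For every reference gene and for the reference summary, the diagnostic
    reports the correlation of (a) the raw per-sample target mean Ct and,
    when a normalized table is given, (b) the normalized target mean, with
    that reference's Ct.  By default the samples used mirror the fitting set
    (the reference-gene outlier screen is applied), so a regression-based
    normalization shows |r| ≈ 0 by construction of OLS residuals.
    """
    diag_table = table
    if restrict_to_fitting:
        report = flag_reference_outliers(table)
        diag_table = drop_outlier_samples(table, report)
    samples = diag_table.samples
    raw_profile = target_mean_profile(diag_table)

    regressors: list[tuple[str, pd.Series]] = [
        (gene, diag_table.values[gene]) for gene in diag_table.reference_genes]
    regressors.append(
        ("reference_summary", reference_summary(diag_table, mode)))

    out = []
    for label, series in regressors:
        out.append(pearson_test(series, raw_profile,
                                x_label=label, y_label="target_mean_ct"))
        if normalized is not None:
            norm_profile = target_mean_profile(normalized).reindex(samples)
            out.append(pearson_test(series, norm_profile,
                                    x_label=label,
                                    y_label="normalized_target_mean"))
    return out


def diagnostics_frame(diags: list[CorrelationDiagnostic]) -> pd.DataFrame:
    """Tabulate diagnostics for reporting."""
    return pd.DataFrame([vars(d) for d in diags])
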