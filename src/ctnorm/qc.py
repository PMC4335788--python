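"""Reference-gene outlier screening.

Before regression coefficients are estimated, each reference (housekeeping)
gene is screened across samples with the Tukey fence: values beyond
Q1 − 1.5·IQR or Q3 + 1.5·IQR are flagged, and any sample with more than one
flagged reference gene is excluded from coefficient estimation.  Excluded
samples are still normalized with the fitted model — exclusion protects the
fit, it does not remove the sample from the study.

Quartiles use linear interpolation between order statistics (numpy's
default, the "type 7" convention) and are computed over the non-missing
values of each reference gene, after undetectable filtering.  The convention
is recorded in the report so runs are auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, CtNormWarning, DegenerateDataError
from .io import CtTable

__all__ = ["OutlierReport", "flag_reference_outliers", "drop_outlier_samples"]

QUANTILE_CONVENTION = "linear interpolation (type 7)"


@dataclass
class OutlierReport:
    """Per-(sample, reference gene) outlier flags and the induced sample drops.

    ``dropped_samples`` are exactly the samples with more than one flagged
    reference gene (strictly more than one: a single outlying reference does
    not condemn a sample).
    """

    flags: pd.DataFrame            # samples × reference genes, boolean
    fences: pd.DataFrame           # per reference gene: q1, q3, lower, upper
    n_outlier_refs: pd.Series      # per sample
    dropped_samples: list[str]
    quantile_convention: str = QUANTILE_CONVENTION

    def to_frame(self, table: CtTable | None = None) -> pd.DataFrame:
        """Long-format report: sample, gene, ct (if a table is given), flag."""
        rows = []
        for sample in self.flags.index:
            for gene in self.flags.columns:
                row = {"sample": sample, "gene": gene,
                       "flag": bool(self.flags.at[sample, gene])}
                if table is not None:
                    row["ct"] = table.values.at[sample, gene]
                rows.append(row)
        return pd.DataFrame(rows)


def flag_reference_outliers(table: CtTable) -> OutlierReport:
    """Flag reference-gene Ct values beyond the 1.5×IQR Tukey fences.

    Quartiles for each reference gene are taken over that gene's non-missing
    values across samples.  A reference gene with fewer than 4 non-missing
    values is skipped (no flags) with a warning — quartiles are not
    meaningful there.  Missing values are never flagged.  Flags are invariant
    to sample ordering.
    """
    refs = table.reference_genes
    if not refs:
        raise ConfigurationError("table has no reference genes to screen")
    flags = pd.DataFrame(False, index=table.values.index, columns=refs)
    fence_rows = {}
    for gene in refs:
        col = table.values[gene]
        vals = col.dropna().to_numpy()
        if len(vals) < 4:
            warnings.warn(
                f"reference gene {gene!r} has only {len(vals)} non-missing "
                "values; outlier fences not computed", CtNormWarning,
                stacklevel=2)
            fence_rows[gene] = dict(q1=np.nan, q3=np.nan,
                                    lower=np.nan, upper=np.nan)
            continue
        q1, q3 = np.quantile(vals, [0.25, 0.75])  # type 7
        iqr = q3 - q1
        lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        flags[gene] = (col < lower) | (col > upper)
        fence_rows[gene] = dict(q1=q1, q3=q3, lower=lower, upper=upper)
    n_out = flags.sum(axis=1)
    dropped = list(n_out.index[n_out > 1])
    return OutlierReport(flags=flags,
                         fences=pd.DataFrame(fence_rows).T,
                         n_outlier_refs=n_out,
                         dropped_samples=dropped)


def drop_outlier_samples(table: CtTable, report: OutlierReport) -> CtTable:
    """Return ``table`` without the samples the report marks for removal.

    The input table is left untouched.  Flag + drop is applied exactly once
    per pipeline run; fences are not recomputed on the reduced table.
    """
    keep = [s for s in table.samples if s not in set(report.dropped_samples)]
    if not keep:
        raise DegenerateDataError(
            "every sample has more than one outlying reference gene")
    if len(keep) == len(table.samples):
        return table
    return table.subset_samples(keep)
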