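"""Two-group differential expression on normalized Ct values.

Per target gene, the group difference of mean normalized values (the ΔΔCt)
and a two-sided Wilcoxon rank-sum p-value are reported.  The sign
convention follows the Ct scale: a positive ΔΔCt means higher Ct — i.e.
*lower* expression — in the case group, so the fold change is
``2^(−ΔΔCt)``.

The exact Wilcoxon null distribution is used when the smaller group has at
most 10 observations and there are no ties; otherwise the normal
approximation with tie and continuity corrections applies.  Because the
test is rank-based, any per-gene shift common to both groups (e.g. the
constant offset separating ΔCt from shared-slope regression normalization
on complete data) leaves the p-value unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError
from .io import CtTable
from .normalize import NormalizedTable, make_normalizer

__all__ = ["GroupDesign", "wilcoxon_de", "compare_normalizations"]

EXACT_MAX_N = 10


@dataclass
class GroupDesign:
    """Two-group sample design.

    ``group1`` is the baseline/control label, ``group2`` the case label;
    ΔΔCt is group2 minus group1.  If the labels are not given they are taken
    from the design in sorted order (and must then number exactly two).
    """

    groups: pd.Series                 # sample id -> label
    group1: str | None = None
    group2: str | None = None

    def __post_init__(self):
        self.groups = pd.Series(self.groups, dtype=object).dropna()
        labels = sorted(set(self.groups))
        if self.group1 is None and self.group2 is None:
            if len(labels) != 2:
                raise DesignError(
                    f"design must have exactly two groups, found {labels}")
            self.group1, self.group2 = labels
        for lab in (self.group1, self.group2):
            if lab not in labels:
                raise DesignError(f"group label {lab!r} absent from design")
        if self.group1 == self.group2:
            raise DesignError("group1 and group2 must differ")

    def split(self, index) -> tuple[list, list]:
        """Sample ids of each group, restricted to ``index`` order."""
        in_design = self.groups.reindex(index)
        g1 = [s for s in index if in_design.get(s) == self.group1]
        g2 = [s for s in index if in_design.get(s) == self.group2]
        return g1, g2


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> tuple[float, str]:
    """Two-sided rank-sum p-value and the variant used."""
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= EXACT_MAX_N and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue), method


def wilcoxon_de(normalized: NormalizedTable | CtTable, design: GroupDesign,
                min_per_group: int = 2, complete_only: bool = False,
                adjust: str | None = None) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum tests and ΔΔCt fold changes.

    Parameters
    ----------
    normalized : NormalizedTable or CtTable
        Values to compare; for a CtTable the target genes are used as-is.
    design : GroupDesign
        Two-group design; samples absent from the design are ignored.
    min_per_group : int
        Genes with fewer non-missing values in either group are reported
        with a missing p-value (and missing ΔΔCt if a group is empty).
    complete_only : bool
        Restrict to genes with no missing values among the design samples
        (the "no undetectable values" analysis).
    adjust : {"fdr_bh", None}
        Optional Benjamini–Hochberg adjustment, added as column ``p_adj``.

    Returns
    -------
    DataFrame indexed by gene with columns n1, n2, delta_delta_ct,
    fold_change, p, test.
    """
    values = normalized.values if not isinstance(normalized, CtTable) \
        else normalized.targets
    g1, g2 = design.split(list(values.index))
    if not g1 or not g2:
        raise DesignError("both groups need at least one sample in the table")
    genes = list(values.columns)
    if complete_only:
        sub = values.loc[g1 + g2]
        genes = [g for g in genes if sub[g].notna().all()]
    rows = []
    for gene in genes:
        x = values.loc[g1, gene].dropna().to_numpy()  # baseline
        y = values.loc[g2, gene].dropna().to_numpy()  # case
        ddct = float(y.mean() - x.mean()) if len(x) and len(y) else math.nan
        fc = 2.0 ** (-ddct) if not math.isnan(ddct) else math.nan
        if min(len(x), len(y)) >= min_per_group:
            p, variant = _wilcoxon_p(x, y)
        else:
            p, variant = math.nan, "insufficient_n"
        rows.append({"gene": gene, "n1": len(x), "n2": len(y),
                     "delta_delta_ct": ddct, "fold_change": fc,
                     "p": p, "test": variant})
    out = pd.DataFrame(rows).set_index("gene")
    if adjust == "fdr_bh" and len(out):
        from statsmodels.stats.multitest import multipletests
        mask = out["p"].notna()
        adj = pd.Series(math.nan, index=out.index)
        if mask.any():
            adj.loc[mask] = multipletests(out.loc[mask, "p"],
                                          method="fdr_bh")[1]
        out["p_adj"] = adj
    elif adjust not in (None, "fdr_bh"):
        raise DesignError(f"unknown adjustment {adjust!r}")
    return out


def compare_normalizations(table: CtTable, design: GroupDesign,
                           methods: list[str], alpha: float = 0.05,
                           complete_only: bool = False,
                           **norm_kwargs) -> tuple[dict[str, pd.DataFrame],
                                                   pd.DataFrame, pd.Series]:
    """Run DE under several normalization methods on one table.

    Returns
    -------
    results : dict method → DE frame (identical gene sets).
    summary : DataFrame with per-gene ``ddct_<m>``, ``fc_<m>``, ``p_<m>``
        columns for each method m.
    n_significant : Series, genes with p < ``alpha`` per method.
    """
    results: dict[str, pd.DataFrame] = {}
    for method in methods:
        normalizer = make_normalizer(method, **norm_kwargs)
        normalized = normalizer.fit_transform(table)
        results[method] = wilcoxon_de(normalized, design,
                                      complete_only=complete_only)
    # common gene set so fold changes and p-values pair up
    common = None
    for df in results.values():
        idx = set(df.index)
        common = idx if common is None else (common & idx)
    genes = [g for g in table.target_genes if g in (common or set())]
    summary = pd.DataFrame(index=pd.Index(genes, name="gene"))
    for method, df in results.items():
        results[method] = df.loc[genes]
        summary[f"ddct_{method}"] = df.loc[genes, "delta_delta_ct"]
        summary[f"fc_{method}"] = df.loc[genes, "fold_change"]
        summary[f"p_{method}"] = df.loc[genes, "p"]
    n_sig = pd.Series({m: int((df["p"] < alpha).sum())
                       for m, df in results.items()}, name="n_significant")
    return results, summary, n_sig
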