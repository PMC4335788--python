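"""Ct normalization methods, as scikit-learn style transformers.

The conventional ΔCt normalization subtracts a reference-gene Ct summary
from every target gene's Ct.  That is only unbiased when the target's Ct is
related to the reference's with slope exactly 1; amplification-efficiency
differences make the true slope gene-specific and usually below 1, so plain
subtraction over-corrects and leaves normalized values negatively correlated
with the references.  The regression-based methods here estimate the slope
by OLS and subtract ``b × reference`` instead of the reference itself:

* :class:`DeltaCtNormalizer` — classic ΔCt (slope pinned to 1).
* :class:`MeanCtRegressionNormalizer` — one shared slope, fitted from the
  per-sample mean target Ct on the reference summary.
* :class:`PerGeneRegressionNormalizer` — a slope per target gene, each gated
  by the significance of its slope t test.
* :class:`MultipleRegressionNormalizer` — per target gene, one coefficient
  per reference gene via multiple OLS, removing dependence on all references
  simultaneously.
* :class:`GlobalMeanNormalizer` — subtract the per-sample mean of all target
  genes (no reference genes involved).

Every transformer follows the sklearn contract: parameters in ``__init__``,
``fit(table)`` estimates coefficients (after the reference-gene outlier
screen, by default), ``transform(table)`` produces a :class:`NormalizedTable`
for *all* samples — samples excluded from fitting are still normalized.
Fitted attributes carry a trailing underscore.

The fitted intercepts are recorded but never subtracted: the normalized
values keep a gene-specific constant offset, which cancels in any
between-group comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    ConfigurationError,
    CtNormError,
    DegenerateDataError,
    FallbackWarning,
)
from .io import CtTable
from .qc import OutlierReport, drop_outlier_samples, flag_reference_outliers
from .regression import RegressionFit, fit_multiple_regression, fit_simple_regression

__all__ = [
    "NormalizationModel",
    "NormalizedTable",
    "reference_summary",
    "BaseCtNormalizer",
    "DeltaCtNormalizer",
    "PerGeneRegressionNormalizer",
    "MeanCtRegressionNormalizer",
    "MultipleRegressionNormalizer",
    "GlobalMeanNormalizer",
    "make_normalizer",
    "delta_ct_normalize",
    "per_gene_regression_normalize",
    "mean_ct_regression_normalize",
    "multiple_regression_normalize",
    "global_mean_normalize",
]

METHODS = ("delta_ct", "mean_ct_regression", "per_gene_regression",
           "multiple_regression", "global_mean")

REGRESSION_APPLIED = "regression_applied"
FALLBACK_APPLIED = "fallback_applied"


def reference_summary(table: CtTable, mode: str = "mean") -> pd.Series:
    """Per-sample summary of the reference-gene Ct values.

    Parameters
    ----------
    mode : str
        ``"mean"`` — arithmetic mean of the reference Ct values;
        ``"geometric_mean"`` — geometric mean of the linear-scale abundances
        ``2^(−Ct)``, reported back on the Ct scale.  Because
        ``−log2(geomean(2^−Ct_j)) = mean(Ct_j)``, this is algebraically
        identical to ``"mean"``; both are kept so intent is explicit.
        ``"single:<gene>"`` — that reference gene's Ct unchanged.

    A sample whose needed references are all missing gets a missing summary.
    """
    if mode.startswith("single:"):
        gene = mode.split(":", 1)[1]
        if gene not in table.reference_genes:
            raise ConfigurationError(
                f"{gene!r} is not a reference gene in this table")
        return table.values[gene].copy()
    if mode in ("mean", "geometric_mean", "geomean"):
        # geometric mean of 2^-Ct on the Ct scale == arithmetic mean of Ct
        return table.references.mean(axis=1, skipna=True)
    raise ConfigurationError(
        f"unknown reference mode {mode!r}; use 'mean', 'geometric_mean' "
        "or 'single:<gene>'")


@dataclass
class NormalizationModel:
    """The fitted normalization model attached to a normalized table.

    ``effective_coefficients`` is the coefficient vector actually subtracted
    for each gene (genes × regressors); for summary-based methods the single
    regressor column is named ``"reference_summary"``.
    """

    method: str
    reference_set: list[str]
    reference_mode: str | None
    alpha: float | None
    fallback: str | None
    fits: dict[str, RegressionFit | None]
    effective_coefficients: pd.DataFrame
    flags: pd.Series
    fitting_samples: list[str]

    def report(self) -> pd.DataFrame:
        """Per-gene model report (method, coefficients, p-values, flag)."""
        rows = []
        for gene in self.effective_coefficients.index:
            fit = self.fits.get(gene)
            row = {"gene": gene, "method": self.method,
                   "flag": self.flags.get(gene, "")}
            for reg in self.effective_coefficients.columns:
                row[f"b[{reg}]"] = self.effective_coefficients.at[gene, reg]
            if fit is not None:
                row["intercept"] = fit.intercept
                row["r2"] = fit.r2
                row["n_used"] = fit.n_used
                for reg, p in zip(fit.regressors, fit.p):
                    row[f"p[{reg}]"] = p
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class NormalizedTable:
    """Normalized target-gene values plus the model that produced them."""

    values: pd.DataFrame          # samples × target genes
    model: NormalizationModel
    groups: pd.Series | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def roles(self) -> pd.Series:
        return pd.Series("target", index=self.values.columns)

    @property
    def flags(self) -> pd.Series:
        return self.model.flags


class BaseCtNormalizer(BaseEstimator, TransformerMixin):
    """Shared fit/transform plumbing for the normalization transformers.

    ``drop_outliers=True`` applies the reference-gene Tukey screen before
    coefficient estimation (the screened samples are still transformed).
    """

    method: str = ""

    def __init__(self, drop_outliers: bool = True):
        self.drop_outliers = drop_outliers

    # subclasses implement ------------------------------------------------
    def _fit(self, table: CtTable) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _transform_values(self, table: CtTable) -> pd.DataFrame:  # pragma: no cover
        raise NotImplementedError

    # sklearn surface ------------------------------------------------------
    def fit(self, table: CtTable, y=None):
        if not isinstance(table, CtTable):
            raise TypeError("fit expects a CtTable")
        fit_table = table
        self.outlier_report_ = None
        if self.drop_outliers and table.reference_genes:
            report = flag_reference_outliers(table)
            fit_table = drop_outlier_samples(table, report)
            self.outlier_report_ = report
        self.fitting_samples_ = list(fit_table.samples)
        self.reference_set_ = list(table.reference_genes)
        self.target_genes_ = list(table.target_genes)
        self._fit(fit_table)
        return self

    def transform(self, table: CtTable) -> NormalizedTable:
        if not hasattr(self, "fitting_samples_"):
            raise CtNormError("transformer is not fitted; call fit() first")
        values = self._transform_values(table)
        model = NormalizationModel(
            method=self.method,
            reference_set=self.reference_set_,
            reference_mode=getattr(self, "reference_mode", None),
            alpha=getattr(self, "alpha", None),
            fallback=getattr(self, "fallback", None),
            fits=getattr(self, "fits_", {}),
            effective_coefficients=self.effective_coefficients_.copy(),
            flags=getattr(self, "flags_", pd.Series(dtype=object)).copy(),
            fitting_samples=list(self.fitting_samples_),
        )
        return NormalizedTable(values=values, model=model, groups=table.groups)

    def fit_transform(self, table: CtTable, y=None, **kwargs) -> NormalizedTable:
        return self.fit(table).transform(table)


class DeltaCtNormalizer(BaseCtNormalizer):
    """Classic ΔCt: subtract the reference summary with slope pinned to 1.

    Equivalent to per-gene regression with every slope forced to 1 and no
    intercept.
    """

    method = "delta_ct"

    def __init__(self, reference_mode: str = "mean", drop_outliers: bool = True):
        super().__init__(drop_outliers=drop_outliers)
        self.reference_mode = reference_mode

    def _fit(self, table: CtTable) -> None:
        summary = reference_summary(table, self.reference_mode)
        if summary.isna().all():
            raise DegenerateDataError("reference summary is missing everywhere")
        self.fits_ = {}
        self.effective_coefficients_ = pd.DataFrame(
            1.0, index=self.target_genes_, columns=["reference_summary"])
        self.flags_ = pd.Series(self.method, index=self.target_genes_)

    def _transform_values(self, table: CtTable) -> pd.DataFrame:
        summary = reference_summary(table, self.reference_mode)
        return table.targets.sub(summary, axis=0)


class PerGeneRegressionNormalizer(BaseCtNormalizer):
    """Per-target-gene regression normalization.

    For each target gene g the slope b_g of Ct_g on the reference summary is
    estimated by OLS over the retained fitting samples (pairwise-complete).
    If the slope's two-sided t test gives p < ``alpha``, the gene is
    normalized as ``Ct_g − b_g · summary`` (``regression_applied``);
    otherwise the control carries no demonstrated information for that gene
    and the ``fallback`` applies (``fallback_applied``):

    * ``"none"`` — leave Ct_g unsubtracted (default);
    * ``"delta_ct"`` — subtract the summary with slope 1.

    Per-gene fit failures (too few pairs, degenerate regressor) also fall
    back, with a warning; they never abort the table.
    """

    method = "per_gene_regression"

    def __init__(self, reference_mode: str = "mean", alpha: float = 0.05,
                 fallback: str = "none", drop_outliers: bool = True):
        super().__init__(drop_outliers=drop_outliers)
        self.reference_mode = reference_mode
        self.alpha = alpha
        self.fallback = fallback

    def _fallback_slope(self) -> float:
        if self.fallback == "delta_ct":
            return 1.0
        if self.fallback == "none":
            return 0.0
        raise ConfigurationError(
            f"unknown fallback {self.fallback!r}; use 'none' or 'delta_ct'")

    def _fit(self, table: CtTable) -> None:
        summary = reference_summary(table, self.reference_mode)
        fits: dict[str, RegressionFit | None] = {}
        slopes = {}
        flags = {}
        for gene in self.target_genes_:
            try:
                fit = fit_simple_regression(
                    table.values[gene], summary, name="reference_summary")
            except CtNormError as exc:
                warnings.warn(
                    f"gene {gene!r}: {exc}; applying fallback "
                    f"{self.fallback!r}", FallbackWarning, stacklevel=2)
                fits[gene] = None
                slopes[gene] = self._fallback_slope()
                flags[gene] = FALLBACK_APPLIED
                continue
            fits[gene] = fit
            if fit.p[0] < self.alpha:
                slopes[gene] = fit.slope
                flags[gene] = REGRESSION_APPLIED
            else:
                slopes[gene] = self._fallback_slope()
                flags[gene] = FALLBACK_APPLIED
        self.fits_ = fits
        self.slopes_ = pd.Series(slopes).reindex(self.target_genes_)
        self.flags_ = pd.Series(flags).reindex(self.target_genes_)
        self.effective_coefficients_ = self.slopes_.to_frame("reference_summary")

    def _transform_values(self, table: CtTable) -> pd.DataFrame:
        summary = reference_summary(table, self.reference_mode)
        out = {}
        for gene in self.target_genes_:
            b = self.slopes_[gene]
            col = table.values[gene]
            # slope 0 needs no reference: output missing only where the
            # target itself is missing
            out[gene] = col if b == 0.0 else col - b * summary
        return pd.DataFrame(out, index=table.values.index)[self.target_genes_]


class MeanCtRegressionNormalizer(BaseCtNormalizer):
    """One shared slope from the per-sample mean target Ct.

    The per-sample mean of all target Ct values is regressed on the
    reference summary; the single fitted slope b is applied to every target
    gene: ``Ct_g − b · summary``.  The same significance gate as the
    per-gene method applies to the shared slope.  Group-mean-difference fold
    changes from this method differ from ΔCt's by one constant across genes.
    """

    method = "mean_ct_regression"

    def __init__(self, reference_mode: str = "mean", alpha: float = 0.05,
                 fallback: str = "none", drop_outliers: bool = True):
        super().__init__(drop_outliers=drop_outliers)
        self.reference_mode = reference_mode
        self.alpha = alpha
        self.fallback = fallback

    def _fit(self, table: CtTable) -> None:
        summary = reference_summary(table, self.reference_mode)
        profile = table.targets.mean(axis=1, skipna=True)
        fit = fit_simple_regression(profile, summary, name="reference_summary")
        if fit.p[0] < self.alpha:
            b, flag = fit.slope, REGRESSION_APPLIED
        else:
            b = 1.0 if self.fallback == "delta_ct" else 0.0
            flag = FALLBACK_APPLIED
        self.shared_fit_ = fit
        self.shared_slope_ = b
        self.fits_ = {gene: fit for gene in self.target_genes_}
        self.flags_ = pd.Series(flag, index=self.target_genes_)
        self.effective_coefficients_ = pd.DataFrame(
            b, index=self.target_genes_, columns=["reference_summary"])

    def _transform_values(self, table: CtTable) -> pd.DataFrame:
        b = self.shared_slope_
        if b == 0.0:
            return table.targets.copy()
        summary = reference_summary(table, self.reference_mode)
        return table.targets.sub(b * summary, axis=0)


class MultipleRegressionNormalizer(BaseCtNormalizer):
    """Multiple regression on all reference genes, per target gene.

    Each target gene's Ct is regressed on the Ct of every reference gene
    simultaneously (OLS with intercept, complete cases), and the fitted
    coefficient vector is subtracted:
    ``Ct_g − Σ_j b_gj · Ct_ref_j``.  This removes the linear dependence on
    all references at once, which a single summary regressor cannot, at the
    price of needing enough samples (residual df ≥ 1 is required; a warning
    is issued below 3 complete cases per regressor).  Unlike global-mean
    normalization it does not force per-sample means to be equal — it only
    removes the correlation with the references.

    The full coefficient vector is applied ungated; ``alpha`` is recorded in
    the model report so per-coefficient significance is auditable.
    Rank-deficient (collinear) references and insufficient degrees of
    freedom raise for the whole table; per-gene missing-data failures fall
    back per ``fallback`` with a warning.
    """

    method = "multiple_regression"

    def __init__(self, alpha: float = 0.05, fallback: str = "none",
                 drop_outliers: bool = True):
        super().__init__(drop_outliers=drop_outliers)
        self.alpha = alpha
        self.fallback = fallback

    def _fit(self, table: CtTable) -> None:
        X = table.references
        fits: dict[str, RegressionFit | None] = {}
        coefs = pd.DataFrame(0.0, index=self.target_genes_,
                             columns=self.reference_set_)
        flags = {}
        from .exceptions import CollinearityError, OverfitError
        for gene in self.target_genes_:
            try:
                fit = fit_multiple_regression(table.values[gene], X)
            except (CollinearityError, OverfitError):
                raise  # structural: affects every gene, abort
            except CtNormError as exc:
                warnings.warn(
                    f"gene {gene!r}: {exc}; applying fallback "
                    f"{self.fallback!r}", FallbackWarning, stacklevel=2)
                fits[gene] = None
                if self.fallback == "delta_ct":
                    coefs.loc[gene] = 1.0 / len(self.reference_set_)
                flags[gene] = FALLBACK_APPLIED
                continue
            fits[gene] = fit
            coefs.loc[gene] = fit.coefficients()
            flags[gene] = REGRESSION_APPLIED
        self.fits_ = fits
        self.flags_ = pd.Series(flags).reindex(self.target_genes_)
        self.effective_coefficients_ = coefs

    def _transform_values(self, table: CtTable) -> pd.DataFrame:
        refs = table.references
        out = {}
        for gene in self.target_genes_:
            coef = self.effective_coefficients_.loc[gene]
            col = table.values[gene]
            if (coef == 0.0).all():
                out[gene] = col
            else:
                # any missing needed reference propagates to the output
                adjust = refs.mul(coef, axis=1).sum(axis=1, skipna=False)
                out[gene] = col - adjust
        return pd.DataFrame(out, index=table.values.index)[self.target_genes_]


class GlobalMeanNormalizer(BaseCtNormalizer):
    """Subtract the per-sample mean of all non-missing target Ct values.

    Reference genes play no part.  For complete data every normalized
    sample mean is exactly 0 — a stronger constraint than the regression
    methods impose.
    """

    method = "global_mean"

    def __init__(self):
        super().__init__(drop_outliers=False)

    def _fit(self, table: CtTable) -> None:
        if table.targets.notna().sum(axis=1).eq(0).any():
            raise DegenerateDataError(
                "some samples have no non-missing target genes")
        self.fits_ = {}
        self.effective_coefficients_ = pd.DataFrame(
            index=self.target_genes_, columns=["global_mean"], data=1.0)
        self.flags_ = pd.Series(self.method, index=self.target_genes_)

    def _transform_values(self, table: CtTable) -> pd.DataFrame:
        targets = table.targets
        return targets.sub(targets.mean(axis=1, skipna=True), axis=0)


_NORMALIZERS = {
    "delta_ct": DeltaCtNormalizer,
    "mean_ct_regression": MeanCtRegressionNormalizer,
    "mean_regression": MeanCtRegressionNormalizer,
    "per_gene_regression": PerGeneRegressionNormalizer,
    "per_gene": PerGeneRegressionNormalizer,
    "multiple_regression": MultipleRegressionNormalizer,
    "multiple": MultipleRegressionNormalizer,
    "global_mean": GlobalMeanNormalizer,
}


def make_normalizer(method: str, **kwargs) -> BaseCtNormalizer:
    """Instantiate a normalizer by method name, passing through parameters."""
    try:
        cls = _NORMALIZERS[method]
    except KeyError:
        raise ConfigurationError(
            f"unknown normalization method {method!r}; "
            f"choose from {sorted(set(_NORMALIZERS))}") from None
    valid = cls().get_params() if cls is not GlobalMeanNormalizer else {}
    if cls is GlobalMeanNormalizer:
        kwargs = {}
    else:
        kwargs = {k: v for k, v in kwargs.items() if k in valid}
    return cls(**kwargs)


# -- thin functional wrappers ------------------------------------------------

def delta_ct_normalize(table: CtTable, mode: str = "mean",
                       drop_outliers: bool = True) -> NormalizedTable:
    """ΔCt normalization: target Ct minus the reference summary."""
    return DeltaCtNormalizer(reference_mode=mode,
                             drop_outliers=drop_outliers).fit_transform(table)


def per_gene_regression_normalize(table: CtTable, mode: str = "mean",
                                  alpha: float = 0.05, fallback: str = "none",
                                  drop_outliers: bool = True) -> NormalizedTable:
    """Per-gene regression normalization (see the class docstring)."""
    return PerGeneRegressionNormalizer(
        reference_mode=mode, alpha=alpha, fallback=fallback,
        drop_outliers=drop_outliers).fit_transform(table)


def mean_ct_regression_normalize(table: CtTable, mode: str = "mean",
                                 alpha: float = 0.05,
                                 drop_outliers: bool = True) -> NormalizedTable:
    """Shared-slope regression normalization from the mean target profile."""
    return MeanCtRegressionNormalizer(
        reference_mode=mode, alpha=alpha,
        drop_outliers=drop_outliers).fit_transform(table)


def multiple_regression_normalize(table: CtTable, alpha: float = 0.05,
                                  drop_outliers: bool = True) -> NormalizedTable:
    """Multiple-regression normalization on all reference genes."""
    return MultipleRegressionNormalizer(
        alpha=alpha, drop_outliers=drop_outliers).fit_transform(table)


def global_mean_normalize(table: CtTable) -> NormalizedTable:
    """Global-mean normalization (per-sample centering of target Ct)."""
    return GlobalMeanNormalizer().fit_transform(table)
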