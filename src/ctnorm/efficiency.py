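"""Amplification-efficiency estimation from dilution series.

A dilution series measures one gene in one sample at a grid of known
template fold-dilutions.  With per-cycle amplification efficiency E
(perfect doubling is E = 1, i.e. 100%), the threshold cycle follows

    Ct = c − log2(d) / log2(1 + E),

where d is the dilution factor.  Regressing Ct on log2(d) therefore gives a
slope of −1/log2(1+E): exactly −1 at 100% efficiency, steeper (more
negative) for lower efficiency.  Inverting,

    E = 2^(−1/slope) − 1.

Efficiency differences between a target and a reference gene are what bend
the target-on-reference slope away from 1: for noise-free series that
pairwise slope equals slope_target / slope_reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlignmentError,
    FormatError,
    InsufficientDataError,
    InvalidAmplificationWarning,
)
from .io import read_dilution_table
from .regression import RegressionFit, fit_simple_regression

__all__ = ["DilutionSeries", "EfficiencyEstimate", "fit_dilution_regression",
           "pairwise_target_reference_slope", "read_dilution_series",
           "efficiency_table"]

#: The seven-point grid used in the reference experiment (fold of original
#: cDNA concentration).
DEFAULT_DILUTIONS = (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0, 2.0, 4.0)


@dataclass
class DilutionSeries:
    """One gene × one sample dilution series, replicates pre-summarized."""

    gene_id: str
    sample_id: str
    dilutions: np.ndarray   # positive fold factors
    ct: np.ndarray          # cycles

    def __post_init__(self):
        self.dilutions = np.asarray(self.dilutions, dtype=float)
        self.ct = np.asarray(self.ct, dtype=float)
        if len(self.dilutions) != len(self.ct):
            raise FormatError("dilutions and ct must have equal length")
        if (self.dilutions <= 0).any():
            raise FormatError("dilution factors must be positive")
        if len(np.unique(self.dilutions)) < 3:
            raise InsufficientDataError(
                "a dilution series needs >= 3 distinct dilution factors")


@dataclass
class EfficiencyEstimate:
    """Dilution-regression slope and the derived amplification efficiency.

    ``efficiency`` is a fraction (1.0 = 100%, perfect doubling); it is NaN
    when the slope is non-negative (no valid amplification signal).
    """

    gene_id: str
    sample_id: str
    slope: float            # Ct per log2-dilution unit
    se_slope: float
    intercept: float
    r2: float
    efficiency: float
    n: int


def fit_dilution_regression(series: DilutionSeries) -> EfficiencyEstimate:
    """OLS of Ct on log2(dilution); efficiency E = 2^(−1/slope) − 1.

    A non-negative slope means the reaction did not behave like an
    amplification (more template should mean earlier threshold); the
    efficiency is then reported as NaN with a warning.
    """
    x = np.log2(series.dilutions)
    fit = fit_simple_regression(series.ct, x, name="log2_dilution")
    slope = fit.slope
    if slope >= 0:
        warnings.warn(
            f"{series.gene_id}/{series.sample_id}: non-negative dilution "
            "slope; amplification efficiency undefined",
            InvalidAmplificationWarning, stacklevel=2)
        eff = float("nan")
    else:
        eff = 2.0 ** (-1.0 / slope) - 1.0
    return EfficiencyEstimate(
        gene_id=series.gene_id, sample_id=series.sample_id,
        slope=slope, se_slope=float(fit.se[0]), intercept=fit.intercept,
        r2=fit.r2, efficiency=eff, n=fit.n_used)


def pairwise_target_reference_slope(target: DilutionSeries,
                                    reference: DilutionSeries) -> RegressionFit:
    """Slope of target Ct on reference Ct across a matched dilution grid.

    Both series must come from the same sample and share the same dilution
    factors; points are matched by dilution.  For noise-free series the
    fitted slope equals slope_target / slope_reference, i.e. the ratio of
    the genes' dilution-regression slopes — the quantity that displaces the
    normalization coefficient from 1 when efficiencies differ.
    """
    if target.sample_id != reference.sample_id:
        raise AlignmentError(
            f"series come from different samples: {target.sample_id!r} vs "
            f"{reference.sample_id!r}")
    t_order = np.argsort(target.dilutions)
    r_order = np.argsort(reference.dilutions)
    if (len(target.dilutions) != len(reference.dilutions)
            or not np.allclose(target.dilutions[t_order],
                               reference.dilutions[r_order], rtol=1e-9)):
        raise AlignmentError("dilution grids do not match")
    return fit_simple_regression(target.ct[t_order], reference.ct[r_order],
                                 name=reference.gene_id)


def read_dilution_series(path, policy=None) -> list[DilutionSeries]:
    """Read a dilution file into per-(gene, sample) series.

    The file has columns gene,sample,dilution[,replicate],ct; replicate Ct
    values are summarized by their median before fitting.
    """
    tidy = read_dilution_table(path, policy=policy)
    series = []
    for (gene, sample), grp in tidy.groupby(["gene", "sample"], sort=False):
        keep = grp["ct"].notna()
        series.append(DilutionSeries(gene, sample,
                                     grp.loc[keep, "dilution"].to_numpy(),
                                     grp.loc[keep, "ct"].to_numpy()))
    return series


def efficiency_table(series: list[DilutionSeries]) -> pd.DataFrame:
    """Fit every series and tabulate gene, sample, slope, se, E, r2."""
    rows = []
    for s in series:
        est = fit_dilution_regression(s)
        rows.append({"gene": est.gene_id, "sample": est.sample_id,
                     "slope": est.slope, "se": est.se_slope,
                     "E": est.efficiency, "r2": est.r2, "n": est.n})
    return pd.DataFrame(rows)
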