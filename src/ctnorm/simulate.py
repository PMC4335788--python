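"""Synthetic Ct data and the type-I-error / power study.

The generator draws from the linear structure the normalization model
assumes.  For sample i in group g ∈ {1, 2}:

    Ct_ref,k  = mu_ref + delta_ref·1[g=2] + ε_ref,k        ε ~ N(0, σ_ref²)
    Ct_tgt,j  = a_j + b_j·R_i + effect_j·1[g=2] + ε_tgt,j  ε ~ N(0, σ_tgt²)

where R_i is the mean of the sample's reference Ct values (a single
reference by default).  ``delta_ref`` is a between-group shift of the
*reference* gene — a loading/efficiency artifact, not expression signal —
and ``effect`` is true differential expression on the Ct scale (0 under
the null).  When b ≠ 1 and delta_ref ≠ 0, ΔCt normalization converts the
reference shift into a spurious target group difference of (1−b)·delta_ref,
inflating the false-positive rate; regressing the slope out removes it.

``error_rate_study`` runs this comparison over Monte-Carlo replicates:
generate → normalize (ΔCt and per-gene regression, by default) → Wilcoxon
rank-sum → aggregate rejection rates, with binomial Monte-Carlo standard
errors and the bias/RMSE of the ΔΔCt estimate against the true effect.

Seeding: one master seed per scenario; per-replicate generators are spawned
from a ``numpy.random.SeedSequence`` so results are reproducible and
independent of replicate order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de import GroupDesign, wilcoxon_de
from .efficiency import DEFAULT_DILUTIONS, DilutionSeries
from .exceptions import ParameterError
from .io import CtTable
from .normalize import make_normalizer

__all__ = ["SimScenario", "MethodSummary", "SimSummary",
           "simulate_ct_dataset", "simulate_dilution_series",
           "error_rate_study"]


@dataclass
class SimScenario:
    """Generative parameters for a synthetic two-group Ct experiment.

    Defaults describe the canonical null study: two groups of 30 samples,
    one reference gene at mean Ct 25 with a 2-cycle between-group shift,
    one target gene with slope 0.5 and intercept 10, noise sd 0.5 cycles on
    both genes, no true expression effect, 2000 Monte-Carlo replicates.
    """

    n1: int = 30
    n2: int = 30
    b: float | tuple = 0.5          # target-on-reference slope (scalar or per gene)
    a: float = 10.0                 # target intercept, cycles
    mu_ref: float = 25.0            # mean reference Ct, cycles
    delta_ref: float = 2.0          # group2 − group1 reference shift, cycles
    effect: float | tuple = 0.0     # true target group shift, cycles
    sigma_ref: float = 0.5          # reference noise sd, cycles
    sigma_target: float = 0.5       # target noise sd, cycles
    n_target_genes: int = 1
    n_reference_genes: int = 1
    n_reps: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ParameterError("need at least 2 samples per group")
        if self.sigma_ref < 0 or self.sigma_target < 0:
            raise ParameterError("noise sds must be non-negative")
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        if self.n_target_genes < 1 or self.n_reference_genes < 1:
            raise ParameterError("need at least one target and one reference gene")

    def _per_gene(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float),
                              (self.n_target_genes,))
        return np.array(arr)


def simulate_ct_dataset(scenario: SimScenario,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[CtTable, GroupDesign]:
    """Draw one synthetic Ct table and its two-group design.

    Deterministic given the seed (``seed`` overrides ``scenario.seed``; an
    explicit ``rng`` overrides both and is consumed in place).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n1 + scenario.n2
    in_case = np.repeat([0.0, 1.0], [scenario.n1, scenario.n2])
    samples = [f"S{i + 1:03d}" for i in range(n)]
    labels = ["control"] * scenario.n1 + ["case"] * scenario.n2

    ref_cols = {}
    for k in range(scenario.n_reference_genes):
        ref_cols[f"REF{k + 1}"] = (scenario.mu_ref
                                   + scenario.delta_ref * in_case
                                   + rng.normal(0.0, scenario.sigma_ref, n))
    refs = pd.DataFrame(ref_cols, index=samples)
    driver = refs.mean(axis=1).to_numpy()

    b = scenario._per_gene(scenario.b)
    effect = scenario._per_gene(scenario.effect)
    tgt_cols = {}
    for j in range(scenario.n_target_genes):
        tgt_cols[f"TG{j + 1}"] = (scenario.a + b[j] * driver
                                  + effect[j] * in_case
                                  + rng.normal(0.0, scenario.sigma_target, n))
    targets = pd.DataFrame(tgt_cols, index=samples)

    values = pd.concat([refs, targets], axis=1)
    roles = pd.Series({**{g: "reference" for g in refs.columns},
                       **{g: "target" for g in targets.columns}})
    groups = pd.Series(labels, index=samples)
    table = CtTable(values, roles, groups)
    design = GroupDesign(groups, group1="control", group2="case")
    return table, design


def simulate_dilution_series(E: float, base_ct: float = 25.0,
                             dilutions=DEFAULT_DILUTIONS,
                             noise_sd: float = 0.0,
                             seed: int | None = None,
                             gene_id: str = "gene",
                             sample_id: str = "sample") -> DilutionSeries:
    """Simulate Ct values along a dilution grid at efficiency ``E``.

    ``Ct = base_ct − log2(d)/log2(1+E) + ε`` with ε ~ N(0, noise_sd²).  At
    E = 1 (100%) each doubling of template advances the threshold by
    exactly one cycle, so the dilution-regression slope is −1.
    """
    if E <= -1:
        raise ParameterError("efficiency must exceed -1 (total loss)")
    if E == 0:
        raise ParameterError("efficiency 0 gives no amplification signal")
    d = np.asarray(dilutions, dtype=float)
    if (d <= 0).any():
        raise ParameterError("dilution factors must be positive")
    ct = base_ct - np.log2(d) / np.log2(1.0 + E)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct = ct + rng.normal(0.0, noise_sd, len(d))
    return DilutionSeries(gene_id, sample_id, d, ct)


@dataclass
class MethodSummary:
    """Aggregated Monte-Carlo results for one normalization method."""

    method: str
    rejection_rate: float
    mc_se: float                    # sqrt(r(1-r)/n_tests)
    n_tests: int
    ddct_mean: float
    ddct_bias: float                # mean(ΔΔCt) − true effect
    ddct_rmse: float


@dataclass
class SimSummary:
    """Results of an error-rate study across methods."""

    scenario: SimScenario
    alpha: float
    per_method: dict[str, MethodSummary]
    pvalues: dict[str, np.ndarray] | None = None

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.per_method.values()]
                            ).set_index("method")


def error_rate_study(scenario: SimScenario, alpha: float = 0.05,
                     methods=("delta_ct", "per_gene_regression"),
                     drop_outliers: bool = False,
                     keep_pvalues: bool = False,
                     **norm_kwargs) -> SimSummary:
    """Monte-Carlo comparison of rejection rates across normalizations.

    For each replicate a dataset is generated, normalized by each method
    (the regression fitted on the pooled samples), tested per gene with the
    two-sided Wilcoxon rank-sum test, and the rejection indicator p < alpha
    and the ΔΔCt estimate recorded.  Under the null (``effect = 0``) the
    rejection rate is the empirical false-positive rate; otherwise it is
    power.  The Monte-Carlo standard error is the binomial
    sqrt(r(1−r)/n_tests).

    Reference-gene outlier screening is off by default here: the generator
    produces no gross outliers and the screen is orthogonal to what the
    study measures (it can be re-enabled with ``drop_outliers=True``).
    """
    master = np.random.SeedSequence(scenario.seed)
    children = master.spawn(scenario.n_reps)
    true_effect = float(np.mean(scenario._per_gene(scenario.effect)))

    pvals: dict[str, list] = {m: [] for m in methods}
    ddcts: dict[str, list] = {m: [] for m in methods}
    for child in children:
        table, design = simulate_ct_dataset(
            scenario, rng=np.random.default_rng(child))
        for method in methods:
            normalizer = make_normalizer(method, alpha=alpha,
                                         drop_outliers=drop_outliers,
                                         **norm_kwargs)
            normalized = normalizer.fit_transform(table)
            de = wilcoxon_de(normalized, design)
            pvals[method].extend(de["p"].tolist())
            ddcts[method].extend(de["delta_delta_ct"].tolist())

    per_method = {}
    for method in methods:
        p = np.asarray(pvals[method], dtype=float)
        d = np.asarray(ddcts[method], dtype=float)
        n = len(p)
        rate = float(np.mean(p < alpha))
        per_method[method] = MethodSummary(
            method=method,
            rejection_rate=rate,
            mc_se=math.sqrt(max(rate * (1.0 - rate), 1e-12) / n),
            n_tests=n,
            ddct_mean=float(d.mean()),
            ddct_bias=float(d.mean() - true_effect),
            ddct_rmse=float(np.sqrt(np.mean((d - true_effect) ** 2))),
        )
    return SimSummary(scenario=scenario, alpha=alpha, per_method=per_method,
                      pvalues={m: np.asarray(v) for m, v in pvals.items()}
                      if keep_pvalues else None)
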