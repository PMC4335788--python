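# ctnorm

Regression-based correction of ΔCt normalization bias for RT-qPCR
low-density array data.

## The problem

RT-qPCR expression data are conventionally normalized by subtracting the
threshold cycle (Ct) of a reference ("housekeeping") gene — or the mean Ct
of several — from each target gene's Ct:

    ΔCt = Ct_target − Ct_reference

This implicitly assumes the target's Ct rises one-for-one with the
reference's.  In practice the target-on-reference regression slope *b* is
gene-specific and usually below 1, because PCR amplification efficiencies
differ between assays (a dilution series gives Ct = c − log2(d)/log2(1+E),
so two genes with efficiencies E₁ ≠ E₂ relate with slope ≠ 1).  Plain
subtraction then over-corrects: normalized values become negatively
correlated with the reference Ct, fold changes pick up a spurious
component of (b−1)·(reference group shift), and rank tests reject true
null genes far too often whenever the reference differs between groups.

`ctnorm` implements the fix: estimate *b* by ordinary least squares and
normalize as

    y = Ct_target − b · Ct_reference,

per target gene (with a significance gate on the slope), with a single
shared slope from the mean target profile, or by multiple regression on
all reference genes simultaneously.  Around that core it provides Ct table
I/O with undetectable-value handling, reference-gene outlier screening
(Tukey 1.5×IQR fences), bias diagnostics (Pearson correlation of target
means against references), amplification-efficiency estimation from
dilution series (E = 2^(−1/slope) − 1), two-group Wilcoxon differential
expression with 2^(−ΔΔCt) fold changes, and a seeded Monte-Carlo study of
false-positive rate and power.  It is aimed at anyone analyzing
low-density qPCR arrays or panels of individual assays: the normalizers
are scikit-learn-style transformers (`fit`/`transform`), and everything is
also reachable from a `ctnorm` command line.

## Worked example

Simulate a two-group null experiment in which the reference gene is
shifted by 2 cycles between groups (a loading artifact, not biology) and
targets depend on the reference with slope 0.5, then compare the two
normalizations:

```python
from ctnorm import (SimScenario, simulate_ct_dataset, wilcoxon_de,
                    per_gene_regression_normalize, delta_ct_normalize)

scenario = SimScenario(n1=30, n2=30, b=0.5, delta_ref=2.0, effect=0.0,
                       n_target_genes=3, seed=7)
table, design = simulate_ct_dataset(scenario)

norm = per_gene_regression_normalize(table)
print(norm.model.report()[["gene", "b[reference_summary]", "flag"]])
print(wilcoxon_de(norm, design).round(4))
print(wilcoxon_de(delta_ct_normalize(table), design).round(4))
```

```
gene  b[reference_summary]                flag
 TG1              0.502171  regression_applied
 TG2              0.471581  regression_applied
 TG3              0.418597  regression_applied

per-gene regression:
      n1  n2  delta_delta_ct  fold_change       p
TG1   30  30         -0.0217       1.0151  0.9705
TG2   30  30          0.0255       0.9824  0.9823
TG3   30  30         -0.1099       1.0791  0.1809

delta Ct:
TG1   30  30         -1.1192       2.1723  0.0000
TG2   30  30         -1.1395       2.2030  0.0000
TG3   30  30         -1.3917       2.6239  0.0000
```

The fitted slopes recover the generating value (~0.5).  ΔCt converts the
2-cycle reference shift into a spurious ΔΔCt of about (b−1)·2 ≈ −1 cycle —
an apparent 2-fold change with p ≈ 0 for genes that are not differentially
expressed at all — while the regression-normalized estimates sit near zero
with unremarkable p-values.

Efficiency from a dilution series:

```python
from ctnorm import simulate_dilution_series, fit_dilution_regression
est = fit_dilution_regression(simulate_dilution_series(E=0.9, noise_sd=0.05, seed=1))
print(f"slope={est.slope:.3f}  E={est.efficiency:.3f}  r2={est.r2:.4f}")
# slope=-1.085  E=0.894  r2=0.9997
```

A perfect-doubling assay (E = 1, 100%) gives slope −1 per log2 dilution;
slope −1.085 corresponds to ~89% efficiency.

The same analyses run from the shell (`ctnorm normalize`, `ctnorm de`,
`ctnorm diagnose`, `ctnorm efficiency`, `ctnorm simulate`), or end to end
from a YAML config with `ctnorm run --config run.yaml`, which writes the
normalized table, model report, diagnostics, DE results, outlier report
and a reproducibility manifest.

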