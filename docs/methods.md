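# Methods

## The normalization model

RT-qPCR reports, for each gene in each sample, a threshold cycle Ct: the
PCR cycle at which fluorescence crosses detection, with lower Ct meaning
more starting template.  Conventional normalization subtracts a reference
(housekeeping) summary from each target gene,

    ΔCt_g(i) = Ct_g(i) − R(i),

where R(i) is a chosen reference gene's Ct or the mean Ct of several
references (on the Ct scale the geometric mean of the linear-scale
abundances 2^(−Ct) *is* the arithmetic mean of Ct, so `mean` and
`geometric_mean` reference modes coincide by identity).

Subtraction is only unbiased if the target's Ct depends on the reference's
with slope 1.  With per-cycle amplification efficiency E, a dilution series
follows Ct = c − log2(d)/log2(1+E); between two genes with different
efficiencies, the induced target-on-reference slope is the ratio of their
dilution slopes, which is 1 only when the efficiencies match.  Empirically
the slope is gene-specific and usually below 1, so ΔCt over-corrects: the
per-sample mean of ΔCt values becomes *negatively* correlated with the
reference Ct even though the raw target means are positively correlated.

The correction implemented here fits the slope and subtracts the scaled
reference instead:

    y_g(i) = Ct_g(i) − b_g · R(i),          b_g from OLS of Ct_g on R.

Three regression variants are provided as sklearn-style transformers:

* **per-gene regression** — one OLS slope per target gene on the reference
  summary, each gated by the two-sided t test of b_g = 0 at level `alpha`
  (default 0.05).  A non-significant slope means the reference carries no
  demonstrated information for that gene; the default fallback then leaves
  Ct unsubtracted (`fallback="none"`), with `fallback="delta_ct"` available
  for conventional behavior.  Every gene's effective coefficient and flag
  (`regression_applied` / `fallback_applied`) is recorded in the model.
* **mean-Ct regression** — a single shared slope fitted from the per-sample
  mean target Ct on the reference summary, applied to every gene.  Its
  group-mean fold changes differ from ΔCt's by one gene-independent
  constant (asserted to 1e−10 in the tests); the same significance gate
  applies to the shared slope.
* **multiple regression** — per target gene, one coefficient per reference
  gene fitted jointly, removing the linear dependence on all references at
  once.  The full coefficient vector is applied ungated (gating individual
  coefficients would destroy the residual orthogonality the method exists
  to deliver); per-coefficient p-values are recorded for audit.  Collinear
  references raise an error naming the offending genes; the fit requires at
  least one residual degree of freedom and warns below 3 complete cases per
  regressor.

ΔCt and global-mean normalization (per-sample centering of target Ct) are
included as baselines.  Unlike global-mean, the regression methods do not
force per-sample means to be equal — they only remove the correlation with
the references.

**Intercept convention.**  The intercept is always estimated but never
subtracted; normalized values keep a gene-specific constant offset.  Group
comparisons (ΔΔCt, rank tests) are invariant to it, and leaving it in keeps
the output on a ΔCt-like cycle scale.

**Fitting vs application.**  Coefficients are estimated on the samples that
survive the reference-gene outlier screen; the fitted model is then applied
to *all* samples.  Screening protects the fit from leverage points; it does
not remove samples from the study.

## Quality control and missing data

Undetectable reactions (instrument ceiling 35/39/40 or the token
"Undetermined") are converted to missing at ingestion, so no sentinel
number can enter a regression.  The ceiling is explicit configuration
(default 40, the common 40-cycle truncation) because truncation values
differ by platform and cannot be inferred reliably from a file.

Technical replicates are summarized by their median (with an even count,
the mean of the two central values).  Reference-gene outliers are flagged
per gene with Tukey fences at 1.5×IQR beyond the quartiles, computed over
non-missing values after undetectable filtering, using linear interpolation
between order statistics (the "type 7" quantile convention; recorded in the
outlier report).  Samples with more than one flagged reference are excluded
from fitting.  Flag + drop runs exactly once per pipeline; fences are not
recomputed on the reduced table.

All regressions are pairwise/casewise-complete.  Normalized output is
missing exactly where the target or any reference with a nonzero effective
coefficient is missing.

## Differential expression

Per gene, ΔΔCt = mean(group2) − mean(group1) of normalized values;
positive ΔΔCt means higher Ct — lower expression — in group 2, and
fold change = 2^(−ΔΔCt).  The two-sided Wilcoxon rank-sum test uses the
exact null distribution when min(n1, n2) ≤ 10 and there are no ties, and
the normal approximation with tie and continuity corrections otherwise.
Because the test is rank-based, per-gene shifts common to both groups
(e.g. the constant separating ΔCt from shared-slope regression output on
complete data) leave p-values unchanged.  No multiplicity adjustment is
applied by default; Benjamini–Hochberg is available behind a flag.

## The synthetic generator and the error-rate study

The generator draws exactly the structure the model assumes: reference Ct
is Gaussian around `mu_ref` with a between-group shift `delta_ref` (a
loading/efficiency artifact, not biology), and each target is
`a + b·R + effect·1[group2]` plus Gaussian noise, with R the mean reference
Ct.  Defaults: two groups of 30, one reference gene at mean Ct 25 with
`delta_ref = 2`, one target with `b = 0.5`, `a = 10`, noise sd 0.5 cycles
on both genes, `effect = 0` (null), 2000 Monte-Carlo replicates.  Seeding
uses one master `SeedSequence` with per-replicate spawned streams, so
results are reproducible and independent of replicate order.

What it does **not** emulate: Ct truncation/undetectable censoring,
heavy-tailed or sample-quality outliers, replicate-level technical noise,
correlated noise across genes, and efficiency drift across samples.
Passing tests therefore demonstrate the statistical mechanics of the
methods under the assumed linear-Gaussian structure, not robustness to
everything real arrays do.

`error_rate_study` generates each replicate, normalizes it by ΔCt and by
per-gene regression (slope fitted on the pooled samples of that
replicate), runs the Wilcoxon test, and aggregates rejection rates with
binomial Monte-Carlo standard errors plus bias/RMSE of ΔΔCt against the
true effect.  Under the shifted null the ΔCt group difference has
expectation (b−1)·delta_ref (−1 cycle at the defaults), which drives its
false-positive rate toward 1 at these noise levels, while the
regression-normalized ΔΔCt is unbiased with smaller RMSE.  The outlier
screen is off inside the study by default (Gaussian draws produce no gross
outliers; it can be re-enabled).

**A calibration caveat worth knowing.**  When the slope is refitted on the
very samples being tested and the reference shift is large relative to the
reference's within-group spread, the OLS fit absorbs most of the group
contrast: residuals are orthogonal to the reference, the reference is
nearly a group indicator, and the realized group contrast of the
normalized values is under-dispersed relative to the Wilcoxon null.  The
between-group leverage share is f = (Δ/2)² / ((Δ/2)² + σ_ref²); the
contrast variance shrinks by (1−f).  At the default null scenario
(Δ = 2, σ_ref = 0.5, f = 0.8) the empirical false-positive rate is
therefore far *below* nominal (≈ 0 rather than 0.05) — conservative, never
anticonservative.  With Δ = 0, or with the slope known or estimated from
independent data, the rate sits at the nominal level (≈ 0.046–0.05 with
the continuity correction).  The package reports the refit-per-replicate
rate as measured rather than substituting a design that would land on
0.05.

## Numerical choices

* Simple OLS is closed-form (cross-check against statsmodels in the test
  suite); multiple OLS goes through statsmodels.  Slope p-values are
  two-sided t tests.
* Zero-residual degenerate fits: exact collinearity with a nonzero slope
  reports p = 0 with a warning (the t statistic is undefined but the
  evidence is perfect); a constant response reports slope 0 with p = 1.
  The zero-residual threshold is a 1e−12 relative tolerance on the
  residual sum of squares.
* Collinearity is detected by rank of the design matrix; offending columns
  are identified as those lying in the span of earlier columns.
* Efficiency is reported as a fraction (1.0 = 100%); formatting as percent
  is presentation-layer.  A non-negative dilution slope yields NaN
  efficiency with a warning rather than an error.
* Dilution series are fitted per (gene, sample); replicates are median-
  summarized before fitting.

## Problem sizes

The test suite runs synthetic tables of 20–120 samples and up to 5 genes,
Monte-Carlo loops of 100–600 replicates, plus one 2000-replicate
false-positive-rate study; the acceptance script reruns the seven-point
dilution identity and the 2000-replicate null study.  The whole suite
completes in well under a minute on one core, the acceptance script in
about fifteen seconds.

## Limitations

* The method assumes an approximately linear target–reference relationship
  on the Ct scale; it corrects slope bias, not nonlinearity.
* Coefficients fitted on one dataset do not transfer to another (different
  plates/chemistry change slopes and intercepts); datasets must be
  normalized separately, and combining them afterwards needs additional
  mean adjustment that is out of scope here.
* With very small sample sizes the slope estimates are noisy and the gate
  will frequently fall back; multiple regression additionally needs
  samples well in excess of the number of references.
* Robust regression as a replacement for the outlier screen, efficiency-
  corrected ΔCt, kinetic-curve efficiency estimation, and
  quantile/rank-invariant normalization are deliberately not implemented.
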