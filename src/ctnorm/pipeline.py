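"""End-to-end pipeline: read → QC → normalize → diagnose → DE → manifest.

A run is a pure function of (inputs, config, seed).  Every run writes a
manifest recording the exact configuration, package version, stage-by-stage
sample/gene counts and the statistical conventions in force (quantile rule,
Wilcoxon variant, per-gene fallback decisions), so the choices that a raw
Ct file cannot express are auditable afterwards.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import GroupDesign, wilcoxon_de
from .diagnostics import diagnose_bias, diagnostics_frame
from .exceptions import ConfigurationError, CtNormError, PipelineError
from .io import (UndetectablePolicy, read_ct_table, read_design,
                 write_ct_table)
from .normalize import METHODS, make_normalizer
from .qc import QUANTILE_CONVENTION, drop_outlier_samples, flag_reference_outliers

__all__ = ["RunConfig", "load_config", "run_pipeline"]

_METHOD_ALIASES = {"per_gene", "mean_regression", "multiple"} | set(METHODS)


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    input: str
    design: str | None = None
    layout: str = "long"
    output_dir: str = "ctnorm_out"
    method: str = "per_gene"
    reference_mode: str = "mean"
    alpha: float = 0.05
    fallback: str = "none"
    ceiling: float = 40.0
    undetectable_codes: list[str] = field(
        default_factory=lambda: ["undetermined", "undetected", "na"])
    complete_only: bool = False
    drop_outliers: bool = True
    seed: int = 0

    def policy(self) -> UndetectablePolicy:
        return UndetectablePolicy(ceiling=self.ceiling,
                                  codes=frozenset(c.lower() for c in
                                                  self.undetectable_codes))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected by name (typos must not silently fall back to
    defaults); ``input`` is the only required key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such config file: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a key-value document")
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown config key(s): {sorted(unknown)}; valid keys are "
            f"{sorted(valid)}")
    if "input" not in raw:
        raise ConfigurationError("config is missing the required key 'input'")
    cfg = RunConfig(**raw)
    if cfg.method not in _METHOD_ALIASES:
        raise ConfigurationError(
            f"unknown method {cfg.method!r}; choose from {sorted(METHODS)}")
    return cfg


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and return the paths written.

    Outputs (in ``config.output_dir``): ``normalized.csv``,
    ``model_report.csv``, ``diagnostics.csv``, ``outlier_report.csv``,
    ``de_results.csv`` (when a design is given) and ``manifest.json``.  Any
    stage failure raises :class:`PipelineError` tagged with the stage and
    removes partial outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    manifest: dict = {"config": asdict(config), "version": __version__,
                      "seed": config.seed, "counts": {}, "conventions": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except CtNormError as exc:
                for p in written.values():
                    p.unlink(missing_ok=True)
                raise PipelineError(name, str(exc)) from exc
        return deco

    @stage("read")
    def table():
        t = read_ct_table(config.input, layout=config.layout,
                          policy=config.policy())
        manifest["counts"]["samples_input"] = len(t.samples)
        manifest["counts"]["genes"] = len(t.genes)
        manifest["counts"]["reference_genes"] = len(t.reference_genes)
        manifest["counts"]["target_genes"] = len(t.target_genes)
        return t

    @stage("qc")
    def qc():
        report = flag_reference_outliers(table)
        retained = drop_outlier_samples(table, report)
        path = outdir / "outlier_report.csv"
        report.to_frame(table).to_csv(path, index=False)
        written["outlier_report"] = path
        manifest["counts"]["samples_retained_for_fit"] = len(retained.samples)
        manifest["counts"]["samples_dropped"] = len(report.dropped_samples)
        manifest["conventions"]["quantile"] = report.quantile_convention
        manifest["conventions"]["outlier_rule"] = (
            "reference Ct beyond 1.5*IQR Tukey fences; samples with >1 "
            "flagged reference excluded from fitting only")
        return report

    @stage("normalize")
    def normalized():
        normalizer = make_normalizer(
            config.method, reference_mode=config.reference_mode,
            alpha=config.alpha, fallback=config.fallback,
            drop_outliers=config.drop_outliers)
        result = normalizer.fit_transform(table)
        path = outdir / "normalized.csv"
        write_ct_table(result, path, layout="long")
        written["normalized"] = path
        rpath = outdir / "model_report.csv"
        result.model.report().to_csv(rpath, index=False)
        written["model_report"] = rpath
        flags = result.model.flags
        manifest["counts"]["genes_normalized"] = len(result.genes)
        manifest["counts"]["flags"] = flags.value_counts().to_dict()
        manifest["conventions"]["fallback"] = config.fallback
        manifest["conventions"]["intercept"] = (
            "estimated but not subtracted; gene-specific offsets cancel in "
            "group comparisons")
        return result

    @stage("diagnose")
    def diagnostics():
        diags = diagnose_bias(table, normalized=normalized,
                              mode=config.reference_mode)
        path = outdir / "diagnostics.csv"
        diagnostics_frame(diags).to_csv(path, index=False)
        written["diagnostics"] = path
        return diags

    if config.design is not None:
        @stage("de")
        def de():
            groups = read_design(config.design)
            design = GroupDesign(groups)
            result = wilcoxon_de(normalized, design,
                                 complete_only=config.complete_only)
            path = outdir / "de_results.csv"
            result.to_csv(path)
            written["de_results"] = path
            manifest["counts"]["genes_tested"] = int(result["p"].notna().sum())
            manifest["conventions"]["wilcoxon"] = (
                "exact null distribution when min(n1,n2) <= 10 and no ties; "
                "otherwise normal approximation with tie and continuity "
                "corrections")
            return result
    else:
        manifest["conventions"]["de"] = "skipped: no design file configured"

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = mpath
    return written
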