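"""Reading and writing Ct tables.

A *Ct table* is a rectangular samples × genes grid of qPCR threshold-cycle
(Ct) values.  Each gene carries a role — ``target`` or ``reference``
(housekeeping) — and each sample may carry a group label.  Undetectable
reactions (reported by the instrument as the cycle ceiling, typically 40, or
as the token "Undetermined") are encoded as missing values at ingestion so
that no sentinel number can leak into downstream regressions.

Two delimited-text layouts are supported:

* ``long`` — one row per observation with columns
  ``sample,gene,role,ct[,group,replicate]``.  This is the canonical layout.
* ``wide`` — first column ``sample`` (optionally followed by ``group``), one
  column per gene, and a second header row whose ``sample`` cell reads
  ``role`` giving each gene's role.

Technical replicates are summarized by their median, following standard
low-density-array practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    DuplicateRecordError,
    FormatError,
)

__all__ = [
    "UndetectablePolicy",
    "CtRecord",
    "CtTable",
    "apply_undetectable_policy",
    "summarize_replicates",
    "read_ct_table",
    "write_ct_table",
    "read_design",
]

ROLES = ("target", "reference")

#: Maximum physically plausible threshold cycle.
CT_MAX = 50.0


@dataclass(frozen=True)
class UndetectablePolicy:
    """How undetectable reactions are encoded in a raw file.

    Parameters
    ----------
    ceiling : float
        Ct at or above which a value is treated as undetectable.  Instruments
        truncate at 35, 39 or 40 depending on the platform; 40 is the common
        default for 40-cycle runs.
    codes : frozenset of str
        Case-insensitive text tokens treated as undetectable.
    """

    ceiling: float = 40.0
    codes: frozenset[str] = frozenset({"undetermined", "undetected", "na"})

    def __post_init__(self):
        if not (self.ceiling > 0):
            raise ConfigurationError("undetectable ceiling must be positive")


@dataclass
class CtRecord:
    """A single (sample, gene, replicate) Ct observation."""

    sample_id: str
    gene_id: str
    role: str
    ct: float  # NaN encodes missing/undetectable
    group: str | None = None
    replicate: str | None = None


def apply_undetectable_policy(ct, policy: UndetectablePolicy = UndetectablePolicy()):
    """Map a raw Ct cell (number or text token) to a float or NaN.

    Values at or above ``policy.ceiling`` and tokens in ``policy.codes``
    become NaN.  A non-numeric token not covered by the policy raises
    :class:`FormatError`.
    """
    if isinstance(ct, str):
        token = ct.strip()
        if token == "" or token.lower() in policy.codes:
            return math.nan
        try:
            ct = float(token)
        except ValueError:
            raise FormatError(
                f"Ct value {ct!r} is neither numeric nor a recognized "
                f"undetectable code {sorted(policy.codes)}"
            ) from None
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return math.nan
    ct = float(ct)
    if ct >= policy.ceiling:
        return math.nan
    if ct <= 0 or ct > CT_MAX:
        raise FormatError(f"Ct value {ct} outside the plausible range (0, {CT_MAX}]")
    return ct


def summarize_replicates(records: Iterable[CtRecord]) -> list[CtRecord]:
    """Collapse technical replicates to one record per (sample, gene).

    The median of the non-missing replicate Ct values is used; a group whose
    replicates are all missing yields a missing Ct.  With an even number of
    non-missing replicates the median is the mean of the two central values.
    The result is invariant to replicate order.
    """
    out: dict[tuple[str, str], list[CtRecord]] = {}
    for rec in records:
        out.setdefault((rec.sample_id, rec.gene_id), []).append(rec)
    summarized = []
    for (sample, gene), group in out.items():
        cts = [r.ct for r in group if not math.isnan(r.ct)]
        ct = float(np.median(cts)) if cts else math.nan
        first = group[0]
        summarized.append(
            CtRecord(sample, gene, first.role, ct, group=first.group, replicate=None)
        )
    return summarized


class CtTable:
    """Samples × genes grid of Ct values with gene roles and sample groups.

    Parameters
    ----------
    values : pandas.DataFrame
        Ct values, index = sample ids, columns = gene ids; NaN marks missing.
    roles : pandas.Series
        Gene id → ``"target"`` or ``"reference"``.
    groups : pandas.Series, optional
        Sample id → group label.
    """

    def __init__(self, values: pd.DataFrame, roles: pd.Series,
                 groups: pd.Series | None = None):
        roles = pd.Series(roles, dtype=object)
        unknown = set(roles.unique()) - set(ROLES)
        if unknown:
            raise FormatError(f"unknown gene roles: {sorted(unknown)}")
        missing_roles = [g for g in values.columns if g not in roles.index]
        if missing_roles:
            raise FormatError(f"genes without a role: {missing_roles}")
        roles = roles.reindex(values.columns)
        if not (roles == "reference").any():
            raise FormatError("Ct table needs at least one reference gene")
        if not (roles == "target").any():
            raise FormatError("Ct table needs at least one target gene")
        if groups is not None:
            groups = pd.Series(groups, dtype=object).reindex(values.index)
        self.values = values.astype(float)
        self.roles = roles
        self.groups = groups

    # -- basic accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def reference_genes(self) -> list[str]:
        return list(self.roles.index[self.roles == "reference"])

    @property
    def target_genes(self) -> list[str]:
        return list(self.roles.index[self.roles == "target"])

    @property
    def references(self) -> pd.DataFrame:
        return self.values[self.reference_genes]

    @property
    def targets(self) -> pd.DataFrame:
        return self.values[self.target_genes]

    def subset_samples(self, samples: Sequence[str]) -> "CtTable":
        samples = [s for s in self.samples if s in set(samples)]
        if not samples:
            raise DegenerateDataError("sample subset is empty")
        groups = self.groups.loc[samples] if self.groups is not None else None
        return CtTable(self.values.loc[samples].copy(), self.roles.copy(), groups)

    def to_records(self) -> list[CtRecord]:
        recs = []
        for sample in self.samples:
            group = None if self.groups is None else self.groups.get(sample)
            if isinstance(group, float) and math.isnan(group):
                group = None
            for gene in self.genes:
                recs.append(CtRecord(sample, gene, self.roles[gene],
                                     float(self.values.at[sample, gene]),
                                     group=group))
        return recs

    def equals(self, other: "CtTable", atol: float = 1e-6) -> bool:
        if self.samples != other.samples or self.genes != other.genes:
            return False
        if not self.roles.equals(other.roles):
            return False
        a, b = self.values.to_numpy(), other.values.to_numpy()
        same = np.isclose(a, b, atol=atol) | (np.isnan(a) & np.isnan(b))
        return bool(same.all())

    def __repr__(self):
        n_ref = len(self.reference_genes)
        return (f"CtTable({len(self.samples)} samples × {len(self.genes)} genes, "
                f"{n_ref} reference)")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _records_to_table(records: list[CtRecord]) -> CtTable:
    samples, genes, roles = [], [], {}
    groups: dict[str, str] = {}
    seen_s, seen_g = set(), set()
    for r in records:
        if r.sample_id not in seen_s:
            seen_s.add(r.sample_id)
            samples.append(r.sample_id)
        if r.gene_id not in seen_g:
            seen_g.add(r.gene_id)
            genes.append(r.gene_id)
        prev = roles.setdefault(r.gene_id, r.role)
        if prev != r.role:
            raise FormatError(f"gene {r.gene_id!r} has conflicting roles "
                              f"{prev!r} and {r.role!r}")
        if r.group is not None:
            prev_g = groups.setdefault(r.sample_id, r.group)
            if prev_g != r.group:
                raise FormatError(f"sample {r.sample_id!r} has conflicting "
                                  f"group labels {prev_g!r} and {r.group!r}")
    values = pd.DataFrame(np.nan, index=samples, columns=genes)
    for r in records:
        values.at[r.sample_id, r.gene_id] = r.ct
    group_series = pd.Series(groups).reindex(samples) if groups else None
    return CtTable(values, pd.Series(roles), group_series)


def _read_long(path, policy: UndetectablePolicy) -> CtTable:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"sample", "gene", "role", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"long layout requires columns {sorted(required)}; "
                          f"missing {sorted(missing)}")
    has_rep = "replicate" in df.columns
    has_group = "group" in df.columns
    if not has_rep:
        dup = df.duplicated(subset=["sample", "gene"])
        if dup.any():
            pairs = df.loc[dup, ["sample", "gene"]].drop_duplicates()
            raise DuplicateRecordError(
                "duplicate (sample, gene) rows without a replicate column: "
                + ", ".join(f"({s}, {g})" for s, g in pairs.itertuples(index=False))
            )
    records = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        group = rec.get("group")
        if isinstance(group, float) and math.isnan(group):
            group = None
        records.append(CtRecord(
            sample_id=str(rec["sample"]).strip(),
            gene_id=str(rec["gene"]).strip(),
            role=str(rec["role"]).strip().lower(),
            ct=apply_undetectable_policy(rec["ct"], policy),
            group=None if group is None else str(group).strip(),
            replicate=str(rec["replicate"]).strip() if has_rep else None,
        ))
    if has_rep:
        records = summarize_replicates(records)
    return _records_to_table(records)


def _read_wide(path, policy: UndetectablePolicy) -> CtTable:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.strip() for c in df.columns]
    first = df.columns[0].lower()
    if first != "sample":
        raise FormatError("wide layout requires 'sample' as the first column")
    has_group = len(df.columns) > 1 and df.columns[1].lower() == "group"
    gene_cols = list(df.columns[2:]) if has_group else list(df.columns[1:])
    if not gene_cols:
        raise FormatError("wide layout has no gene columns")
    key = df.iloc[:, 0].astype(str).str.strip().str.lower()
    role_rows = df.index[key == "role"]
    if len(role_rows) != 1:
        raise FormatError("wide layout requires exactly one 'role' row "
                          "giving target/reference per gene")
    role_row = df.loc[role_rows[0]]
    roles = pd.Series({g: str(role_row[g]).strip().lower() for g in gene_cols})
    data = df.drop(index=role_rows)
    records = []
    for rec in data.to_dict("records"):
        sample = str(rec[df.columns[0]]).strip()
        group = None
        if has_group:
            raw = rec[df.columns[1]]
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                group = str(raw).strip() or None
        for g in gene_cols:
            records.append(CtRecord(sample, g, roles[g],
                                    apply_undetectable_policy(rec[g], policy),
                                    group=group))
    return _records_to_table(records)


def read_ct_table(path, layout: str = "long",
                  policy: UndetectablePolicy = UndetectablePolicy()) -> CtTable:
    """Read a Ct table from a delimited text file.

    Parameters
    ----------
    path : path-like
        ``.csv`` (comma) or ``.tsv``/``.tab``/``.txt`` (tab) file.
    layout : {"long", "wide"}
        See the module docstring for the two layouts.
    policy : UndetectablePolicy
        Undetectable-value encoding; applied to every cell before any
        statistics, so sentinel numbers never survive ingestion.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if layout == "long":
        return _read_long(path, policy)
    if layout == "wide":
        return _read_wide(path, policy)
    raise ConfigurationError(f"unknown layout {layout!r}; use 'long' or 'wide'")


def write_ct_table(table, path, layout: str = "long") -> None:
    """Write a :class:`CtTable` (or a normalized table) to delimited text.

    Missing values are written as empty cells, never as sentinel numbers.
    ``read_ct_table(write_ct_table(t))`` reproduces ``t`` up to float
    formatting.
    """
    path = Path(path)
    values = table.values
    roles = table.roles
    groups = getattr(table, "groups", None)
    if values.empty:
        raise DegenerateDataError("refusing to write an empty table")
    sep = _sep_for(path)
    if layout == "long":
        rows = []
        for sample in values.index:
            group = None if groups is None else groups.get(sample)
            for gene in values.columns:
                row = {"sample": sample, "gene": gene, "role": roles[gene],
                       "ct": values.at[sample, gene]}
                if groups is not None:
                    row["group"] = group
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        out = values.copy()
        header = {"sample": "role"}
        if groups is not None:
            header["group"] = ""
        role_row = pd.DataFrame(
            [{**header, **{g: roles[g] for g in out.columns}}])
        body = out.reset_index(names="sample")
        if groups is not None:
            body.insert(1, "group", [groups.get(s) for s in values.index])
        pd.concat([role_row, body], ignore_index=True).to_csv(
            path, sep=sep, index=False)
    else:
        raise ConfigurationError(f"unknown layout {layout!r}")


def read_dilution_table(path, policy: UndetectablePolicy | None = None) -> pd.DataFrame:
    """Read a dilution-series file with columns gene,sample,dilution[,replicate],ct.

    Replicates are summarized by their median per (gene, sample, dilution).
    Returns a tidy frame with columns gene, sample, dilution, ct.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"gene", "sample", "dilution", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"dilution file requires columns {sorted(required)}; "
                          f"missing {sorted(missing)}")
    policy = policy or UndetectablePolicy()
    df["ct"] = [apply_undetectable_policy(v, policy) for v in df["ct"]]
    df["dilution"] = df["dilution"].astype(float)
    if (df["dilution"] <= 0).any():
        raise FormatError("dilution factors must be positive")
    out = (df.groupby(["gene", "sample", "dilution"], sort=False)["ct"]
             .median().reset_index())
    return out


def read_design(path) -> pd.Series:
    """Read a sample → group design file with columns sample,group."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"sample", "group"} <= set(df.columns):
        raise FormatError("design file requires columns sample,group")
    return pd.Series(df["group"].str.strip().values,
                     index=df["sample"].str.strip().values, name="group")
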