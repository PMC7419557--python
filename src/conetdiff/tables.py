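"""Abundance-table I/O, prevalence filtering and compositionality diagnostics.

The universal input is a feature × sample table of relative abundances
(MetaPhlAn-style species tables or HUMAnN2-style pathway tables) together with
per-sample metadata (cohort, age, sex, read depth). Tables arrive as TSV with
features as rows; the raw MetaPhlAn percent scale is auto-detected from the
column sums and normalized to fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("sample", "cohort", "age", "sex", "read_depth")

#: column sums above this are taken to be on the percent scale
PERCENT_DETECT = 1.5


@dataclass
class AbundanceTable:
    """Feature × sample relative abundances (fractions).

    ``data`` holds features as rows and samples as columns. For pathway
    tables, species-stratified rows ("PWY|g__X.s__Y") are split off into
    ``stratified`` and only community-level rows remain in ``data``.
    """

    data: pd.DataFrame
    level: str  # "species" or "pathway"
    stratified: pd.DataFrame | None = None

    def __post_init__(self):
        if self.level not in ("species", "pathway"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature names: {dups}")
        if (self.data.values < 0).any():
            raise ValueError("negative abundance values")
        colsum = self.data.sum(axis=0)
        if (colsum > 1 + 1e-6).any():
            bad = colsum[colsum > 1 + 1e-6].index.tolist()
            raise ValueError(f"sample columns sum above 1: {bad}")

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CountTable:
    """Predicted read counts on the same axes as an :class:`AbundanceTable`."""

    data: pd.DataFrame
    level: str = "species"

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class CompositionSummary:
    """Per-cohort effective feature number and per-feature prevalence."""

    n_eff_mean: dict[str, float]  # mean of per-sample inverse Simpson
    n_eff_of_mean: dict[str, float]  # inverse Simpson of the mean composition
    prevalence: pd.DataFrame = field(default_factory=pd.DataFrame)  # feature × cohort


def _is_species_row(name: str) -> bool:
    last = name.split("|")[-1]
    return last.startswith("s__")


def _is_strain_row(name: str) -> bool:
    return name.split("|")[-1].startswith("t__")


def read_abundance_table(path, level: str) -> AbundanceTable:
    """Read a TSV abundance table (features as rows, samples as columns).

    Species tables are restricted to species-level rows (clades whose deepest
    rank is ``s__``; higher ranks and ``t__`` strain rows are dropped).
    Pathway tables are split into unstratified community rows and a
    stratified ("pathway|species") store used for contribution analysis.
    Percent-scale input is detected from column sums and divided by 100.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature names in {path}: {dups}")
    values = df.apply(pd.to_numeric)
    if (values.values < 0).any():
        raise ValueError(f"negative values in {path}")

    stratified = None
    if level == "species":
        keep = [f for f in values.index if _is_species_row(f) and not _is_strain_row(f)]
        values = values.loc[keep]
        # name by the species segment only
        values.index = [f.split("|")[-1] for f in values.index]
    elif level == "pathway":
        strat_rows = [f for f in values.index if "|" in f]
        stratified = values.loc[strat_rows]
        values = values.drop(index=strat_rows)
    else:
        raise ValueError(f"unknown level {level!r}")

    colsum = values.sum(axis=0)
    if (colsum > PERCENT_DETECT).any():
        values = values / 100.0
        if stratified is not None:
            stratified = stratified / 100.0
    return AbundanceTable(data=values, level=level, stratified=stratified)


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata TSV with columns sample, cohort, age, sex, read_depth."""
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if (meta["read_depth"] <= 0).any():
        raise ValueError("read_depth must be positive")
    return meta.set_index("sample", drop=False)


def validate_samples(table: AbundanceTable, metadata: pd.DataFrame) -> None:
    """Require exactly one metadata row for every sample in the table."""
    missing = [s for s in table.samples if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")


def prevalence(table: AbundanceTable | pd.DataFrame) -> pd.Series:
    """Fraction of samples in which each feature is detected (> 0 strictly)."""
    df = table.data if isinstance(table, AbundanceTable) else table
    if df.shape[1] == 0:
        raise ValueError("empty table")
    return (df > 0).mean(axis=1)


def prevalence_filter(
    tables: dict[str, AbundanceTable],
    threshold: float = 0.20,
    strict: bool = False,
) -> list[str]:
    """Features present in ≥ ``threshold`` of samples in at least one cohort.

    Tables share an outer-union feature namespace (absent features count as
    zero abundance). ``strict=True`` switches the boundary to ``>``. The
    returned order follows first appearance across cohorts.
    """
    if not tables:
        raise ValueError("no cohort tables supplied")
    union: list[str] = []
    for t in tables.values():
        if t.data.shape[1] == 0:
            raise ValueError("empty table")
        for f in t.features:
            if f not in union:
                union.append(f)
    retained = []
    for f in union:
        for t in tables.values():
            if f in t.data.index:
                prev = float((t.data.loc[f] > 0).mean())
            else:
                prev = 0.0
            if (prev > threshold) if strict else (prev >= threshold):
                retained.append(f)
                break
    return retained


def to_counts(table: AbundanceTable, metadata: pd.DataFrame) -> CountTable:
    """Predicted read counts: abundance × read depth, rounded half away from zero."""
    validate_samples(table, metadata)
    missing = metadata.loc[table.samples, "read_depth"].isna()
    if missing.any():
        raise ValueError(
            f"missing read_depth for samples: {list(missing[missing].index)}"
        )
    depth = metadata.loc[table.samples, "read_depth"].to_numpy(dtype=float)
    raw = table.data.to_numpy() * depth[None, :]
    counts = np.floor(raw + 0.5).astype(np.int64)  # values are non-negative
    return CountTable(
        data=pd.DataFrame(counts, index=table.data.index, columns=table.data.columns),
        level=table.level,
    )


def inverse_simpson(composition) -> float:
    """Effective number of features n_eff = 1 / Σ p_i² of a composition.

    The vector is renormalized to sum 1; an all-zero vector is an error.
    """
    p = np.asarray(composition, dtype=float)
    if (p < 0).any():
        raise ValueError("negative composition entries")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero composition")
    p = p / total
    return float(1.0 / np.sum(p**2))


def composition_summary(tables: dict[str, AbundanceTable]) -> CompositionSummary:
    """Per-cohort n_eff (mean over samples, and of the mean composition) and prevalence."""
    n_eff_mean, n_eff_of_mean, prev = {}, {}, {}
    for cohort, t in tables.items():
        per_sample = [
            inverse_simpson(t.data[s].to_numpy())
            for s in t.samples
            if t.data[s].sum() > 0
        ]
        n_eff_mean[cohort] = float(np.mean(per_sample))
        n_eff_of_mean[cohort] = inverse_simpson(t.data.mean(axis=1).to_numpy())
        prev[cohort] = prevalence(t)
    return CompositionSummary(
        n_eff_mean=n_eff_mean,
        n_eff_of_mean=n_eff_of_mean,
        prevalence=pd.DataFrame(prev),
    )


def write_table(df: pd.DataFrame, path, index_label: str = "feature") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)
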