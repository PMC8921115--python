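"""Metabolite excretion tables, their I/O and phase-II phenotyping.

The central container is :class:`MetaboliteTable`: a samples x metabolites
matrix of urinary amounts (µmol excreted over 24 h) with per-sample metadata
(subject, study arm, dose/visit) and per-variable annotations (parent
aglycone and conjugate class).  Two schemas exist: the 11-variable
individual-metabolite table and the 4-variable table of sums per aglycone.

The phase-II phenotyping implemented here is the per-sample
sulfate/glucuronide ratio, overall and per aglycone group; a subject whose
ratio exceeds 1.1 is flagged sulfate-dominant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ["sample_id", "subject_id", "study", "condition"]
MISSING_TOKENS = ["", "NA", "NaN"]

AGLYCONE_GROUPS = ("3'OH-PVL", "4'OH-PVL", "3'4'diOH-PVL", "HPP")
CONJUGATE_CLASSES = (
    "sulfate",
    "glucuronide",
    "sulfo-glucuronide",
    "aglycone",
    "methoxy-sulfate",
)

# The 11 quantified conjugates: (column name, aglycone group, conjugate class).
# PVL = phenyl-gamma-valerolactone, PPA = 3-(phenyl)propanoic acid.
METABOLITES_11 = [
    ("PVL-3'-sulfate", "3'OH-PVL", "sulfate"),
    ("PVL-3'-glucuronide", "3'OH-PVL", "glucuronide"),
    ("PVL-4'-glucuronide", "4'OH-PVL", "glucuronide"),
    ("diOH-PVL", "3'4'diOH-PVL", "aglycone"),
    ("PVL-sulfate-3'4'", "3'4'diOH-PVL", "sulfate"),
    ("4'OH-PVL-3'-glucuronide", "3'4'diOH-PVL", "glucuronide"),
    ("3'OH-PVL-4'-glucuronide", "3'4'diOH-PVL", "glucuronide"),
    ("PVL-methoxy-sulfate", "3'4'diOH-PVL", "methoxy-sulfate"),
    ("PVL-sulfate-glucuronide", "3'4'diOH-PVL", "sulfo-glucuronide"),
    ("PPA-sulfate", "HPP", "sulfate"),
    ("PPA-glucuronide", "HPP", "glucuronide"),
]

METABOLITE_NAMES_11 = [m[0] for m in METABOLITES_11]

SULFATE_DOMINANCE_THRESHOLD = 1.1


def default_var_meta() -> pd.DataFrame:
    """Variable annotations of the 11-metabolite schema."""
    return pd.DataFrame(
        METABOLITES_11,
        columns=["metabolite_name", "aglycone_group", "conjugate_class"],
    ).set_index("metabolite_name")


def aggregated_var_meta() -> pd.DataFrame:
    """Variable annotations of the 4-variable aglycone-sum schema."""
    return pd.DataFrame(
        {"aglycone_group": list(AGLYCONE_GROUPS), "conjugate_class": "aglycone"},
        index=pd.Index(list(AGLYCONE_GROUPS), name="metabolite_name"),
    )


class SchemaError(ValueError):
    """Raised when a table does not conform to its declared variable schema."""


@dataclass
class MetaboliteTable:
    """Samples x metabolites table of 24-h urinary excretion amounts.

    Parameters
    ----------
    values
        DataFrame indexed by sample_id, one column per metabolite, amounts in
        µmol/24 h (non-negative; NaN marks a missing measurement).
    sample_meta
        DataFrame indexed by sample_id with columns subject_id, study
        (``acute``/``chronic``) and condition (dose in mg or visit label).
    var_meta
        DataFrame indexed by metabolite name with columns aglycone_group and
        conjugate_class.
    aggregated
        True for the 4-variable aglycone-sum schema.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    var_meta: pd.DataFrame
    aggregated: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise SchemaError(f"duplicate sample_id(s): {dups}")
        unknown = [c for c in self.values.columns if c not in self.var_meta.index]
        if unknown:
            raise SchemaError(f"columns not in schema: {unknown}")
        if not self.values.index.equals(self.sample_meta.index):
            raise SchemaError("values and sample_meta indexes differ")
        bad_group = set(self.var_meta["aglycone_group"]) - set(AGLYCONE_GROUPS)
        if bad_group:
            raise SchemaError(f"unknown aglycone group(s): {sorted(bad_group)}")
        bad_class = set(self.var_meta["conjugate_class"]) - set(CONJUGATE_CLASSES)
        if bad_class:
            raise SchemaError(f"unknown conjugate class(es): {sorted(bad_class)}")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if np.any(~np.isfinite(finite)):
            raise SchemaError("non-finite (inf) values present")
        if np.any(finite < 0):
            raise SchemaError("negative amounts present")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def columns_of_class(self, conjugate_class: str) -> list[str]:
        mask = self.var_meta.loc[self.values.columns, "conjugate_class"] == conjugate_class
        return list(self.values.columns[mask.to_numpy()])

    def columns_of_group(self, aglycone_group: str) -> list[str]:
        mask = self.var_meta.loc[self.values.columns, "aglycone_group"] == aglycone_group
        return list(self.values.columns[mask.to_numpy()])


def read_metabolite_table(
    path: str | Path,
    var_meta: pd.DataFrame | None = None,
    *,
    delimiter: str | None = None,
    aggregated: bool = False,
) -> MetaboliteTable:
    """Read a delimited-text metabolite table.

    The file must carry a header row with the metadata block
    ``sample_id, subject_id, study, condition`` followed by numeric
    metabolite columns.  Delimiter is inferred from the extension
    (``.tsv`` -> tab, otherwise comma) unless given explicitly.  Missing
    tokens: empty cell, ``NA``, ``NaN``.  Unparseable numeric cells become
    missing with a logged warning; duplicate sample ids and columns absent
    from the schema are hard errors.
    """
    path = Path(path)
    if var_meta is None:
        var_meta = aggregated_var_meta() if aggregated else default_var_meta()
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(
        path, sep=delimiter, na_values=MISSING_TOKENS, keep_default_na=False, dtype=str
    )
    if df.shape[0] == 0:
        raise ValueError("no samples")
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise SchemaError(f"missing metadata column(s): {missing_meta}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SchemaError(f"duplicate sample_id(s): {dups}")
    value_cols = [c for c in df.columns if c not in META_COLUMNS]
    unknown = [c for c in value_cols if c not in var_meta.index]
    if unknown:
        raise SchemaError(f"columns not in schema: {unknown}")
    sample_meta = df[META_COLUMNS].set_index("sample_id")
    values = df[value_cols].copy()
    n_tokens = values.notna().sum().sum()
    values = values.apply(pd.to_numeric, errors="coerce")
    n_coerced = n_tokens - values.notna().sum().sum()
    if n_coerced:
        logger.warning("%d unparseable numeric cell(s) set to missing in %s", n_coerced, path)
    values.index = sample_meta.index
    return MetaboliteTable(values, sample_meta, var_meta.loc[value_cols], aggregated=aggregated)


def write_metabolite_table(table: MetaboliteTable, path: str | Path, *, delimiter: str | None = None) -> None:
    """Write a table in the format :func:`read_metabolite_table` accepts."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    out = pd.concat([table.sample_meta, table.values], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep=delimiter, na_rep="NA")


def aggregate_to_aglycones(table: MetaboliteTable, *, missing_as_zero: bool = False) -> MetaboliteTable:
    """Sum conjugates of the same parent aglycone into the 4-variable table.

    3'OH-PVL (2 terms), 4'OH-PVL (1), 3'4'diOH-PVL (6) and HPP (2).  A
    missing addend makes the sum missing unless ``missing_as_zero`` is set
    (silent zero imputation would bias downstream cluster means, so the
    switch is off by default).
    """
    if table.aggregated:
        raise SchemaError("table is already aggregated")
    unknown = [c for c in table.values.columns if c not in default_var_meta().index]
    if unknown:
        raise SchemaError(f"unknown column(s): {unknown}")
    sums = {}
    for group in AGLYCONE_GROUPS:
        cols = table.columns_of_group(group)
        if not cols:
            raise SchemaError(f"no columns for aglycone group {group}")
        block = table.values[cols]
        sums[group] = block.sum(axis=1, skipna=missing_as_zero)
    values = pd.DataFrame(sums, index=table.values.index)
    return MetaboliteTable(values, table.sample_meta, aggregated_var_meta(), aggregated=True)


@dataclass
class RatioReport:
    """Per-sample sulfate/glucuronide ratios and dominance phenotype.

    ``ratios`` holds one row per sample with the overall ratio and one ratio
    per aglycone group (NaN where the glucuronide sum is zero or fully
    missing).  ``sulfate_dominant`` flags overall ratio > 1.1.
    ``correlations`` holds the Pearson r between the overall ratio and each
    per-group ratio over samples where both are defined.
    """

    ratios: pd.DataFrame
    sulfate_dominant: pd.Series
    correlations: pd.Series
    n_undefined: int = 0
    sulfate_columns: list[str] = field(default_factory=list)
    glucuronide_columns: list[str] = field(default_factory=list)


def _safe_ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    out = num / den
    out[(den == 0) | den.isna() | num.isna()] = np.nan
    return out


def sulfate_glucuronide_ratios(
    table: MetaboliteTable, *, include_methoxy_sulfate: bool = True
) -> RatioReport:
    """Sulfate over glucuronide excretion ratio, overall and per aglycone.

    The sulfo-glucuronide diconjugate and the free aglycone belong to
    neither class and are excluded.  ``include_methoxy_sulfate`` keeps the
    methoxy-sulfate on the sulfate side (default); switching it off covers
    the stricter reading where only plain sulfates are summed.
    """
    if table.aggregated:
        raise SchemaError("ratios require the 11-variable schema")
    sulf_cols = table.columns_of_class("sulfate")
    if include_methoxy_sulfate:
        sulf_cols = sulf_cols + table.columns_of_class("methoxy-sulfate")
    gluc_cols = table.columns_of_class("glucuronide")
    v = table.values
    ratios = pd.DataFrame(index=v.index)
    ratios["overall"] = _safe_ratio(v[sulf_cols].sum(axis=1, skipna=False),
                                    v[gluc_cols].sum(axis=1, skipna=False))
    for group in AGLYCONE_GROUPS:
        gs = [c for c in sulf_cols if c in table.columns_of_group(group)]
        gg = [c for c in gluc_cols if c in table.columns_of_group(group)]
        if not gs or not gg:
            ratios[group] = np.nan
            continue
        ratios[group] = _safe_ratio(v[gs].sum(axis=1, skipna=False),
                                    v[gg].sum(axis=1, skipna=False))
    dominant = ratios["overall"] > SULFATE_DOMINANCE_THRESHOLD
    dominant[ratios["overall"].isna()] = False
    corr = {}
    for group in AGLYCONE_GROUPS:
        pair = ratios[["overall", group]].dropna()
        corr[group] = (
            pair["overall"].corr(pair[group]) if len(pair) >= 3 else np.nan
        )
    n_undef = int(ratios.isna().sum().sum())
    if n_undef:
        logger.info("%d undefined ratio cell(s) excluded pairwise", n_undef)
    return RatioReport(
        ratios=ratios,
        sulfate_dominant=dominant,
        correlations=pd.Series(corr),
        n_undefined=n_undef,
        sulfate_columns=sulf_cols,
        glucuronide_columns=gluc_cols,
    )
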