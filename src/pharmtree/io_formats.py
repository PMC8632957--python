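"""Tabular and JSON serialisation for drug screens and derived artefacts.

All on-disk tables are plain text (TSV/CSV) with a header row; subtype trees
are nested JSON records with explicit child pointers.  IDs are case-sensitive
strings.  Objects are canonicalised on construction (lexicographically sorted
IDs), so row order on disk never matters.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("pharmtree")

#: histology label marking cell lines excluded from every analysis
UNCLASSIFIED = "UNCLASSIFIED"
#: placeholder used when no histology annotation is supplied
MISSING_HISTOLOGY = "NA"


class FormatError(ValueError):
    """An input file could not be parsed into the expected shape."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


# Accepted (lower-cased) header spellings for the long-format response table.
_RESPONSE_ALIASES: Mapping[str, tuple[str, ...]] = {
    "cell": ("cell", "cell_line", "cell_line_name", "cell_id", "cosmic_id"),
    "drug": ("drug", "drug_id", "drug_name"),
    "ln_ic50": ("ln_ic50", "lnic50", "log_ic50"),
    "max_conc": ("max_conc", "max_concentration", "max_conc_um", "maxc"),
    "histology": ("histology", "tcga_desc", "tcga_label", "tissue", "cancer_type"),
}


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is not None:
        raise FormatError(f"unknown dialect {dialect!r} (expected 'csv' or 'tsv')")
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


@dataclass
class ResponseMatrix:
    """Cell x drug natural-log IC50 values with per-drug assay ceilings.

    Parameters
    ----------
    ln_ic50
        DataFrame indexed by cell ID with one column per drug; entries are
        natural-log IC50 in ln(uM).  Missing entries (cell not assayed for a
        drug) are NaN.
    max_conc
        Per-drug maximum screened concentration in uM (strictly positive).
    histology
        Per-cell histology label (TCGA-style code).
    n_excluded
        Number of UNCLASSIFIED cells removed while reading, for reporting.
    """

    ln_ic50: pd.DataFrame
    max_conc: pd.Series
    histology: pd.Series
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.ln_ic50.index.has_duplicates:
            raise ValidationError("duplicate cell IDs in response matrix")
        if self.ln_ic50.columns.has_duplicates:
            raise ValidationError("duplicate drug IDs in response matrix")
        if self.ln_ic50.size == 0:
            raise ValidationError("response matrix has no cells or no drugs")
        self.ln_ic50 = (
            self.ln_ic50.sort_index()
            .sort_index(axis=1)
            .astype(float)
            .rename_axis(index="cell", columns="drug")
        )
        self.max_conc = self.max_conc.reindex(self.ln_ic50.columns).astype(float)
        self.histology = (
            self.histology.reindex(self.ln_ic50.index)
            .fillna(MISSING_HISTOLOGY)
            .astype(str)
        )
        if self.max_conc.isna().any():
            missing = list(self.max_conc.index[self.max_conc.isna()])
            raise ValidationError(f"missing max_conc for drugs {missing}")
        bad = self.max_conc.index[self.max_conc <= 0]
        if len(bad):
            raise ValidationError(f"non-positive max_conc for drug {bad[0]!r}")
        vals = self.ln_ic50.to_numpy()
        if np.isinf(vals).any():
            raise ValidationError("non-finite ln_ic50 entry in response matrix")

    @property
    def cells(self) -> list[str]:
        return list(self.ln_ic50.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.ln_ic50.columns)

    def drug_response(self, drug: str) -> pd.Series:
        """Non-missing ln-IC50 values for one drug, indexed by cell ID."""
        if drug not in self.ln_ic50.columns:
            raise ValidationError(f"unknown drug {drug!r}")
        return self.ln_ic50[drug].dropna()


@dataclass
class AlterationMatrix:
    """Binary gene/fusion x cell mutation-or-translocation status."""

    status: pd.DataFrame  # genes x cells, entries in {0, 1}

    def __post_init__(self) -> None:
        if self.status.index.has_duplicates:
            raise ValidationError("duplicated gene row ID in alteration matrix")
        if self.status.columns.has_duplicates:
            raise ValidationError("duplicated cell column ID in alteration matrix")
        vals = self.status.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            g, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary entry {vals[g, c]!r} at gene "
                f"{self.status.index[g]!r}, cell {self.status.columns[c]!r}"
            )
        self.status = self.status.sort_index().sort_index(axis=1).astype(np.int8)

    @property
    def genes(self) -> list[str]:
        return list(self.status.index)

    @property
    def cells(self) -> list[str]:
        return list(self.status.columns)


@dataclass
class ExpressionMatrix:
    """Continuous gene x cell expression values."""

    expr: pd.DataFrame  # genes x cells

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            raise ValidationError("duplicated gene row ID in expression matrix")
        if self.expr.columns.has_duplicates:
            raise ValidationError("duplicated cell column ID in expression matrix")
        self.expr = self.expr.sort_index().sort_index(axis=1).astype(float)
        if not np.isfinite(self.expr.to_numpy()).all():
            raise ValidationError("non-finite entry in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    @property
    def cells(self) -> list[str]:
        return list(self.expr.columns)


# ---------------------------------------------------------------------------
# response table
# ---------------------------------------------------------------------------

def _resolve_columns(columns: Iterable[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    found: dict[str, str] = {}
    for role, aliases in _RESPONSE_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                found[role] = lower[alias]
                break
    return found


def read_response_table(path: str | Path, dialect: str | None = None) -> ResponseMatrix:
    """Read a long-format (cell, drug, ln_ic50, max_conc[, histology]) table.

    Cells labelled UNCLASSIFIED are removed; the number removed is reported
    on the returned object and logged.
    """
    sep = _sep_for(Path(path), dialect)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty response table: {path}") from exc
    if df.empty:
        raise ValidationError(f"empty response table: {path}")

    cols = _resolve_columns(df.columns)
    required = ("cell", "drug", "ln_ic50", "max_conc")
    missing = [r for r in required if r not in cols]
    if missing:
        raise FormatError(f"response table {path} lacks required columns: {missing}")

    df = df.rename(columns={v: k for k, v in cols.items()})
    if "histology" not in df.columns:
        df["histology"] = MISSING_HISTOLOGY
    df["histology"] = df["histology"].fillna(MISSING_HISTOLOGY).astype(str)
    df["cell"] = df["cell"].astype(str)
    df["drug"] = df["drug"].astype(str)
    for col in ("ln_ic50", "max_conc"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric value in column {col!r} of {path}") from exc

    excluded = set(df.loc[df["histology"] == UNCLASSIFIED, "cell"])
    if excluded:
        log.info("excluding %d UNCLASSIFIED cell line(s)", len(excluded))
        df = df[~df["cell"].isin(excluded)]
    if df.empty:
        raise ValidationError(f"response table {path} has no classified cells")

    if df.duplicated(["cell", "drug"]).any():
        dup = df.loc[df.duplicated(["cell", "drug"]), ["cell", "drug"]].iloc[0]
        raise FormatError(f"duplicate response row for cell {dup['cell']!r}, drug {dup['drug']!r}")

    per_drug = df.groupby("drug")["max_conc"].nunique()
    if (per_drug > 1).any():
        raise ValidationError(
            f"conflicting max_conc values for drug {per_drug.index[per_drug > 1][0]!r}"
        )
    per_cell = df.groupby("cell")["histology"].nunique()
    if (per_cell > 1).any():
        raise ValidationError(
            f"conflicting histology labels for cell {per_cell.index[per_cell > 1][0]!r}"
        )

    ln = df.pivot(index="cell", columns="drug", values="ln_ic50")
    max_conc = df.groupby("drug")["max_conc"].first()
    histology = df.groupby("cell")["histology"].first()
    return ResponseMatrix(ln_ic50=ln, max_conc=max_conc, histology=histology,
                          n_excluded=len(excluded))


def write_response_table(responses: ResponseMatrix, path: str | Path) -> None:
    """Write the long-format response table (missing entries omitted)."""
    long = (
        responses.ln_ic50.stack()
        .rename("ln_ic50")
        .rename_axis(["cell", "drug"])
        .reset_index()
    )
    long["max_conc"] = long["drug"].map(responses.max_conc)
    long["histology"] = long["cell"].map(responses.histology)
    sep = _sep_for(Path(path), None)
    long.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# gene x cell matrices
# ---------------------------------------------------------------------------

def _read_gene_by_cell(path: str | Path, dialect: str | None) -> pd.DataFrame:
    sep = _sep_for(Path(path), dialect)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty matrix file: {path}") from exc
    if df.empty:
        raise ValidationError(f"empty matrix file: {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_alteration_matrix(path: str | Path, dialect: str | None = None) -> AlterationMatrix:
    """Read a gene-rows x cell-columns 0/1 table."""
    df = _read_gene_by_cell(path, dialect)
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric entry in alteration matrix {path}") from exc
    return AlterationMatrix(status=df)


def write_alteration_matrix(alterations: AlterationMatrix, path: str | Path) -> None:
    alterations.status.rename_axis("gene").to_csv(path, sep=_sep_for(Path(path), None))


def read_expression_matrix(path: str | Path, dialect: str | None = None) -> ExpressionMatrix:
    """Read a gene-rows x cell-columns real-valued table."""
    df = _read_gene_by_cell(path, dialect)
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric entry in expression matrix {path}") from exc
    return ExpressionMatrix(expr=df)


def write_expression_matrix(expression: ExpressionMatrix, path: str | Path) -> None:
    expression.expr.rename_axis("gene").to_csv(path, sep=_sep_for(Path(path), None))


# ---------------------------------------------------------------------------
# subtype trees (JSON)
# ---------------------------------------------------------------------------

def _node_to_dict(node) -> dict:
    out: dict = {"cells": list(node.cells), "n": node.n}
    if node.is_leaf:
        out["response_class"] = node.response_class
    else:
        out["split_p"] = node.split_p
        out["left"] = _node_to_dict(node.left)
        out["right"] = _node_to_dict(node.right)
    return out


def _node_from_dict(d: dict):
    from .subtype_tree import TreeNode  # local import avoids a cycle

    if not isinstance(d, dict) or "cells" not in d:
        raise FormatError("malformed tree node record")
    cells = tuple(str(c) for c in d["cells"])
    if "left" in d or "right" in d:
        if "left" not in d or "right" not in d or "split_p" not in d:
            raise FormatError("internal tree node lacks children or split_p")
        return TreeNode(
            cells=cells,
            split_p=float(d["split_p"]),
            left=_node_from_dict(d["left"]),
            right=_node_from_dict(d["right"]),
        )
    return TreeNode(cells=cells, response_class=d.get("response_class"))


def write_tree(tree, path: str | Path) -> None:
    """Serialise a subtype tree as nested JSON (deterministic byte layout)."""
    payload = {"drug": tree.drug, "root": _node_to_dict(tree.root)}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_tree(path: str | Path):
    from .subtype_tree import SubtypeTree

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed tree file {path}: {exc}") from exc
    try:
        return SubtypeTree(drug=str(payload["drug"]), root=_node_from_dict(payload["root"]))
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed tree file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# similarity matrices and connection tables
# ---------------------------------------------------------------------------

def write_square_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    df.rename_axis(index_name).to_csv(path, sep=_sep_for(Path(path), None))


def read_square_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(Path(path), None), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


_CONNECTION_COLUMNS = ["gene", "drug", "modality", "p", "q_fdr", "direction", "pcc"]


def write_connections(records, path: str | Path) -> None:
    """Write connection records as a long-format TSV/CSV table."""
    rows = [
        {
            "gene": r.gene,
            "drug": r.drug,
            "modality": r.modality,
            "p": r.p,
            "q_fdr": r.q_fdr,
            "direction": r.direction,
            "pcc": "" if r.pcc is None else r.pcc,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_CONNECTION_COLUMNS)
    df.to_csv(path, sep=_sep_for(Path(path), None), index=False)


def read_connections(path: str | Path):
    from .connections import ConnectionRecord

    df = pd.read_csv(path, sep=_sep_for(Path(path), None))
    missing = [c for c in _CONNECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"connection table {path} lacks columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        pcc = None if pd.isna(row.pcc) else float(row.pcc)
        records.append(
            ConnectionRecord(
                gene=str(row.gene),
                drug=str(row.drug),
                modality=str(row.modality),
                p=float(row.p),
                q_fdr=float(row.q_fdr),
                direction=str(row.direction),
                pcc=pcc,
            )
        )
    return records
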