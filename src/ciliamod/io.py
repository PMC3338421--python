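"""Readers and writers for the plain-text formats the pipeline consumes.

Expression TSV: first column gene id, header row = sample ids, tab-separated.
GMT: one gene set per line — name, description, then gene ids.
Evidence TSV: gene, n_high, n_medium, n_low.
Atlas sample sheet TSV: sample_id, tissue.
All writers emit LF line endings with a fixed column order.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import DataError, ExpressionDataset, TissueAtlas


def read_expression_tsv(path, tissue: str = "", dataset_id: str | None = None) -> ExpressionDataset:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        rows, index = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise DataError(
                    f"{path.name}: line {lineno} has {len(fields)} fields, expected {n_cols}"
                )
            index.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise DataError(f"{path.name}: line {lineno}: {exc}") from exc
    expr = pd.DataFrame(rows, index=pd.Index(index, name=header[0]), columns=header[1:])
    return ExpressionDataset(expr, tissue=tissue, dataset_id=dataset_id or path.stem)


def write_expression_tsv(dataset: ExpressionDataset | pd.DataFrame, path) -> None:
    expr = dataset.expr if isinstance(dataset, ExpressionDataset) else dataset
    expr = expr.copy()
    expr.index.name = expr.index.name or "gene"
    expr.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"GMT line {lineno}: expected name, description, >=1 gene")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w", newline="\n") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_evidence_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    required = ["n_high", "n_medium", "n_low"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise DataError(f"evidence table missing columns: {missing}")
    if (table[required] < 0).to_numpy().any():
        raise DataError("evidence table contains negative counts")
    return table[required].astype(int)


def write_evidence_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = out.index.name or "gene"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_atlas(expr_path, sample_sheet_path, ciliated_tissues, excluded_tissues=()) -> TissueAtlas:
    ds = read_expression_tsv(expr_path, dataset_id="atlas")
    sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    if "tissue" not in sheet.columns:
        raise DataError("atlas sample sheet must have a 'tissue' column")
    return TissueAtlas(
        ds.expr,
        sheet["tissue"],
        list(ciliated_tissues),
        list(excluded_tissues),
    )


def write_atlas(atlas: TissueAtlas, expr_path, sample_sheet_path) -> None:
    write_expression_tsv(atlas.expr, expr_path)
    sheet = atlas.sample_tissues.rename("tissue").to_frame()
    sheet.index.name = "sample_id"
    sheet.to_csv(sample_sheet_path, sep="\t", lineterminator="\n")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset, pd.Index, np.ndarray)):
            return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")
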