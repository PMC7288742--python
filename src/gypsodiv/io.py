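"""Readers and writers for the four input artifacts and the result tables.

All tabular files are comma-separated UTF-8 with a mandatory header row and
the key (plot or species id) in the first column; decimals use a point. Blank
cells in the community matrix mean absence and are read as zero. Trees are
standard Newick with branch lengths.
"""

from __future__ import annotations

import csv
import os
from pathlib import Path

import dendropy
import pandas as pd
import yaml

from .datasets import (
    CommunityMatrix,
    DataFormatError,
    EnvironmentTable,
    Phylogeny,
    TraitTable,
)


def _read_keyed_csv(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise DataFormatError(f"{what} file {path} has no data columns")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    return df


def _check_header_duplicates(path: str | Path, what: str) -> None:
    # pandas silently mangles duplicate column names, so check the raw header
    with open(path, "r", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    cols = header[1:]
    dupes = sorted({c for c in cols if cols.count(c) > 1})
    if dupes:
        raise DataFormatError(f"duplicate {what}: {dupes}")


def read_community_matrix(path: str | Path) -> CommunityMatrix:
    """Read a plot×species abundance CSV (first column: plot id)."""
    _check_header_duplicates(path, "species ids")
    df = _read_keyed_csv(path, "community matrix")
    df.columns = df.columns.astype(str)
    df = df.fillna(0.0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise DataFormatError(f"non-numeric abundance in {path}: {exc}") from exc
    return CommunityMatrix(df)


def write_community_matrix(cm: CommunityMatrix, path: str | Path) -> None:
    cm.abundance.rename_axis("plot_id").to_csv(path)


def read_trait_table(path: str | Path) -> TraitTable:
    """Read a two-column species→GI CSV."""
    df = _read_keyed_csv(path, "trait table")
    if df.shape[1] != 1:
        raise DataFormatError(
            f"trait table must have exactly two columns (species_id, GI); "
            f"found {df.shape[1] + 1}"
        )
    return TraitTable(df.iloc[:, 0])


def write_trait_table(tt: TraitTable, path: str | Path) -> None:
    tt.gi.rename_axis("species_id").to_csv(path)


def read_environment_table(path: str | Path) -> EnvironmentTable:
    """Read the per-plot Tmax/MAP/cover CSV (first column: plot id)."""
    return EnvironmentTable(_read_keyed_csv(path, "environment table"))


def write_environment_table(env: EnvironmentTable, path: str | Path) -> None:
    env.table.rename_axis("plot_id").to_csv(path)


def read_newick(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", rooting="force-rooted"
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise DataFormatError(f"cannot parse Newick file {path}: {exc}") from exc
    return Phylogeny(tree)


def write_newick(ph: Phylogeny, path: str | Path) -> None:
    ph.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    """Write the per-plot metrics table (one row per plot)."""
    metrics.rename_axis("plot_id").to_csv(path)


def write_model_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write the per-response×term analysis-of-deviance report."""
    report.to_csv(path, index=False)


def read_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def atomic_write(df_writer, path: str | Path) -> None:
    """Write via a temporary file then rename, so failures leave no partial file."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    df_writer(tmp)
    os.replace(tmp, path)
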