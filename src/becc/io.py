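"""File formats: expression matrices, probe annotation, result tables.

Supported inputs are tab-delimited matrices (probes in rows, a header
row of sample ids), the table block of a GEO series-matrix file, and
GPL-style tab-delimited annotation tables mapping probe ids to gene
symbols (multi-symbol cells delimited by " /// ").  Results are written
as a tab-delimited report with a commented header.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ProbeAnnotation

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_annotation",
    "write_results",
    "read_results",
]

logger = logging.getLogger("becc")

SYMBOL_DELIMITER = " /// "


class MatrixParseError(ValueError):
    pass


def _frame_to_matrix(df: pd.DataFrame, platform_tag: str) -> ExpressionMatrix:
    ids = [str(i) for i in df.index]
    dup = sorted({i for i in ids if ids.count(i) > 1}) if len(set(ids)) != len(ids) else []
    if dup:
        raise MatrixParseError(f"duplicate probe ids: {dup}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    vals = numeric.to_numpy(dtype=float)
    mask = ~np.isfinite(vals)
    return ExpressionMatrix(
        probe_ids=ids,
        sample_ids=[str(c) for c in df.columns],
        values=np.where(mask, 0.0, vals),
        mask=mask,
        platform_tag=platform_tag,
    )


def _read_tsv(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip() or "\t" not in header:
        raise MatrixParseError(
            f"{path}:1: malformed header (expected tab-delimited sample ids)"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise MatrixParseError(f"{path}: no sample columns found")
    return _frame_to_matrix(df, platform_tag="")


def _read_series_matrix(path: Path) -> ExpressionMatrix:
    """Parse the !series_matrix_table_begin/end block of a GEO file."""
    lines: list[str] = []
    in_table = False
    platform = ""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("!Series_platform_id") or \
               line.startswith("!Sample_platform_id"):
                parts = line.split("\t")
                if len(parts) > 1:
                    platform = parts[1].strip().strip('"')
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                table_start = lineno
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                lines.append(line)
    if not lines:
        raise MatrixParseError(
            f"{path}: no !series_matrix_table_begin/end block found"
        )
    header = [c.strip('"') for c in lines[0].split("\t")]
    if len(header) < 2:
        raise MatrixParseError(
            f"{path}:{table_start + 1}: malformed table header: {lines[0]!r}"
        )
    records = []
    index = []
    for off, line in enumerate(lines[1:], start=2):
        cells = [c.strip('"') for c in line.split("\t")]
        if len(cells) != len(header):
            raise MatrixParseError(
                f"{path}:{table_start + off}: row has {len(cells)} cells, "
                f"expected {len(header)}"
            )
        index.append(cells[0])
        records.append(cells[1:])
    df = pd.DataFrame(records, index=index, columns=header[1:])
    return _frame_to_matrix(df, platform_tag=platform)


def read_matrix(path, format: str = "tsv") -> ExpressionMatrix:
    """Read an expression matrix from disk.

    ``format`` is ``"tsv"`` (plain tab-delimited, header = sample ids)
    or ``"series_matrix"`` (GEO series-matrix text; only the table block
    is consumed).  Non-numeric cells (e.g. ``null``) become masked
    missing values; duplicate probe rows raise with the offending ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "series_matrix":
        return _read_series_matrix(path)
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'series_matrix'")


def write_matrix(matrix: ExpressionMatrix, path, na_rep: str = "NA") -> None:
    """Write a matrix as tab-delimited text; masked entries as ``na_rep``."""
    df = matrix.to_dataframe()
    df.index.name = "ID"
    df.to_csv(path, sep="\t", na_rep=na_rep, float_format="%.6g")


def read_annotation(
    path,
    probe_column: str = "ID",
    symbol_column: str = "Gene Symbol",
) -> ProbeAnnotation:
    """Read a GPL-style probe-to-gene-symbol table.

    Multi-symbol cells are split on ``" /// "``; empty cells yield
    unannotated probes (empty symbol lists).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in (probe_column, symbol_column) if c not in df.columns]
    if missing:
        raise ValueError(
            f"annotation table lacks column(s) {missing}; "
            f"expected {probe_column!r} and {symbol_column!r}, "
            f"found {list(df.columns)}"
        )
    mapping: dict[str, list[str]] = {}
    for probe, cell in zip(df[probe_column], df[symbol_column]):
        probe = str(probe)
        if isinstance(cell, str) and cell.strip():
            symbols = [s.strip() for s in cell.split("///")]
            symbols = [s for s in symbols if s]
        else:
            symbols = []
        mapping[probe] = symbols
    return ProbeAnnotation(mapping)


def write_results(result, path, annotation: ProbeAnnotation | None = None) -> None:
    """Write a run's ranked candidate table.

    One row per candidate probeset, sorted by gs descending (ties broken
    lexicographically by probe id) with columns probe_id, gene_symbols,
    gs, rank, selected and dynamic_range.  The gs threshold and the
    Z-test statistics go into ``#``-commented header lines.
    """
    lines = []
    if result.gs_threshold is not None:
        lines.append(f"# gs_threshold\t{result.gs_threshold:.10g}")
    if result.null is not None:
        lines.append(f"# z_statistic\t{result.null.z:.10g}")
        lines.append(f"# z_p_value\t{result.null.p_value:.10g}")
        lines.append(f"# null_mean_score\t{result.null.mean_score:.10g}")
        lines.append(f"# null_pairs\t{result.null.n_pairs}")
    lines.append(f"# status\t{result.status}")
    lines.append("probe_id\tgene_symbols\tgs\trank\tselected\tdynamic_range")

    if not result.candidates:
        logger.warning("empty result: writing header-only results table")
    else:
        selected = set(result.selected)
        rows = sorted(
            zip(result.candidates, result.gs),
            key=lambda t: (-t[1], t[0]),
        )
        for rank, (probe, gs) in enumerate(rows, start=1):
            symbols = SYMBOL_DELIMITER.join(
                annotation.symbols_for(probe)) if annotation else ""
            dyn = result.dynamic_range.get(probe, float("nan"))
            lines.append(
                f"{probe}\t{symbols}\t{gs:.10g}\t{rank}\t"
                f"{int(probe in selected)}\t{dyn:.6g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`.

    Returns the data rows as a DataFrame; the commented header values
    are attached under ``df.attrs``.
    """
    attrs: dict[str, float | str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("\t")
            try:
                attrs[key] = float(value)
            except ValueError:
                attrs[key] = value
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"probe_id": str, "gene_symbols": str})
    if "gene_symbols" in df.columns:
        df["gene_symbols"] = df["gene_symbols"].fillna("")
    df.attrs.update(attrs)
    return df
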