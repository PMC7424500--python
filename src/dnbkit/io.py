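"""Readers and writers for the pipeline's plain-text dialects.

* Expression TSV — header row of sample ids, first column gene id.
* Metadata TSV — columns sample_id, group, week.
* Gene-set file — one symbol per line; blanks and whitespace tolerated.
* Annotation TSV — columns probe_id, gene_symbol (empty = unannotated).
* GEO series-matrix text — best-effort convenience reader for locally
  downloaded files (no network access anywhere in the package).
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, GeneSet, SampleMetadata, SCALE_LOG2, SCALE_RAW
from .preprocess import ProbeAnnotation

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "read_geneset",
    "write_geneset",
    "read_annotation",
    "write_annotation",
    "read_geo_series_matrix",
]


def read_expression(path: str | os.PathLike, scale: str = SCALE_LOG2) -> ExpressionMatrix:
    """Read an expression TSV (genes in rows, samples in columns)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse expression file {path}: {exc}") from exc
    if frame.empty:
        raise ValueError(f"expression file {path} holds no data rows")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene row(s) in {path}: {dup[:10]}")
    non_numeric = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric column(s) in {path}: {non_numeric[:5]}")
    frame.index = frame.index.astype(str)
    frame.index.name = "gene"
    frame.columns = frame.columns.astype(str)
    return ExpressionMatrix(frame, scale=scale)


def write_expression(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    matrix.data.rename_axis("gene").to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path: str | os.PathLike) -> SampleMetadata:
    try:
        table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    except Exception as exc:
        raise ValueError(f"cannot parse metadata file {path}: {exc}") from exc
    return SampleMetadata(table)


def write_metadata(metadata: SampleMetadata, path: str | os.PathLike) -> None:
    metadata.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_geneset(path: str | os.PathLike, name: str | None = None) -> GeneSet:
    """One symbol per line; blank lines and surrounding whitespace ignored."""
    with open(path) as handle:
        genes = [line.strip() for line in handle]
    if name is None:
        name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return GeneSet([g for g in genes if g], name=name)


def write_geneset(gene_set: GeneSet, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for gene in gene_set:
            handle.write(gene + "\n")


def read_annotation(path: str | os.PathLike) -> ProbeAnnotation:
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ValueError(f"cannot parse annotation file {path}: {exc}") from exc
    for col in ("probe_id", "gene_symbol"):
        if col not in table.columns:
            raise ValueError(f"annotation file {path} lacks column {col!r}")
    return ProbeAnnotation(list(zip(table["probe_id"], table["gene_symbol"])))


def write_annotation(annotation: ProbeAnnotation, path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("probe_id\tgene_symbol\n")
        for probe, symbol in annotation.items():
            handle.write(f"{probe}\t{symbol}\n")


_CHARACTERISTIC = re.compile(r"^(?P<key>[^:]+):\s*(?P<value>.*)$")


def read_geo_series_matrix(
    path: str | os.PathLike, scale: str = SCALE_RAW
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Parse a locally stored GEO series-matrix text file.

    Returns the expression matrix plus a per-sample annotation frame built
    from the ``!Sample_*`` header lines (title, characteristics, etc.).
    Group/week assignment is left to the caller: characteristic layouts
    vary across series, so metadata extraction is best-effort only.
    """
    header_rows: dict[str, list[list[str]]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key = line.split("\t", 1)[0][len("!Sample_"):]
                values = [v.strip('"') for v in line.split("\t")[1:]]
                header_rows.setdefault(key, []).append(values)
    if not table_lines:
        raise ValueError(f"{path} is not a series-matrix file (no table block)")

    from io import StringIO

    frame = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    frame.index = frame.index.astype(str).str.strip('"')
    frame.index.name = "gene"
    frame.columns = frame.columns.astype(str).str.strip('"')
    matrix = ExpressionMatrix(frame, scale=scale)

    ann: dict[str, list[str]] = {}
    for key, rows in header_rows.items():
        if key.startswith("characteristics"):
            for i, values in enumerate(rows):
                parsed_keys = set()
                for value in values:
                    m = _CHARACTERISTIC.match(value)
                    if m:
                        parsed_keys.add(m.group("key").strip())
                if len(parsed_keys) == 1:
                    ann[parsed_keys.pop()] = [
                        _CHARACTERISTIC.match(v).group("value") if _CHARACTERISTIC.match(v) else v
                        for v in values
                    ]
                else:
                    ann[f"{key}_{i}"] = values
        else:
            ann[key] = rows[0]
    n = matrix.n_samples
    ann = {k: v for k, v in ann.items() if len(v) == n}
    annotations = pd.DataFrame(ann, index=matrix.samples)
    return matrix, annotations
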