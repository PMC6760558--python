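"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices, annotation, gene models and survival tables travel as
TSV; binding sites as 3+-column BED (0-based half-open, extra columns
ignored); gene-set collections as GMT.  All I/O is deterministic given the
file, and round-trip read(write(x)) preserves ids exactly and values to
better than 1e-12.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BINDING_SITE_COLUMNS,
    ExpressionMatrix,
    GeneSetCollection,
    validate_annotation,
    validate_binding_sites,
    validate_gene_models,
    validate_survival,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def read_expression(path, platform: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[~df[col].map(lambda v: _is_number(v))]
            raise ValueError(
                f"non-numeric expression value in {path} at gene "
                f"{bad[0] if len(bad) else '?'!r}, sample {col!r}"
            )
    return ExpressionMatrix(df.astype(float), platform)


def _is_number(v) -> bool:
    try:
        float(v)
        return np.isfinite(float(v))
    except (TypeError, ValueError):
        return False


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.12g")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotation(df)


def write_annotation(df: pd.DataFrame, path) -> None:
    validate_annotation(df).to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "tss": int, "strand": str})
    return validate_gene_models(df)


def write_gene_models(df: pd.DataFrame, path) -> None:
    validate_gene_models(df).to_csv(path, sep="\t", index=False)


def read_bed(path, source: str | None = None) -> pd.DataFrame:
    """Read a 3+-column BED file into a binding-site table.

    Coordinates are kept exactly as written (integer, 0-based half-open);
    columns beyond the first three are ignored.  ``source`` labels the
    dataset the sites came from (defaults to the file stem).
    """
    records = []
    source = source if source is not None else Path(path).stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            records.append((chrom, start, end, source))
    df = pd.DataFrame(records, columns=BINDING_SITE_COLUMNS)
    return validate_binding_sites(df)


def read_bed_multi(paths, sources=None) -> pd.DataFrame:
    """Read and concatenate several BED files, labelling each by source."""
    if sources is None:
        sources = [None] * len(paths)
    parts = [read_bed(p, source=s) for p, s in zip(paths, sources)]
    return pd.concat(parts, ignore_index=True)


def write_bed(df: pd.DataFrame, path) -> None:
    validate_binding_sites(df)
    df.loc[:, ["chrom", "start", "end", "source"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gmt(path, name: str | None = None) -> GeneSetCollection:
    """Read a GMT gene-set collection (set name, description, members...).

    The description column is discarded.  Duplicate members within a set are
    deduplicated with a logged warning.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT line has <3 fields")
            set_name, members = fields[0], fields[2:]
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "%s: line %d: set %r has %d duplicate member(s), deduplicated",
                    path, lineno, set_name, len(members) - len(unique),
                )
            sets[set_name] = unique
    return GeneSetCollection(name=name or Path(path).stem, sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_name, members in collection.sets.items():
            fh.write("\t".join([set_name, "na", *members]) + "\n")


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    df["time_months"] = df["time_months"].astype(float)
    df["event"] = df["event"].astype(int).astype(bool)
    return validate_survival(df)


def write_survival(df: pd.DataFrame, path) -> None:
    out = validate_survival(df).copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index=False)
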