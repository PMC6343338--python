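"""Readers/writers for PAC tables, sample sheets, matrices and cluster files.

All files are tab-delimited UTF-8 with a header row; lines starting with
``#`` are ignored.  Genomic coordinates, when present, are 1-based.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    DesignMismatchError,
    ExperimentDesign,
    PacDataset,
    SiteRecord,
    ValidationError,
)

__all__ = [
    "read_sample_sheet",
    "read_pac_table",
    "write_pac_table",
    "read_matrix",
    "write_matrix",
    "read_clusters",
    "write_clusters",
    "read_annotation",
    "read_gene_list",
]

#: columns of the PAC table that are metadata, not sample counts
_META_COLS = ("site", "gene", "chrom", "strand", "position")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_sample_sheet(path) -> ExperimentDesign:
    """Parse a sample sheet (columns: sample, experiment, replicate)."""
    df = _read_tsv(path)
    required = {"sample", "experiment", "replicate"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"sample sheet must have columns {sorted(required)}, got {list(df.columns)}"
        )
    experiments: list[str] = []
    for e in df["experiment"]:
        if e not in experiments:
            experiments.append(e)
    samples = tuple(
        (row["sample"], row["experiment"], int(row["replicate"]))
        for _, row in df.iterrows()
    )
    return ExperimentDesign(experiments=tuple(experiments), samples=samples)


def read_pac_table(path, sample_sheet_path) -> PacDataset:
    """Read a poly(A)-site count table plus its sample sheet.

    The table's first columns are ``site`` and ``gene`` (optionally
    ``chrom``, ``strand``, ``position``); every remaining column must be a
    sample listed in the sheet, and vice versa.  Returned counts follow the
    sheet's sample order.
    """
    design = read_sample_sheet(sample_sheet_path)
    df = _read_tsv(path)
    for col in ("site", "gene"):
        if col not in df.columns:
            raise ValidationError(f"PAC table is missing required column {col!r}")
    count_cols = [c for c in df.columns if c not in _META_COLS]
    want = set(design.sample_ids)
    have = set(count_cols)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise DesignMismatchError(
            f"count columns do not match the sample sheet (missing {missing}, extra {extra})"
        )
    sites = []
    gene_of: dict[str, str] = {}
    for _, row in df.iterrows():
        sid = row["site"]
        if sid in gene_of and gene_of[sid] != row["gene"]:
            raise ValidationError(f"site {sid!r} mapped to two genes")
        gene_of[sid] = row["gene"]
        sites.append(
            SiteRecord(
                site_id=sid,
                gene_id=row["gene"],
                chrom=row.get("chrom") if "chrom" in df.columns else None,
                strand=row.get("strand") if "strand" in df.columns else None,
                position=int(row["position"]) if "position" in df.columns else None,
            )
        )
    counts = df[list(design.sample_ids)].to_numpy(dtype=float)
    if np.any(counts < 0):
        raise ValidationError("negative counts in PAC table")
    return PacDataset(sites=sites, counts=counts, design=design)


def write_pac_table(data: PacDataset, path) -> None:
    """Write a PAC table readable back by :func:`read_pac_table`."""
    cols: dict[str, object] = {
        "site": [s.site_id for s in data.sites],
        "gene": [s.gene_id for s in data.sites],
    }
    if any(s.chrom is not None for s in data.sites):
        cols["chrom"] = [s.chrom if s.chrom is not None else "." for s in data.sites]
    if any(s.strand is not None for s in data.sites):
        cols["strand"] = [s.strand if s.strand is not None else "." for s in data.sites]
    if any(s.position is not None for s in data.sites):
        cols["position"] = [s.position if s.position is not None else 0 for s in data.sites]
    df = pd.DataFrame(cols)
    for j, sid in enumerate(data.design.sample_ids):
        df[sid] = data.counts[:, j]
    df.to_csv(path, sep="\t", index=False)


def write_sample_sheet(design: ExperimentDesign, path) -> None:
    df = pd.DataFrame(
        [(sid, exp, rep) for sid, exp, rep in design.samples],
        columns=["sample", "experiment", "replicate"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_matrix(labels, matrix, path) -> None:
    """Write a square labelled matrix (row and column labels identical)."""
    matrix = np.asarray(matrix, dtype=float)
    labels = list(labels)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError(f"matrix must be square, got shape {matrix.shape}")
    if matrix.shape[0] != len(labels):
        raise ValidationError("label count does not match matrix size")
    if len(set(labels)) != len(labels):
        raise ValidationError("labels must be unique")
    if not np.allclose(matrix, matrix.T, atol=1e-12, rtol=0):
        raise ValidationError("matrix must be symmetric")
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(sep="\t", path_or_buf=path)


def read_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a square labelled matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValidationError(f"matrix in {path} is not square: {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValidationError("row and column labels differ")
    return list(df.index.astype(str)), df.to_numpy(dtype=float)


def write_clusters(assignment: Mapping[str, int], path) -> None:
    """Write a gene -> cluster table, sorted by gene label."""
    if not assignment:
        raise ValidationError("empty cluster assignment")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tcluster\n")
        for gene in sorted(assignment):
            fh.write(f"{gene}\t{assignment[gene]}\n")


def read_clusters(path) -> dict[str, int]:
    df = _read_tsv(path)
    return {row["gene"]: int(row["cluster"]) for _, row in df.iterrows()}


def read_annotation(path) -> dict[str, set[str]]:
    """Read a gene -> functional-class table (one row per gene-class pair)."""
    df = _read_tsv(path)
    if not {"gene", "class"}.issubset(df.columns):
        raise ValidationError("annotation table needs columns 'gene' and 'class'")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["gene"], set()).add(row["class"])
    return out


def read_gene_list(path) -> set[str]:
    """One gene id per line; '#' comments and blank lines ignored."""
    genes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line.split("\t")[0])
    return genes
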