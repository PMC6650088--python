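"""Readers and writers for the tab-separated formats the tool consumes.

All tables are plain TSV, UTF-8, first row and first column are labels, no
quoting — the layout of Firehose-style exports. Readers preserve file order
of both axes; nothing is sorted or deduplicated silently.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import (
    BinaryEventMatrix,
    FormatError,
    GeneSetCollection,
    MutSigTable,
    NormalReference,
    ScnaCallMatrix,
)

PathLike = Union[str, Path]


def _read_table(path: PathLike) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):  # pandas would silently mangle these
        dup = next(x for x in header if header.count(x) > 1)
        raise FormatError(f"{path}: duplicate column identifier {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: no tumors/genes (empty data section)")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row identifier {dup!r}")
    return df


def read_binary_matrix(path: PathLike, orientation: str = "tumor_by_gene") -> BinaryEventMatrix:
    """Read a 0/1 event matrix.

    ``orientation`` is the layout of the *file*: ``tumor_by_gene`` (rows are
    tumors) or ``gene_by_tumor`` (rows are genes, transposed on read). The
    returned matrix is always tumor×gene.
    """
    if orientation not in ("tumor_by_gene", "gene_by_tumor"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = _read_table(path)
    if orientation == "gene_by_tumor":
        df = df.T
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1)) | pd.isna(df).to_numpy()
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FormatError(
            f"{path}: non-binary cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return BinaryEventMatrix(values.astype(np.uint8), list(df.index), list(df.columns))


def write_binary_matrix(matrix: BinaryEventMatrix, path: PathLike) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="tumor_id")


def read_scna_calls(path: PathLike) -> ScnaCallMatrix:
    """Read gene×tumor GISTIC-style thresholded calls (levels −2..+2)."""
    df = _read_table(path)
    values = df.to_numpy()
    if pd.isna(df).to_numpy().any():
        raise FormatError(f"{path}: missing copy-number cell")
    return ScnaCallMatrix(values, list(df.index), list(df.columns))


def write_scna_calls(matrix: ScnaCallMatrix, path: PathLike) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_expression(path: PathLike) -> pd.DataFrame:
    """Read a gene×tumor log2 expression matrix (floats allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate gene or tumor identifier")
    return df


def read_tumor_map(path: PathLike) -> dict[str, str]:
    """Read the tumor→cancer-type map (first two columns used)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: tumor map needs tumor_id and cancer_type columns")
    tumors = df.iloc[:, 0]
    if tumors.duplicated().any():
        dup = tumors[tumors.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate tumor id {dup!r}")
    return dict(zip(tumors, df.iloc[:, 1]))


def write_tumor_map(tissue: dict[str, str], path: PathLike) -> None:
    pd.DataFrame(
        {"tumor_id": list(tissue), "cancer_type": list(tissue.values())}
    ).to_csv(path, sep="\t", index=False)


def read_mutsig(path: PathLike) -> MutSigTable:
    """Read a MutSigCV output table; only the gene and p columns are used."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene", df.columns[0])
    p_col = cols.get("p", cols.get("p_value", cols.get("pvalue")))
    if p_col is None:
        raise FormatError(f"{path}: no p-value column found")
    genes = df[gene_col].astype(str)
    if genes.duplicated().any():
        raise FormatError(f"{path}: duplicate gene in MutSig table")
    return MutSigTable(dict(zip(genes, df[p_col].astype(float))))


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read MSigDB-style GMT gene sets (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = frozenset(fields[2:])
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


def read_normal_reference(path: PathLike) -> NormalReference:
    """Read per-(gene, tissue) normal log2-expression stats (mean, sd, n)."""
    df = pd.read_csv(path, sep="\t")
    return NormalReference(df)


def write_normal_reference(ref: NormalReference, path: PathLike) -> None:
    ref.table.to_csv(path, sep="\t", index=False)


def write_json(obj, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
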