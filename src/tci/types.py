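"""Core domain containers for tumor genome-event data.

The whole pipeline works on two binary tumor×gene event matrices — somatic
genome alterations (SGAs: mutations and/or copy-number events) and
differentially expressed genes (DEGs) — plus a handful of auxiliary tables
(GISTIC-style copy-number calls, tissue-matched normal expression references,
MutSigCV p-values, GMT gene sets). Containers here validate their invariants
on construction and otherwise stay out of the way: label order is part of the
contract and is never changed silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

A0 = "A0"
"""Name of the non-specific cause: unmeasured genomic or micro-environmental
factors that may explain any DEG in any tumor."""


class FormatError(ValueError):
    """Raised when an input file or matrix violates the format contract."""


def _unique(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        dup = next(x for x in labels if x in seen or seen.add(x))  # type: ignore[func-returns-value]
        raise FormatError(f"duplicate {what} identifier: {dup!r}")
    return labels


@dataclass(eq=False)
class BinaryEventMatrix:
    """A tumor×gene 0/1 event matrix with ordered axis labels.

    Serves both as the SGA matrix (1 = gene somatically altered in tumor) and
    the DEG matrix (1 = gene differentially expressed in tumor).
    """

    values: np.ndarray
    tumors: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise FormatError("matrix must be 2-dimensional")
        self.tumors = _unique(self.tumors, "tumor")
        self.genes = _unique(self.genes, "gene")
        if self.values.shape != (len(self.tumors), len(self.genes)):
            raise FormatError(
                f"shape {self.values.shape} does not match labels "
                f"({len(self.tumors)} tumors × {len(self.genes)} genes)"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"non-binary cell at tumor {self.tumors[i]!r}, "
                f"gene {self.genes[j]!r}: {self.values[i, j]!r}"
            )
        self.values = self.values.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_tumors(self) -> int:
        return len(self.tumors)

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def tumor_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tumors)}

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.genes.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tumors, columns=self.genes)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BinaryEventMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def subset_genes(self, genes: Iterable[str]) -> "BinaryEventMatrix":
        genes = list(genes)
        idx = self.gene_index()
        cols = [idx[g] for g in genes]
        return BinaryEventMatrix(self.values[:, cols], list(self.tumors), genes)

    def copy(self) -> "BinaryEventMatrix":
        return BinaryEventMatrix(self.values.copy(), list(self.tumors), list(self.genes))

    def equals(self, other: "BinaryEventMatrix") -> bool:
        return (
            self.tumors == other.tumors
            and self.genes == other.genes
            and np.array_equal(self.values, other.values)
        )


SCNA_LEVELS = (-2, -1, 0, 1, 2)


@dataclass(eq=False)
class ScnaCallMatrix:
    """GISTIC-style thresholded copy-number calls, gene×tumor.

    Levels: −2 homozygous deletion, −1 single-copy deletion, 0 diploid,
    +1 low-level amplification, +2 high-level amplification.
    """

    values: np.ndarray
    genes: list[str]
    tumors: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise FormatError("matrix must be 2-dimensional")
        self.genes = _unique(self.genes, "gene")
        self.tumors = _unique(self.tumors, "tumor")
        if self.values.shape != (len(self.genes), len(self.tumors)):
            raise FormatError(
                f"shape {self.values.shape} does not match labels "
                f"({len(self.genes)} genes × {len(self.tumors)} tumors)"
            )
        bad = ~np.isin(self.values, SCNA_LEVELS)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"copy-number level outside {{-2..2}} at gene {self.genes[i]!r}, "
                f"tumor {self.tumors[j]!r}: {self.values[i, j]!r}"
            )
        self.values = self.values.astype(np.int8)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.tumors)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScnaCallMatrix":
        return cls(df.to_numpy(), list(df.index), list(df.columns))


@dataclass(eq=False)
class NormalReference:
    """Per-(gene, tissue) Gaussian parameters of log2 expression in normals.

    ``table`` columns: gene, tissue, mean, sd, n. One row per (gene, tissue).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "tissue", "mean", "sd", "n"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"normal reference missing columns: {sorted(missing)}")
        if (self.table["sd"] < 0).any():
            raise FormatError("normal reference sd must be >= 0")
        if (self.table["n"] < 1).any():
            raise FormatError("normal reference n must be >= 1")
        if self.table.duplicated(["gene", "tissue"]).any():
            raise FormatError("duplicate (gene, tissue) pair in normal reference")
        self._by_tissue = {
            tissue: grp.set_index("gene")[["mean", "sd"]]
            for tissue, grp in self.table.groupby("tissue")
        }

    def params(self, tissue: str) -> pd.DataFrame:
        """(mean, sd) frame indexed by gene for one tissue; empty if unknown."""
        return self._by_tissue.get(tissue, pd.DataFrame(columns=["mean", "sd"]))


@dataclass(eq=False)
class MutSigTable:
    """Per-gene MutSigCV significance p-values used for the Eq-3-style prior."""

    pvalues: dict[str, float]

    def __post_init__(self) -> None:
        for gene, p in self.pvalues.items():
            if not (0.0 <= p <= 1.0):
                raise FormatError(f"MutSig p for {gene!r} outside [0, 1]: {p}")

    def get(self, gene: str, default: float = 1.0) -> float:
        """Missing genes default to p = 1 (no evidence of positive selection)."""
        return self.pvalues.get(gene, default)


@dataclass(eq=False)
class GeneSetCollection:
    """Named gene sets with GMT semantics (unique names, non-empty sets)."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass(eq=False)
class Cohort:
    """SGA and DEG matrices over one ordered tumor set, plus tissue labels."""

    sga: BinaryEventMatrix
    deg: BinaryEventMatrix
    tissue: dict[str, str]

    def __post_init__(self) -> None:
        if self.sga.tumors != self.deg.tumors:
            raise FormatError("SGA and DEG matrices must share the same tumor order")
        missing = [t for t in self.sga.tumors if t not in self.tissue]
        if missing:
            raise FormatError(f"tumors without tissue label: {missing[:5]}")
        shared = set(self.sga.genes) & set(self.deg.genes)
        # Shared symbols across axes are legal (a gene can be both altered and
        # differentially expressed); nothing to enforce here.
        self._ = shared

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.sga.tumors)

    @property
    def n_tumors(self) -> int:
        return self.sga.n_tumors

    def tissue_vector(self) -> np.ndarray:
        return np.array([self.tissue[t] for t in self.sga.tumors])

    def sga_set(self, tumor: str) -> list[str]:
        """Genes altered in ``tumor``, in SGA-axis order."""
        row = self.sga.values[self.sga.tumors.index(tumor)]
        return [g for g, v in zip(self.sga.genes, row) if v]

    def deg_set(self, tumor: str) -> list[str]:
        row = self.deg.values[self.deg.tumors.index(tumor)]
        return [g for g, v in zip(self.deg.genes, row) if v]
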