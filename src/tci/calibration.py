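"""Permutation nulls for edge posteriors and empirical p-values.

Raw edge posteriors are not comparable across SGAs: a frequent alteration can
reach moderately high posteriors by chance alone, a rare one cannot. The
calibration step builds, for each SGA, an empirical null distribution of the
posteriors it attains on datasets in which the DEG matrix has been permuted
among tumors of a common tissue of origin while the SGA matrix stays as
observed — destroying SGA→DEG signal but preserving tissue structure and
alteration frequencies. An observed posterior P_e is then converted to

    p = (1 + #{null ≥ P_e}) / (1 + N_null),

the pseudo-counted upper-tail rank, which can never be exactly zero.

By default the null pools, per SGA, the posteriors of the edges on which that
SGA was the designated (most probable) cause — the same statistic that is
tested on real data, which is what makes the resulting p-values uniform
under the null. Pooling every candidate-edge posterior instead is available
via ``pool="all"`` but yields a stochastically smaller null and therefore
anti-conservative p-values for top edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .types import A0, BinaryEventMatrix, Cohort, FormatError
from .priors import PriorVector
from .engine import (
    ScoreCache,
    TumorCausalModel,
    _tumor_posterior_matrix,
    compute_scores,
)


@dataclass(eq=False)
class CalibrationTable:
    """Per-SGA sorted null posteriors, with a global pooled fallback."""

    nulls: dict[str, np.ndarray]
    global_null: np.ndarray
    n_perm: int
    seed: int
    pool: str = "winners"
    min_null_size: int = 1000

    def null_for(self, sga: str) -> np.ndarray:
        null = self.nulls.get(sga)
        if null is None or null.size < self.min_null_size:
            return self.global_null
        return null

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "pool": self.pool,
            "min_null_size": self.min_null_size,
            "global_null": self.global_null.tolist(),
            "nulls": {g: v.tolist() for g, v in self.nulls.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationTable":
        return cls(
            nulls={g: np.asarray(v, dtype=float) for g, v in d["nulls"].items()},
            global_null=np.asarray(d["global_null"], dtype=float),
            n_perm=int(d["n_perm"]),
            seed=int(d["seed"]),
            pool=d.get("pool", "winners"),
            min_null_size=int(d.get("min_null_size", 1000)),
        )


def permute_degs_within_tissue(
    deg: BinaryEventMatrix,
    tissue: Mapping[str, str],
    seed: int | np.random.Generator = 0,
) -> BinaryEventMatrix:
    """Shuffle each DEG column independently within each tissue block.

    Per-tissue column sums are preserved gene by gene; the tumor axis and the
    SGA matrix (not touched here) keep their observed values.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = deg.values.copy()
    types = np.array([tissue[t] for t in deg.tumors])
    for ct in np.unique(types):
        rows = np.flatnonzero(types == ct)
        # independent per-column permutations via column-wise random ranks
        order = np.argsort(rng.random((rows.size, values.shape[1])), axis=0)
        values[rows] = values[rows][order, np.arange(values.shape[1])]
    return BinaryEventMatrix(values, list(deg.tumors), list(deg.genes))


def permute_single_sga(cohort: Cohort, gene: str, seed: int | np.random.Generator = 0) -> Cohort:
    """Shuffle one gene's SGA column across all tumors (frequency preserved).

    Everything else — other SGA columns, the DEG matrix, tissue labels — is
    byte-identical to the input cohort.
    """
    if gene not in cohort.sga.genes:
        raise FormatError(f"unknown SGA gene: {gene!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = cohort.sga.values.copy()
    j = cohort.sga.genes.index(gene)
    values[:, j] = rng.permutation(values[:, j])
    sga = BinaryEventMatrix(values, list(cohort.sga.tumors), list(cohort.sga.genes))
    return Cohort(sga=sga, deg=cohort.deg.copy(), tissue=dict(cohort.tissue))


def build_null(
    cohort: Cohort,
    priors: Mapping[str, PriorVector],
    n_perm: int = 20,
    seed: int = 0,
    alpha1: float = 1.0,
    alpha0: float = 1.0,
    pool: str = "winners",
    min_null_size: int = 1000,
) -> CalibrationTable:
    """Run inference on ``n_perm`` permuted datasets and pool per-SGA nulls."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if pool not in ("winners", "all"):
        raise ValueError(f"unknown pooling mode: {pool!r}")
    rng = np.random.default_rng(seed)
    buckets: dict[str, list[np.ndarray]] = {g: [] for g in cohort.sga.genes}
    deg_genes = np.array(cohort.deg.genes)
    for _ in range(n_perm):
        deg_p = permute_degs_within_tissue(cohort.deg, cohort.tissue, rng)
        scores = compute_scores(cohort.sga, deg_p, alpha1, alpha0)
        for i, tumor in enumerate(cohort.tumor_ids):
            deg_idx = np.flatnonzero(deg_p.values[i])
            if deg_idx.size == 0:
                continue
            prior = priors[tumor]
            candidates, post = _tumor_posterior_matrix(prior, deg_idx, scores)
            if pool == "winners":
                winners = post.argmax(axis=0)
                for j, g in enumerate(candidates[:-1]):  # A0 is last, never pooled
                    won = winners == j
                    if won.any():
                        buckets[g].append(post[j, won])
            else:
                for j, g in enumerate(candidates[:-1]):
                    buckets[g].append(post[j])
    nulls = {
        g: np.sort(np.concatenate(parts)) if parts else np.empty(0)
        for g, parts in buckets.items()
    }
    pooled = [v for v in nulls.values() if v.size]
    if not pooled:
        raise FormatError("calibration produced an empty global null")
    global_null = np.sort(np.concatenate(pooled))
    return CalibrationTable(
        nulls=nulls,
        global_null=global_null,
        n_perm=n_perm,
        seed=seed if isinstance(seed, int) else -1,
        pool=pool,
        min_null_size=min_null_size,
    )


def edge_pvalue(p_e: float, table: CalibrationTable, sga: str) -> float:
    """Empirical upper-tail p-value of an observed posterior for one SGA."""
    null = table.null_for(sga)
    if null.size == 0:
        raise FormatError("calibration missing: empty null distribution")
    n_ge = null.size - int(np.searchsorted(null, p_e, side="left"))
    return (1 + n_ge) / (1 + null.size)


def attach_pvalues(
    models: Sequence[TumorCausalModel], table: CalibrationTable
) -> list[TumorCausalModel]:
    """Fill empirical p-values in place for every SGA-caused assignment.

    A0 assignments keep ``pvalue=None`` — the non-specific cause is never a
    driver call candidate. Returns the same model list for chaining.
    """
    for model in models:
        for a in model.assignments:
            a.pvalue = None if a.cause == A0 else edge_pvalue(a.posterior, table, a.cause)
    return list(models)
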