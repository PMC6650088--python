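"""Bipartite causal edge scoring and per-tumor posterior inference.

For each tumor t, every DEG E_i observed in t is explained by exactly one
cause drawn from {A0} ∪ SGA_SET_t. The posterior over candidate causes is

    P(A_h → E_i | D) ∝ P(A_h → E_i) · P(D | A_h → E_i),

where the prior is the tumor-specific θ vector and the marginal likelihood
is a two-stratum Beta-Bernoulli (K2-style) score computed on the whole
cohort: tumors hosting A_h and tumors not hosting A_h each contribute an
integrated Bernoulli likelihood of E_i with a Beta(α1, α0) parameter prior,

    P(D | A_h→E_i) = Π_{v∈{0,1}} B(α1 + n_{v1}, α0 + n_{v0}) / B(α1, α0),

with n_{v1}/n_{v0} the DEG-positive/negative counts in stratum A_h = v. The
non-specific cause A0 is "present" in every tumor, so its score is the
single-stratum marginal over the whole cohort. Scores depend only on the
(SGA gene, DEG gene) pair, so they are computed once per cohort and shared
by all tumors; tumor specificity enters through the candidate set and the
prior. All arithmetic is in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import betaln, logsumexp

from .types import A0, BinaryEventMatrix, Cohort, FormatError
from .priors import PriorVector


@dataclass(frozen=True)
class EdgeCounts:
    """2×2 cross-tabulation of (SGA present, DEG present) over the cohort."""

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def edge_counts(sga_col: np.ndarray, deg_col: np.ndarray) -> EdgeCounts:
    """Exact 2×2 cross-tabulation of two equal-length binary vectors."""
    sga_col = np.asarray(sga_col)
    deg_col = np.asarray(deg_col)
    if sga_col.shape != deg_col.shape:
        raise ValueError("SGA and DEG vectors differ in length")
    s = sga_col.astype(bool)
    e = deg_col.astype(bool)
    return EdgeCounts(
        n11=int((s & e).sum()),
        n10=int((s & ~e).sum()),
        n01=int((~s & e).sum()),
        n00=int((~s & ~e).sum()),
    )


def edge_loglik(counts: EdgeCounts, alpha1: float = 1.0, alpha0: float = 1.0) -> float:
    """Log marginal likelihood of A_h → E_i: independent Beta-Bernoulli
    marginals in the SGA-present and SGA-absent strata."""
    base = betaln(alpha1, alpha0)
    return float(
        betaln(alpha1 + counts.n11, alpha0 + counts.n10)
        + betaln(alpha1 + counts.n01, alpha0 + counts.n00)
        - 2.0 * base
    )


def a0_loglik(deg_col: np.ndarray, alpha1: float = 1.0, alpha0: float = 1.0) -> float:
    """Log marginal likelihood of A0 → E_i: a single stratum over all tumors
    (the non-specific cause has no on/off pattern)."""
    deg_col = np.asarray(deg_col)
    k = int(deg_col.astype(bool).sum())
    n = deg_col.size
    return float(betaln(alpha1 + k, alpha0 + n - k) - betaln(alpha1, alpha0))


@dataclass(eq=False)
class ScoreCache:
    """Cohort-level edge scores shared across tumors.

    L[h, i] is the log marginal likelihood of SGA gene h causing DEG gene i;
    L0[i] is the A0 score for DEG gene i.
    """

    L: np.ndarray
    L0: np.ndarray
    sga_genes: list[str]
    deg_genes: list[str]
    alpha1: float = 1.0
    alpha0: float = 1.0
    sga_index: dict[str, int] = field(init=False)
    deg_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.sga_index = {g: i for i, g in enumerate(self.sga_genes)}
        self.deg_index = {g: i for i, g in enumerate(self.deg_genes)}


def compute_scores(
    sga: BinaryEventMatrix,
    deg: BinaryEventMatrix,
    alpha1: float = 1.0,
    alpha0: float = 1.0,
) -> ScoreCache:
    """Vectorized edge scores for every (SGA gene, DEG gene) pair."""
    if sga.tumors != deg.tumors:
        raise FormatError("SGA and DEG matrices must share the same tumor order")
    S = sga.values.astype(np.float64)
    E = deg.values.astype(np.float64)
    n = S.shape[0]
    n11 = S.T @ E
    n1 = S.sum(axis=0)[:, None]
    e1 = E.sum(axis=0)[None, :]
    n10 = n1 - n11
    n01 = e1 - n11
    n00 = n - n1 - e1 + n11
    base = betaln(alpha1, alpha0)
    L = betaln(alpha1 + n11, alpha0 + n10) + betaln(alpha1 + n01, alpha0 + n00) - 2.0 * base
    L0 = betaln(alpha1 + e1[0], alpha0 + (n - e1[0])) - base
    return ScoreCache(L, L0, list(sga.genes), list(deg.genes), alpha1, alpha0)


SCORES = {"beta_bernoulli": compute_scores}
"""Registry of pluggable edge-scoring functions (signature of compute_scores)."""


@dataclass(eq=False)
class CausalAssignment:
    """One DEG's designated cause in one tumor."""

    tumor_id: str
    deg: str
    cause: str
    posterior: float
    pvalue: float | None = None
    posterior_vector: dict[str, float] | None = None


@dataclass(eq=False)
class TumorCausalModel:
    """The tumor-specific causal model M_t: exactly one cause per DEG."""

    tumor_id: str
    assignments: list[CausalAssignment]

    def __post_init__(self) -> None:
        degs = [a.deg for a in self.assignments]
        if len(set(degs)) != len(degs):
            raise ValueError(f"duplicate DEG in model for tumor {self.tumor_id!r}")

    def cause_of(self, deg: str) -> str:
        for a in self.assignments:
            if a.deg == deg:
                return a.cause
        raise KeyError(deg)


def _tumor_posterior_matrix(
    prior: PriorVector,
    deg_idx: np.ndarray,
    scores: ScoreCache,
) -> tuple[list[str], np.ndarray]:
    """Log-space posterior over candidates for each of a tumor's DEGs.

    Returns (candidates, P) with candidates ordered SGA genes (prior order,
    lexicographic) first and A0 last, P of shape (n_candidates, n_degs) with
    columns summing to 1. The candidate ordering makes ``argmax`` implement
    the deterministic tie-break: highest posterior, A0 losing ties, then
    lexicographically smallest gene.
    """
    sga_set = prior.causes[1:]
    theta = prior.theta
    rows = [scores.sga_index[g] for g in sga_set]
    with np.errstate(divide="ignore"):
        log_theta = np.log(np.concatenate([theta[1:], theta[:1]]))
    logp = np.vstack(
        [scores.L[np.ix_(rows, deg_idx)], scores.L0[deg_idx][None, :]]
    ) + log_theta[:, None]
    logp -= logsumexp(logp, axis=0, keepdims=True)
    return sga_set + [A0], np.exp(logp)


def infer_tumor_model(
    tumor_id: str,
    prior: PriorVector,
    deg_genes: Sequence[str],
    scores: ScoreCache,
    keep_posteriors: bool = False,
) -> TumorCausalModel:
    """Infer the causal model for one tumor given its prior and DEG set."""
    deg_genes = list(deg_genes)
    if not deg_genes:
        return TumorCausalModel(tumor_id, [])
    missing = [g for g in prior.causes[1:] if g not in scores.sga_index]
    if missing:
        raise FormatError(f"prior covers genes absent from the score cache: {missing[:5]}")
    deg_idx = np.array([scores.deg_index[g] for g in deg_genes])
    candidates, post = _tumor_posterior_matrix(prior, deg_idx, scores)
    winners = post.argmax(axis=0)
    assignments = []
    for k, deg in enumerate(deg_genes):
        j = winners[k]
        assignments.append(
            CausalAssignment(
                tumor_id=tumor_id,
                deg=deg,
                cause=candidates[j],
                posterior=float(post[j, k]),
                posterior_vector=(
                    dict(zip(candidates, post[:, k].tolist())) if keep_posteriors else None
                ),
            )
        )
    return TumorCausalModel(tumor_id, assignments)


def infer_cohort(
    cohort: Cohort,
    priors: Mapping[str, PriorVector],
    scores: ScoreCache | None = None,
    alpha1: float = 1.0,
    alpha0: float = 1.0,
    keep_posteriors: bool = False,
) -> list[TumorCausalModel]:
    """One causal model per tumor; deterministic given the inputs."""
    missing = [t for t in cohort.tumor_ids if t not in priors]
    if missing:
        raise FormatError(f"tumors without prior: {missing[:5]}")
    if scores is None:
        scores = compute_scores(cohort.sga, cohort.deg, alpha1, alpha0)
    deg_values = cohort.deg.values
    deg_genes = np.array(cohort.deg.genes)
    models = []
    for i, tumor in enumerate(cohort.tumor_ids):
        degs = deg_genes[deg_values[i] == 1]
        models.append(
            infer_tumor_model(tumor, priors[tumor], list(degs), scores, keep_posteriors)
        )
    return models


def models_frame(models: Sequence[TumorCausalModel]):
    """Long-format edge table (tumor_id, deg, cause, posterior, pvalue)."""
    import pandas as pd

    rows = [
        (m.tumor_id, a.deg, a.cause, a.posterior, a.pvalue)
        for m in models
        for a in m.assignments
    ]
    return pd.DataFrame(rows, columns=["tumor_id", "deg", "cause", "posterior", "pvalue"])
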