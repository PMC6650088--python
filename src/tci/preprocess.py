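"""Build the SGA and DEG binary matrices from raw inputs.

The SGA side combines gene-level somatic mutations (any non-synonymous SNV or
indel) with GISTIC-thresholded copy-number extremes (homozygous deletion −2,
high-level amplification +2), after screening out genes whose amplification
and deletion calls are inconsistent within a cancer type. The DEG side calls
each (tumor, gene) against the tissue-matched normal Gaussian at a per-side
p ≤ 0.005, then strips DEGs explained in cis by a copy-number event and DEGs
that merely mark tissue of origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import BinaryEventMatrix, FormatError, NormalReference, ScnaCallMatrix

log = logging.getLogger(__name__)

VARIANT_CLASSES = ("non_synonymous_snv", "indel", "synonymous", "other")
SGA_VARIANT_CLASSES = ("non_synonymous_snv", "indel")


@dataclass
class Removal:
    """One logged filtering action (gene dropped or event zeroed)."""

    gene: str
    rule: str
    cancer_type: str | None = None
    statistic: float | None = None
    detail: str = ""


def removals_frame(removals: Sequence[Removal]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.rule, r.cancer_type, r.statistic, r.detail) for r in removals],
        columns=["gene", "rule", "cancer_type", "statistic", "detail"],
    )


def binarize_mutations(
    events: pd.DataFrame,
    tumors: Sequence[str],
    genes: Sequence[str],
    strict: bool = True,
) -> BinaryEventMatrix:
    """Collapse a mutation event table to a tumor×gene 0/1 matrix.

    ``events`` columns: tumor_id, gene, variant_class. A cell is 1 iff the
    tumor carries at least one non-synonymous SNV or indel in the gene;
    synonymous and other classes never set a bit.
    """
    required = {"tumor_id", "gene", "variant_class"}
    if not required.issubset(events.columns):
        raise FormatError(f"mutation table needs columns {sorted(required)}")
    bad_class = set(events["variant_class"]) - set(VARIANT_CLASSES)
    if bad_class:
        raise FormatError(f"unknown variant_class values: {sorted(bad_class)}")

    tumors = list(tumors)
    genes = list(genes)
    t_idx = {t: i for i, t in enumerate(tumors)}
    g_idx = {g: i for i, g in enumerate(genes)}
    values = np.zeros((len(tumors), len(genes)), dtype=np.uint8)
    mask = events["variant_class"].isin(SGA_VARIANT_CLASSES)
    for tumor, gene in zip(events.loc[mask, "tumor_id"], events.loc[mask, "gene"]):
        if tumor not in t_idx:
            if strict:
                raise FormatError(f"mutation event references unknown tumor {tumor!r}")
            log.warning("skipping event for unknown tumor %r", tumor)
            continue
        if gene not in g_idx:
            if strict:
                raise FormatError(f"mutation event references unknown gene {gene!r}")
            log.warning("skipping event for unknown gene %r", gene)
            continue
        values[t_idx[tumor], g_idx[gene]] = 1
    return BinaryEventMatrix(values, tumors, genes)


def filter_scna(
    calls: ScnaCallMatrix,
    tissue: dict[str, str],
    max_both_frac: float = 0.25,
) -> tuple[BinaryEventMatrix, list[Removal]]:
    """Binarize copy-number calls and drop within-type inconsistent genes.

    Levels −2 (homozygous deletion) and +2 (high amplification) become 1.
    Then, per cancer type, a gene whose −2 frequency AND +2 frequency each
    exceed ``max_both_frac`` (strict >) among that type's tumors is zeroed
    for all tumors of that type: such a gene is being called in both
    directions and neither call is trustworthy there.
    """
    missing = [t for t in calls.tumors if t not in tissue]
    if missing:
        raise FormatError(f"tumors without tissue label: {missing[:5]}")
    levels = calls.values  # gene×tumor
    binary = np.isin(levels, (-2, 2)).astype(np.uint8).T  # tumor×gene
    tumors = list(calls.tumors)
    genes = list(calls.genes)
    types = np.array([tissue[t] for t in tumors])
    removals: list[Removal] = []
    for cancer_type in pd.unique(types):
        cols = np.flatnonzero(types == cancer_type)
        n = len(cols)
        amp_frac = (levels[:, cols] == 2).sum(axis=1) / n
        del_frac = (levels[:, cols] == -2).sum(axis=1) / n
        inconsistent = (amp_frac > max_both_frac) & (del_frac > max_both_frac)
        for gi in np.flatnonzero(inconsistent):
            binary[cols, gi] = 0
            removals.append(
                Removal(
                    gene=genes[gi],
                    rule="scna_inconsistent",
                    cancer_type=str(cancer_type),
                    statistic=float(min(amp_frac[gi], del_frac[gi])),
                    detail=f"amp_frac={amp_frac[gi]:.4f},del_frac={del_frac[gi]:.4f}",
                )
            )
    return BinaryEventMatrix(binary, tumors, genes), removals


def combine_sga(sm: BinaryEventMatrix, scna: BinaryEventMatrix) -> BinaryEventMatrix:
    """Elementwise OR of mutation and copy-number events on the unioned gene axis.

    A gene absent from one input contributes 0 from that side. Gene order:
    SM genes in order, then SCNA-only genes in order.
    """
    if sm.tumors != scna.tumors:
        raise FormatError("SM and SCNA matrices must share the same tumor order")
    genes = list(sm.genes) + [g for g in scna.genes if g not in set(sm.genes)]
    values = np.zeros((len(sm.tumors), len(genes)), dtype=np.uint8)
    g_idx = {g: i for i, g in enumerate(genes)}
    for src in (sm, scna):
        cols = [g_idx[g] for g in src.genes]
        values[:, cols] |= src.values
    return BinaryEventMatrix(values, list(sm.tumors), genes)


def call_degs(
    expr: pd.DataFrame,
    tissue: dict[str, str],
    ref: NormalReference,
    alpha: float = 0.005,
) -> tuple[BinaryEventMatrix, np.ndarray, list[Removal]]:
    """Call DEGs against the tissue-matched normal Gaussian.

    ``expr`` is gene×tumor log2 expression. For tumor t of tissue s and gene
    g with value x, the one-sided tail p is Φ(z) below or 1−Φ(z) above with
    z = (x − mean_{g,s}) / sd_{g,s}; the gene is a DEG iff the smaller side
    has p ≤ alpha (inclusive). Returns the tumor×gene DEG matrix, a matching
    int8 direction matrix (−1 under-, +1 over-expressed, 0 otherwise), and a
    log of genes excluded for missing or degenerate reference stats.
    """
    tumors = list(expr.columns)
    genes = [str(g) for g in expr.index]
    missing = [t for t in tumors if t not in tissue]
    if missing:
        raise FormatError(f"tumors without tissue label: {missing[:5]}")
    deg = np.zeros((len(tumors), len(genes)), dtype=np.uint8)
    direction = np.zeros((len(tumors), len(genes)), dtype=np.int8)
    removals: list[Removal] = []
    types = np.array([tissue[t] for t in tumors])
    x_all = expr.to_numpy(dtype=float)  # gene×tumor
    g_pos = {g: i for i, g in enumerate(genes)}
    for cancer_type in pd.unique(types):
        cols = np.flatnonzero(types == cancer_type)
        params = ref.params(str(cancer_type))
        usable = [g for g in genes if g in params.index and params.at[g, "sd"] > 0]
        for g in genes:
            if g not in params.index:
                removals.append(Removal(g, "no_normal_reference", str(cancer_type)))
            elif params.at[g, "sd"] <= 0:
                removals.append(Removal(g, "zero_reference_sd", str(cancer_type)))
        if not usable:
            continue
        rows = np.array([g_pos[g] for g in usable])
        mean = params.loc[usable, "mean"].to_numpy()
        sd = params.loc[usable, "sd"].to_numpy()
        z = (x_all[np.ix_(rows, cols)] - mean[:, None]) / sd[:, None]
        p_two_min = stats.norm.sf(np.abs(z))  # smaller one-sided tail
        is_deg = p_two_min <= alpha
        deg[np.ix_(cols, rows)] = is_deg.T.astype(np.uint8)
        direction[np.ix_(cols, rows)] = (np.sign(z) * is_deg).T.astype(np.int8)
    return BinaryEventMatrix(deg, tumors, genes), direction, removals


def remove_cis_scna_degs(
    deg: BinaryEventMatrix,
    direction: np.ndarray,
    scna_calls: ScnaCallMatrix,
    concordant_only: bool = True,
) -> tuple[BinaryEventMatrix, list[Removal]]:
    """Drop DEGs explained in cis by a copy-number event on the same gene.

    With ``concordant_only`` (default) a DEG is removed only when the event
    sign matches the expression change (+2 with over-expression, −2 with
    under-expression); otherwise any −2/+2 event on the gene removes it.
    """
    if list(scna_calls.tumors) != deg.tumors:
        raise FormatError("DEG and SCNA matrices must share the same tumor order")
    values = deg.values.copy()
    removals: list[Removal] = []
    scna_g = {g: i for i, g in enumerate(scna_calls.genes)}
    for j, gene in enumerate(deg.genes):
        if gene not in scna_g:
            continue
        levels = scna_calls.values[scna_g[gene]]  # per tumor
        if concordant_only:
            hit = ((levels == 2) & (direction[:, j] > 0)) | (
                (levels == -2) & (direction[:, j] < 0)
            )
        else:
            hit = np.isin(levels, (-2, 2))
        hit = hit & (values[:, j] == 1)
        if hit.any():
            values[hit, j] = 0
            removals.append(
                Removal(gene, "cis_scna", statistic=float(hit.sum()), detail="tumor_count")
            )
    return BinaryEventMatrix(values, list(deg.tumors), list(deg.genes)), removals


def remove_tissue_specific_degs(
    deg: BinaryEventMatrix,
    tissue: dict[str, str],
    rule: str = "presence",
    hi: float = 0.90,
    lo: float = 0.01,
    r_max: float = 0.9,
) -> tuple[BinaryEventMatrix, list[Removal]]:
    """Drop DEG columns that merely mark tissue of origin.

    presence rule: frequency > ``hi`` in one cancer type while < ``lo`` in
    every other type. correlation rule: Pearson r > ``r_max`` between the
    gene's DEG indicator and any one-vs-rest cancer-type indicator.
    ``both`` applies either. Dropped gene columns are zeroed everywhere.
    """
    if rule not in ("presence", "correlation", "both"):
        raise ValueError(f"unknown tissue-specific rule: {rule!r}")
    types = np.array([tissue[t] for t in deg.tumors])
    unique_types = pd.unique(types)
    if len(unique_types) < 2:
        log.warning("single-cancer-type cohort: tissue-specific DEG rule is a no-op")
        return deg.copy(), []
    values = deg.values.copy()
    removals: list[Removal] = []
    masks = {ct: types == ct for ct in unique_types}
    freqs = np.stack([values[m].mean(axis=0) for m in masks.values()])  # type×gene
    drop = np.zeros(len(deg.genes), dtype=bool)
    if rule in ("presence", "both"):
        for i, ct in enumerate(unique_types):
            others = np.delete(freqs, i, axis=0)
            hits = (freqs[i] > hi) & (others < lo).all(axis=0)
            for j in np.flatnonzero(hits & ~drop):
                removals.append(
                    Removal(deg.genes[j], "tissue_presence", str(ct), float(freqs[i, j]))
                )
            drop |= hits
    if rule in ("correlation", "both"):
        col = values.astype(float)
        col_c = col - col.mean(axis=0)
        col_sd = col.std(axis=0)
        for i, ct in enumerate(unique_types):
            ind = masks[ct].astype(float)
            ind_c = ind - ind.mean()
            denom = col_sd * ind.std() * len(ind)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, col_c.T @ ind_c / denom, 0.0)
            hits = r > r_max
            for j in np.flatnonzero(hits & ~drop):
                removals.append(
                    Removal(deg.genes[j], "tissue_correlation", str(ct), float(r[j]))
                )
            drop |= hits
    values[:, drop] = 0
    return BinaryEventMatrix(values, list(deg.tumors), list(deg.genes)), removals
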