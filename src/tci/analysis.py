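"""Post-inference analyses over SGA-FI calls and target DEG sets.

Covers: pairwise Fisher overlap networks between SGA-FI target sets,
hypergeometric gene-set overlap, hallmark-style coverage fractions,
per-tumor mechanism graphs (which functional process each SGA-FI perturbs),
and the sensitivity of top-cause assignments to the A0 prior θ0.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import A0, Cohort, GeneSetCollection
from .priors import THETA0_GRID, PriorInputs, cohort_priors
from .engine import ScoreCache, TumorCausalModel, compute_scores, infer_cohort
from .calling import SgaFiCall

log = logging.getLogger(__name__)


def hypergeometric_overlap(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeometric(N population, K marked,
    n drawn) — the one-sided Fisher exact p of an observed overlap of k."""
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def pairwise_target_overlap(
    target_sets: Mapping[str, set],
    universe_size: int,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Significantly overlapping SGA-FI pairs (one-sided Fisher + BH).

    Tests every unordered pair of non-empty target sets against a universe
    of ``universe_size`` candidate target DEGs; keeps pairs with p < p_max
    and BH q < q_max. Columns: sga_a, sga_b, overlap, p, q.
    """
    names = sorted(g for g, s in target_sets.items() if s)
    for g in sorted(set(target_sets) - set(names)):
        log.info("skipping %s: empty target set", g)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = target_sets[a], target_sets[b]
            k = len(sa & sb)
            rows.append((a, b, k, hypergeometric_overlap(k, len(sb), len(sa), universe_size)))
    df = pd.DataFrame(rows, columns=["sga_a", "sga_b", "overlap", "p"])
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        return df
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df[(df["p"] < p_max) & (df["q"] < q_max)].reset_index(drop=True)


def overlap_graph(edges: pd.DataFrame) -> nx.Graph:
    """Undirected overlap network from a pairwise_target_overlap table."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.sga_a, row.sga_b, overlap=row.overlap, p=row.p, q=row.q)
    return g


def hallmark_coverage(
    target_sets: Mapping[str, set],
    genesets: GeneSetCollection,
) -> pd.DataFrame:
    """Fraction of each gene set covered by each SGA-FI's targets.

    Rows: SGA; columns: gene set; cell = |targets ∩ set| / |set|.
    """
    sgas = sorted(target_sets)
    names = sorted(genesets)
    data = np.zeros((len(sgas), len(names)))
    for i, sga in enumerate(sgas):
        targets = target_sets[sga]
        for j, name in enumerate(names):
            members = genesets[name]
            data[i, j] = len(targets & members) / len(members)
    return pd.DataFrame(data, index=sgas, columns=names)


def tumor_mechanism_graph(
    model: TumorCausalModel,
    calls: Sequence[SgaFiCall],
    genesets: GeneSetCollection,
    universe: set,
    min_frac: float = 0.10,
    q_max: float = 0.05,
) -> nx.Graph:
    """Bipartite SGA-FI → process graph for one tumor.

    Processes are gene sets significantly enriched (hypergeometric + BH)
    among the tumor's DEGs; an SGA-FI links to a process when it is the
    designated cause of at least ``min_frac`` of the tumor's DEGs belonging
    to it (inclusive).
    """
    tumor_degs = {a.deg for a in model.assignments} & universe
    tumor_calls = [c for c in calls if c.tumor_id == model.tumor_id]
    graph = nx.Graph()
    graph.add_nodes_from((c.sga for c in tumor_calls), bipartite="sga_fi")
    if not tumor_degs:
        return graph
    names, pvals = [], []
    for name, members in genesets.items():
        marked = members & universe
        if not marked:
            continue
        names.append(name)
        pvals.append(
            hypergeometric_overlap(
                len(tumor_degs & marked), len(tumor_degs), len(marked), len(universe)
            )
        )
    if not names:
        return graph
    qvals = multipletests(pvals, method="fdr_bh")[1]
    enriched = [name for name, q in zip(names, qvals) if q < q_max]
    graph.add_nodes_from(enriched, bipartite="process")
    cause = {a.deg: a.cause for a in model.assignments}
    for name in enriched:
        in_process = tumor_degs & genesets[name]
        for call in tumor_calls:
            caused = sum(1 for d in in_process if cause.get(d) == call.sga)
            frac = caused / len(in_process)
            if frac >= min_frac:
                graph.add_edge(call.sga, name, fraction=frac, n_degs=caused)
    return graph


def mechanism_edges_frame(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        (u, v, d["fraction"], d["n_degs"]) for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["sga_fi", "process", "fraction", "n_degs"])


def a0_sensitivity(
    cohort: Cohort,
    scheme: str = "uniform",
    inputs: PriorInputs | None = None,
    theta0_grid: Sequence[float] = THETA0_GRID,
    reference_theta0: float = 0.1,
    scores: ScoreCache | None = None,
) -> pd.DataFrame:
    """Fraction of (tumor, DEG) top-cause changes across the θ0 grid.

    Each grid value is compared against the reference run at
    ``reference_theta0``; edge scores are computed once and shared, since θ0
    only enters through the prior. Columns: theta0, change_rate, n_pairs.
    """
    if scores is None:
        scores = compute_scores(cohort.sga, cohort.deg)

    def top_causes(theta0: float) -> dict[tuple[str, str], str]:
        priors = cohort_priors(cohort, scheme=scheme, inputs=inputs, theta0=theta0)
        models = infer_cohort(cohort, priors, scores=scores)
        return {(m.tumor_id, a.deg): a.cause for m in models for a in m.assignments}

    reference = top_causes(reference_theta0)
    n_pairs = len(reference)
    rows = []
    for theta0 in theta0_grid:
        current = reference if theta0 == reference_theta0 else top_causes(theta0)
        changed = sum(1 for key, cause in reference.items() if current[key] != cause)
        rows.append((theta0, changed / n_pairs if n_pairs else 0.0, n_pairs))
    return pd.DataFrame(rows, columns=["theta0", "change_rate", "n_pairs"])
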