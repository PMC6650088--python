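"""Seeded synthetic cohorts with known causal ground truth.

The generator emulates the data-generating process the causal model assumes:
a handful of driver genes, each altered in a sizeable fraction of tumors,
push fixed sets of target genes into differential expression with some
fidelity; passenger alterations and background expression noise carry no
signal; drivers hitting the same pathway are mutually exclusive (at most one
member of a module per tumor) yet share that pathway's target set, which is
exactly the situation where per-tumor causal attribution beats cohort-level
association. Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
import pandas as pd

from .types import BinaryEventMatrix, Cohort, NormalReference


@dataclass
class SyntheticConfig:
    """Benchmark cohort parameters (defaults are the standard desk-scale
    benchmark used throughout the test suite)."""

    n_tumors: int = 500
    n_tissues: int = 2
    n_sga_genes: int = 150
    n_deg_genes: int = 600
    n_drivers: int = 10
    driver_freq_range: tuple[float, float] = (0.25, 0.4)
    targets_per_driver: int = 20
    fidelity: float = 0.8
    background_deg_rate: float = 0.05
    passenger_sga_rate: float = 0.03
    n_exclusivity_modules: int = 2
    module_size: int = 2

    def validate(self) -> None:
        if self.n_drivers > self.n_sga_genes:
            raise ValueError("more drivers than SGA genes")
        if self.n_exclusivity_modules * self.module_size > self.n_drivers:
            raise ValueError("exclusivity modules need more drivers than configured")
        n_pathways = self.n_drivers - self.n_exclusivity_modules * (self.module_size - 1)
        if n_pathways * self.targets_per_driver > self.n_deg_genes:
            raise ValueError("not enough DEG genes for disjoint pathway target sets")
        for name in ("fidelity", "background_deg_rate", "passenger_sga_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]: {v}")


@dataclass(eq=False)
class SyntheticTruth:
    """Planted ground truth of a generated cohort."""

    drivers: list[str]
    targets: dict[str, list[str]]
    frequencies: dict[str, float]
    modules: list[tuple[str, ...]]
    fidelity: float
    background_deg_rate: float
    passenger_sga_rate: float
    seed: int

    def edges(self) -> set[tuple[str, str]]:
        return {(d, t) for d, ts in self.targets.items() for t in ts}


def generate_cohort(
    config: SyntheticConfig | None = None, seed: int = 0
) -> tuple[Cohort, SyntheticTruth]:
    """Draw a cohort with planted driver→DEG structure.

    Drivers get frequencies evenly spaced across ``driver_freq_range``.
    Same-module drivers never co-occur (one is chosen, proportionally to
    frequency, from a single uniform draw) and share one target set; the
    remaining drivers get disjoint target sets. DEGs fire with probability
    ``fidelity`` per hosted driver's target, OR-ed with background noise.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    c = config

    tumors = [f"T{i + 1:04d}" for i in range(c.n_tumors)]
    sga_genes = [f"S{i + 1:04d}" for i in range(c.n_sga_genes)]
    deg_genes = [f"G{i + 1:04d}" for i in range(c.n_deg_genes)]
    tissues = {t: f"tissue{(i % c.n_tissues) + 1}" for i, t in enumerate(tumors)}

    drivers = sga_genes[: c.n_drivers]
    freqs = dict(zip(drivers, np.linspace(*c.driver_freq_range, c.n_drivers)))
    modules = [
        tuple(drivers[i * c.module_size: (i + 1) * c.module_size])
        for i in range(c.n_exclusivity_modules)
    ]
    in_module = {d for mod in modules for d in mod}
    solo_drivers = [d for d in drivers if d not in in_module]

    # disjoint pathway target sets: one per module, one per solo driver
    pathway_owners: list[tuple[str, ...]] = modules + [(d,) for d in solo_drivers]
    targets: dict[str, list[str]] = {}
    cursor = 0
    for owners in pathway_owners:
        block = deg_genes[cursor: cursor + c.targets_per_driver]
        cursor += c.targets_per_driver
        for d in owners:
            targets[d] = list(block)

    sga = np.zeros((c.n_tumors, c.n_sga_genes), dtype=np.uint8)
    g_idx = {g: i for i, g in enumerate(sga_genes)}
    for mod in modules:
        # single uniform draw per tumor: marginal P(member) = its frequency,
        # co-occurrence within the module exactly zero
        edges = np.cumsum([freqs[d] for d in mod])
        if edges[-1] > 1.0:
            raise ValueError("module frequencies sum above 1; cannot be exclusive")
        u = rng.random(c.n_tumors)
        choice = np.searchsorted(edges, u)  # == len(mod) means no member
        for k, d in enumerate(mod):
            sga[choice == k, g_idx[d]] = 1
    for d in solo_drivers:
        sga[:, g_idx[d]] = rng.random(c.n_tumors) < freqs[d]
    passenger_cols = np.arange(c.n_drivers, c.n_sga_genes)
    sga[:, passenger_cols] = rng.random((c.n_tumors, passenger_cols.size)) < c.passenger_sga_rate

    deg = rng.random((c.n_tumors, c.n_deg_genes)) < c.background_deg_rate
    d_idx = {g: i for i, g in enumerate(deg_genes)}
    for d in drivers:
        hosts = np.flatnonzero(sga[:, g_idx[d]])
        cols = np.array([d_idx[t] for t in targets[d]])
        fired = rng.random((hosts.size, cols.size)) < c.fidelity
        deg[np.ix_(hosts, cols)] |= fired
    cohort = Cohort(
        sga=BinaryEventMatrix(sga, tumors, sga_genes),
        deg=BinaryEventMatrix(deg.astype(np.uint8), tumors, deg_genes),
        tissue=tissues,
    )
    truth = SyntheticTruth(
        drivers=list(drivers),
        targets=targets,
        frequencies={d: float(f) for d, f in freqs.items()},
        modules=modules,
        fidelity=c.fidelity,
        background_deg_rate=c.background_deg_rate,
        passenger_sga_rate=c.passenger_sga_rate,
        seed=seed,
    )
    return cohort, truth


def emit_expression(
    deg: BinaryEventMatrix,
    tissue: Mapping[str, str],
    seed: int = 0,
    alpha: float = 0.005,
    effect: float = 2.0,
) -> tuple[pd.DataFrame, NormalReference]:
    """Gaussian log2 expression consistent with a binary DEG matrix.

    For DEG entries the z-score is placed beyond the two-sided alpha
    boundary by an Exp(1/effect) margin with random sign; non-DEG entries
    are drawn from the normal reference truncated inside the boundary. A
    matching per-(gene, tissue) reference (mean 8, sd 1, n 100) is returned,
    so feeding the pair through the DEG caller reproduces ``deg`` exactly.
    """
    rng = np.random.default_rng(seed)
    z_crit = float(stats.norm.isf(alpha))
    n_t, n_g = deg.shape
    u = rng.random((n_t, n_g))
    inner = stats.norm.ppf(stats.norm.cdf(-z_crit) + u * (1 - 2 * stats.norm.cdf(-z_crit)))
    outer = (z_crit + rng.exponential(1.0 / effect, (n_t, n_g))) * np.where(
        rng.random((n_t, n_g)) < 0.5, 1.0, -1.0
    )
    z = np.where(deg.values == 1, outer, inner)
    mean, sd = 8.0, 1.0
    expr = pd.DataFrame((mean + sd * z).T, index=deg.genes, columns=deg.tumors)
    rows = [
        {"gene": g, "tissue": ct, "mean": mean, "sd": sd, "n": 100}
        for ct in sorted(set(tissue.values()))
        for g in deg.genes
    ]
    return expr, NormalReference(pd.DataFrame(rows))


@dataclass
class RecoveryScores:
    """Precision/recall of driver and edge recovery against planted truth."""

    driver_precision: float
    driver_recall: float
    edge_precision: float
    edge_recall: float
    n_called_drivers: int
    n_called_edges: int


def _precision_recall(called: set, truth: set) -> tuple[float, float]:
    # empty call set: no false positives, so precision 1 by convention
    precision = len(called & truth) / len(called) if called else 1.0
    recall = len(called & truth) / len(truth) if truth else 1.0
    return precision, recall


def evaluate_recovery(
    truth: SyntheticTruth,
    summary: pd.DataFrame,
    targets: pd.DataFrame,
) -> RecoveryScores:
    """Score a run's significant SGA-FIs and their target edges.

    Driver level compares the significant-SGA-FI set against planted
    drivers; edge level compares qualifying (sga, deg) target pairs against
    planted driver→target edges.
    """
    called_drivers = set(summary.index[summary["significant"]])
    true_drivers = set(truth.drivers)
    called_edges = {(r.sga, r.deg) for r in targets.itertuples(index=False)}
    true_edges = truth.edges()
    dp, dr = _precision_recall(called_drivers, true_drivers)
    ep, er = _precision_recall(called_edges, true_edges)
    return RecoveryScores(
        driver_precision=dp,
        driver_recall=dr,
        edge_precision=ep,
        edge_recall=er,
        n_called_drivers=len(called_drivers),
        n_called_edges=len(called_edges),
    )
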