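"""Decision rules turning calibrated causal models into driver calls.

An SGA is an *SGA with functional impact* (SGA-FI) in a tumor when it is the
designated cause of at least 5 of that tumor's DEGs, each at calibrated
empirical p < 0.05. Cohort-level significance then requires the gene to be
an SGA-FI in more than 30 tumors with a call rate (calling tumors over
altered tumors) of 25% or greater. Target DEGs of a significant SGA-FI are
those it regulates in at least 50 tumors or in 20% or more of its calling
tumors; the per-target PPV is that fraction. Boundary conventions follow the
rule wording exactly: ">30" strict, "≥25%", "≥50", "≥20%", "≥5" inclusive,
"p < 0.05" strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import logging

import numpy as np
import pandas as pd

from .types import A0, BinaryEventMatrix, FormatError
from .engine import TumorCausalModel

log = logging.getLogger(__name__)


@dataclass(eq=False)
class SgaFiCall:
    """One positive SGA-FI call: a gene functionally active in one tumor."""

    tumor_id: str
    sga: str
    target_degs: list[str]

    @property
    def n_targets(self) -> int:
        return len(self.target_degs)


def call_sga_fi(
    model: TumorCausalModel,
    min_targets: int = 5,
    alpha: float = 0.05,
) -> list[SgaFiCall]:
    """SGA-FI calls for one tumor from its calibrated causal model."""
    by_cause: dict[str, list[str]] = {}
    for a in model.assignments:
        if a.cause == A0:
            continue
        if a.pvalue is None:
            raise FormatError(
                f"assignment {a.tumor_id}/{a.deg} lacks an empirical p-value; "
                "run calibration before calling"
            )
        if a.pvalue < alpha:
            by_cause.setdefault(a.cause, []).append(a.deg)
    return [
        SgaFiCall(model.tumor_id, sga, sorted(degs))
        for sga, degs in sorted(by_cause.items())
        if len(degs) >= min_targets
    ]


def call_cohort(
    models: Sequence[TumorCausalModel],
    min_targets: int = 5,
    alpha: float = 0.05,
) -> list[SgaFiCall]:
    calls: list[SgaFiCall] = []
    for model in models:
        calls.extend(call_sga_fi(model, min_targets, alpha))
    return calls


def summarize_sga_fis(
    calls: Sequence[SgaFiCall],
    sga: BinaryEventMatrix,
    min_tumors: int = 30,
    min_rate: float = 0.25,
) -> pd.DataFrame:
    """Cohort-level summary per SGA gene, indexed by gene.

    Columns: n_altered, n_called, call_rate, significant. A gene is a
    *significant* SGA-FI iff called in strictly more than ``min_tumors``
    tumors and its call rate is at least ``min_rate``.
    """
    altered = pd.Series(sga.col_sums(), index=sga.genes, dtype=int)
    called = pd.Series(0, index=sga.genes, dtype=int)
    for call in calls:
        called[call.sga] += 1
    if (called > altered).any():
        raise FormatError("SGA called in more tumors than it is altered in")
    rate = np.divide(called, altered, out=np.zeros(len(altered)), where=altered > 0)
    return pd.DataFrame(
        {
            "n_altered": altered,
            "n_called": called,
            "call_rate": rate,
            "significant": (called > min_tumors) & (rate >= min_rate),
        }
    )


def target_degs(
    calls: Sequence[SgaFiCall],
    summary: pd.DataFrame,
    min_abs: int = 50,
    min_frac: float = 0.20,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Per-SGA target DEGs with PPV.

    A DEG qualifies as a target of an SGA-FI iff the SGA is its designated,
    significant cause in at least ``min_abs`` tumors OR in at least
    ``min_frac`` of the SGA's calling tumors. PPV = count / n_called.
    Columns: sga, deg, n_tumors, ppv. Restricted to significant SGA-FIs
    unless ``significant_only=False``.
    """
    counts: dict[tuple[str, str], int] = {}
    for call in calls:
        for deg in call.target_degs:
            counts[(call.sga, deg)] = counts.get((call.sga, deg), 0) + 1
    rows = []
    for (sga, deg), n in sorted(counts.items()):
        if significant_only and not summary.at[sga, "significant"]:
            continue
        n_called = int(summary.at[sga, "n_called"])
        ppv = n / n_called if n_called else 0.0
        if n >= min_abs or ppv >= min_frac:
            rows.append((sga, deg, n, ppv))
    return pd.DataFrame(rows, columns=["sga", "deg", "n_tumors", "ppv"])


def target_sets(targets: pd.DataFrame) -> dict[str, set[str]]:
    """Collapse the target table to {sga: set of target DEGs}."""
    return {str(sga): set(grp["deg"]) for sga, grp in targets.groupby("sga")}


def conserved_edges(
    models: Sequence[TumorCausalModel],
    tissue: Mapping[str, str],
) -> set[tuple[str, str]]:
    """(SGA, DEG) pairs designated as cause in at least two cancer types."""
    types_seen: dict[tuple[str, str], set[str]] = {}
    observed_types = set()
    for model in models:
        ct = tissue[model.tumor_id]
        observed_types.add(ct)
        for a in model.assignments:
            if a.cause != A0:
                types_seen.setdefault((a.cause, a.deg), set()).add(ct)
    if len(observed_types) < 2:
        log.warning("fewer than two cancer types: conservation rule yields nothing")
        return set()
    return {edge for edge, types in types_seen.items() if len(types) >= 2}


def calls_frame(calls: Sequence[SgaFiCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.tumor_id, c.sga, c.n_targets, ",".join(c.target_degs)) for c in calls],
        columns=["tumor_id", "sga", "n_targets", "target_degs"],
    )
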