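"""Tumor-specific edge priors over candidate causes {A0} ∪ SGA_SET_t.

For a tumor t hosting m altered genes, the prior that a DEG is caused by the
non-specific factor A0 is a fixed θ0 (default 0.1); the residual mass 1−θ0
is split across the tumor's SGAs by one of four schemes:

  mutsig     θ_h ∝ μ_h with μ_h = 1 − p_h (MutSigCV p-value) — the default
             when a MutSig table is available
  uniform    θ_h = (1−θ0)/m
  frequency  θ_h ∝ f_h, the gene's cohort alteration count
  weighted   θ_h ∝ w_h = Σ_{t∈U_h} 1/m_t — frequency discounted by how many
             alterations each hosting tumor carries

Because the candidate set differs between tumors, the same gene gets a
different prior in different tumors: the prior is tumor-specific even though
its ingredients are cohort-level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import A0, BinaryEventMatrix, Cohort, MutSigTable

SCHEMES = ("mutsig", "uniform", "frequency", "weighted")

#: θ0 grid used for the A0 sensitivity analysis.
THETA0_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(eq=False)
class PriorInputs:
    """Cohort-level ingredients of the prior schemes.

    f: per-gene alteration counts; w: per-gene 1/m_t-weighted counts;
    m: per-tumor SGA counts; mutsig: optional MutSigCV p-value table.
    """

    f: pd.Series
    w: pd.Series
    m: pd.Series
    mutsig: MutSigTable | None = None


@dataclass(eq=False)
class PriorVector:
    """Prior over a tumor's candidate causes, A0 first."""

    tumor_id: str
    causes: list[str]
    theta: np.ndarray
    scheme: str
    theta0: float

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.causes[0] != A0:
            raise ValueError("causes must start with A0")
        if len(self.causes) != len(self.theta):
            raise ValueError("causes/theta length mismatch")
        if (self.theta < 0).any():
            raise ValueError("negative prior probability")
        if abs(self.theta.sum() - 1.0) > 1e-12:
            raise ValueError(f"prior does not sum to 1: {self.theta.sum()!r}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.theta, index=self.causes)


def alteration_stats(sga: BinaryEventMatrix, mutsig: MutSigTable | None = None) -> PriorInputs:
    """Compute f_h, w_h and m_t from the SGA matrix.

    w_h sums 1/m_t over the tumors altered in h; tumors with no SGAs at all
    contribute nothing (they host no alterations to weight).
    """
    values = sga.values.astype(float)
    m = values.sum(axis=1)
    f = values.sum(axis=0)
    inv_m = np.divide(1.0, m, out=np.zeros_like(m), where=m > 0)
    w = inv_m @ values
    return PriorInputs(
        f=pd.Series(f, index=sga.genes),
        w=pd.Series(w, index=sga.genes),
        m=pd.Series(m, index=sga.tumors),
        mutsig=mutsig,
    )


def compute_prior(
    tumor_id: str,
    sga_set: Sequence[str],
    scheme: str,
    inputs: PriorInputs | None = None,
    theta0: float = 0.1,
    mu_floor: float = 1e-6,
) -> PriorVector:
    """Prior vector for one tumor under one scheme.

    An empty SGA set yields the degenerate prior (1.0) on A0 alone. Under the
    mutsig scheme, μ_h = max(1 − p_h, mu_floor), so a gene with MutSigCV
    p = 1 keeps a vanishing but nonzero prior that a strong marginal
    likelihood can still overcome; genes absent from the table get p = 1.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown prior scheme: {scheme!r}")
    if not 0.0 < theta0 < 1.0:
        raise ValueError(f"theta0 must be in (0, 1): {theta0}")
    sga_set = list(sga_set)
    if not sga_set:
        return PriorVector(tumor_id, [A0], np.array([1.0]), scheme, theta0)
    m = len(sga_set)
    if scheme == "uniform":
        mass = np.full(m, 1.0 / m)
    else:
        if inputs is None:
            raise ValueError(f"scheme {scheme!r} requires cohort-level PriorInputs")
        if scheme == "mutsig":
            table = inputs.mutsig or MutSigTable({})
            mu = np.array([max(1.0 - table.get(g), mu_floor) for g in sga_set])
        elif scheme == "frequency":
            mu = inputs.f.loc[sga_set].to_numpy(dtype=float)
        else:  # weighted
            mu = inputs.w.loc[sga_set].to_numpy(dtype=float)
        total = mu.sum()
        if total <= 0:
            raise ValueError(
                f"degenerate prior for tumor {tumor_id!r}: all {scheme} masses are zero"
            )
        mass = mu / total
    theta = np.concatenate([[theta0], (1.0 - theta0) * mass])
    theta /= theta.sum()  # absorb rounding so the invariant holds exactly
    return PriorVector(tumor_id, [A0] + sga_set, theta, scheme, theta0)


def cohort_priors(
    cohort: Cohort,
    scheme: str = "uniform",
    inputs: PriorInputs | None = None,
    theta0: float = 0.1,
    mu_floor: float = 1e-6,
) -> dict[str, PriorVector]:
    """One PriorVector per tumor; candidate genes in lexicographic order."""
    if inputs is None and scheme != "uniform":
        inputs = alteration_stats(cohort.sga)
    priors = {}
    values = cohort.sga.values
    genes = np.array(cohort.sga.genes)
    for i, tumor in enumerate(cohort.tumor_ids):
        sga_set = sorted(genes[values[i] == 1])
        priors[tumor] = compute_prior(tumor, sga_set, scheme, inputs, theta0, mu_floor)
    return priors


def prior_distance(a: Mapping[str, PriorVector], b: Mapping[str, PriorVector]) -> pd.Series:
    """Per-tumor Euclidean distance of log10 fold-changes between two priors.

    d_t = sqrt(Σ_c log10(θ_a,c / θ_b,c)²) over the tumor's causes; zero iff
    the two priors are identical. Cause sets must match tumor by tumor.
    """
    if set(a) != set(b):
        raise ValueError("prior mappings cover different tumors")
    out = {}
    for tumor, pa in a.items():
        pb = b[tumor]
        if pa.causes != pb.causes:
            raise ValueError(f"cause sets differ for tumor {tumor!r}")
        logs = np.log10(pa.theta) - np.log10(pb.theta)
        out[tumor] = float(np.sqrt((logs**2).sum()))
    return pd.Series(out)


def priors_frame(priors: Mapping[str, PriorVector]) -> pd.DataFrame:
    """Long-format (tumor, cause, theta) export."""
    rows = [
        (t, c, th)
        for t, pv in priors.items()
        for c, th in zip(pv.causes, pv.theta)
    ]
    return pd.DataFrame(rows, columns=["tumor_id", "cause", "theta"])
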