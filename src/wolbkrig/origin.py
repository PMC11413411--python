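"""Candidate invasion-origin regions, haplotype concordance, and spread dynamics.

The introduced North American population carried no wCer2 (0 of 40
individuals infected). A native region is a plausible source only if its
predicted infection frequency makes that observation likely; regions
predicted (near-)fixed for wCer2 are effectively excluded. The binomial
compatibility score quantifying this is an explicit extension of the
qualitative map-reading argument and is labelled as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kriging import KrigingSurface

__all__ = [
    "OriginAssessment",
    "HaplotypeConcordance",
    "invasion_compatibility",
    "haplotype_concordance",
    "ci_spread_criterion",
]


@dataclass(frozen=True)
class OriginAssessment:
    """Compatibility of one grid cell with the invasive-range observation."""

    location: tuple[float, float]
    predicted_p: float
    compat: float
    candidate: bool


@dataclass(frozen=True)
class HaplotypeConcordance:
    """Cross-tabulation of wCer2 infection status against mtDNA haplotype.

    HT2 hitch-hikes with wCer2 through maternal co-transmission, so
    infected/HT2 and uninfected/HT1 are the concordant cells; the
    misassociation rate is the fraction of individuals in the other two.
    """

    n_scored: int
    n_wCer2_HT2: int
    n_wCer2_HT1: int
    n_uninf_HT1: int
    n_uninf_HT2: int

    @property
    def misassociation_rate(self) -> float:
        if self.n_scored == 0:
            raise ValueError("no scored individuals")
        return (self.n_wCer2_HT1 + self.n_uninf_HT2) / self.n_scored


def invasion_compatibility(
    surface: KrigingSurface,
    k_inv: int,
    n_inv: int,
    alpha: float = 0.05,
    *,
    method: str = "point-mass",
) -> list[OriginAssessment]:
    """Score every grid cell's compatibility with the invasive sample.

    ``compat`` is the exact binomial probability of the invasive
    observation (``k_inv`` infected of ``n_inv``) given the cell's
    predicted frequency: the point mass P(K = k_inv) by default, or a
    two-tailed exact binomial p-value with ``method="two-tailed"``. A
    cell is a candidate origin when compat >= alpha.
    """
    if not 0 <= k_inv <= n_inv:
        raise ValueError(f"k_inv={k_inv} outside [0, n_inv={n_inv}]")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    p = np.clip(np.asarray(surface.z_hat, float), 0.0, 1.0)
    if method == "point-mass":
        compat = stats.binom.pmf(k_inv, n_inv, p)
    elif method == "two-tailed":
        compat = np.array([stats.binomtest(k_inv, n_inv, pi).pvalue for pi in p])
    else:
        raise ValueError(f"unknown method {method!r}")
    compat = np.clip(compat, 0.0, 1.0)
    pts = surface.grid.points
    return [
        OriginAssessment(
            location=(float(la), float(lo)),
            predicted_p=float(pi),
            compat=float(ci),
            candidate=bool(ci >= alpha),
        )
        for (la, lo), pi, ci in zip(pts, p, compat)
    ]


def assessments_to_frame(assessments: list[OriginAssessment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lat": [a.location[0] for a in assessments],
            "lon": [a.location[1] for a in assessments],
            "predicted_p": [a.predicted_p for a in assessments],
            "compat": [a.compat for a in assessments],
            "candidate": [a.candidate for a in assessments],
        }
    )


def haplotype_concordance(individuals) -> HaplotypeConcordance:
    """Cross-tabulate per-individual (wCer2 status, haplotype) pairs.

    ``individuals`` yields (status, haplotype) with status in
    {"infected", "uninfected"} and haplotype in {"HT1", "HT2"}.
    """
    cells = {("infected", "HT2"): 0, ("infected", "HT1"): 0,
             ("uninfected", "HT1"): 0, ("uninfected", "HT2"): 0}
    for status, hap in individuals:
        if (status, hap) not in cells:
            raise ValueError(f"invalid (status, haplotype) pair {(status, hap)!r}")
        cells[(status, hap)] += 1
    return HaplotypeConcordance(
        n_scored=sum(cells.values()),
        n_wCer2_HT2=cells[("infected", "HT2")],
        n_wCer2_HT1=cells[("infected", "HT1")],
        n_uninf_HT1=cells[("uninfected", "HT1")],
        n_uninf_HT2=cells[("uninfected", "HT2")],
    )


def ci_spread_criterion(F: float, mu: float) -> str:
    """Deterministic spread condition for a maternally inherited symbiont.

    With relative fecundity F of infected females and maternal
    transmission failure mu, a strain increases from rarity iff
    F (1 - mu) > 1 ("spreads_from_rare"); otherwise local dynamics are
    bistable and a rare infection is lost ("bistable"). The boundary
    F (1 - mu) = 1 classifies as bistable (strict inequality).
    """
    if F < 0:
        raise ValueError("F must be >= 0")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")
    return "spreads_from_rare" if F * (1.0 - mu) > 1.0 else "bistable"
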