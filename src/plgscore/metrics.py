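"""Evaluation metrics for pose scoring and virtual screening.

Covers the standard benchmark quantities: top-N docking success rates at
an RMSD cutoff, Pearson/Spearman correlations, enrichment factors,
screening success rates and per-target binding-funnel rank correlations.

Score orientation is explicit everywhere: RMSD-like scores rank
ascending (lower is better), affinity-like scores descending.  Ties are
broken by stable input order, which is documented because success rates
can differ under ties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PoseRecord",
    "DecoySet",
    "delta_g_from_pkd",
    "correlations",
    "top_n_success_rate",
    "enrichment_factor",
    "screening_success_rate",
    "funnel_analysis",
    "GAS_CONSTANT_CAL",
]

#: Gas constant in cal / (mol K)
GAS_CONSTANT_CAL = 1.9858


@dataclass(frozen=True)
class PoseRecord:
    pose_id: str
    score: float
    rmsd_real: float | None = None
    is_binder: bool = False


@dataclass
class DecoySet:
    """Scored poses (or screened compounds) for one target.

    ``lower_is_better`` states the score orientation: True for RMSD-like
    scores, False for affinity-like scores.
    """

    target_id: str
    poses: list[PoseRecord] = field(default_factory=list)
    lower_is_better: bool = True

    def ranked(self) -> list[PoseRecord]:
        key = (lambda p: p.score) if self.lower_is_better else (lambda p: -p.score)
        return sorted(self.poses, key=key)  # stable: input order breaks ties


def delta_g_from_pkd(
    pkd: float, temperature: float = 298.15, gas_constant_cal: float = GAS_CONSTANT_CAL
) -> float:
    """Binding free energy in kcal/mol from pKd: dG = -(R T ln 10) pKd.

    At T = 298.15 K with R = 1.9858 cal/(mol K) the factor is
    -1.3633 kcal/mol per pKd unit.
    """
    return -(gas_constant_cal * temperature * math.log(10.0)) * pkd / 1000.0


def correlations(x, y) -> tuple[float, float]:
    """(Pearson, Spearman) correlation; Spearman uses mid-ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("correlations need two equal-length vectors of size >= 3")
    pcc = float(stats.pearsonr(x, y).statistic)
    scc = float(stats.spearmanr(x, y).statistic)
    return pcc, scc


def top_n_success_rate(
    decoy_sets: list[DecoySet], n: int = 1, rmsd_cutoff: float = 2.0
) -> float:
    """Fraction of targets whose n best-scored poses include one with
    rmsd_real below the cutoff (strict <)."""
    used = 0
    hits = 0
    for ds in decoy_sets:
        if not ds.poses:
            logger.warning("decoy set %s is empty; excluded", ds.target_id)
            continue
        used += 1
        top = ds.ranked()[:n]
        if any(p.rmsd_real is not None and p.rmsd_real < rmsd_cutoff for p in top):
            hits += 1
    if used == 0:
        raise ValueError("no non-empty decoy sets")
    return hits / used


def enrichment_factor(decoy_set: DecoySet, fraction: float) -> float:
    """EF at a screening fraction: (binder recall in the top fraction) / fraction.

    With N candidates the top ``ceil(fraction * N)`` are inspected; a
    uniformly random ranking gives EF ~= 1.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    ranked = decoy_set.ranked()
    n_total = len(ranked)
    n_binders = sum(p.is_binder for p in ranked)
    if n_binders == 0:
        raise ValueError(f"{decoy_set.target_id}: no binders in the set")
    n_top = math.ceil(fraction * n_total)
    found = sum(p.is_binder for p in ranked[:n_top])
    return (found / n_binders) / fraction


def screening_success_rate(decoy_sets: list[DecoySet], fraction: float) -> float:
    """Fraction of targets where the known best binder appears in the top
    ``ceil(fraction * N)`` ranked candidates.

    The best binder of a target is its pose/compound flagged
    ``is_binder`` (the highest-affinity ligand in a screening deck).
    """
    used = 0
    hits = 0
    for ds in decoy_sets:
        if not ds.poses or not any(p.is_binder for p in ds.poses):
            logger.warning("decoy set %s unusable for screening; excluded", ds.target_id)
            continue
        used += 1
        n_top = math.ceil(fraction * len(ds.poses))
        if any(p.is_binder for p in ds.ranked()[:n_top]):
            hits += 1
    if used == 0:
        raise ValueError("no usable decoy sets")
    return hits / used


def funnel_analysis(
    decoy_sets: list[DecoySet],
    rmsd_bins: list[tuple[float, float]],
    min_count: int = 3,
) -> pd.DataFrame:
    """Mean per-target Spearman correlation between score and true RMSD
    within RMSD intervals ``[lo, hi)``.

    Bins holding fewer than `min_count` poses for a target are excluded
    from that target's contribution; the report carries the counts.
    """
    rows = []
    for lo, hi in rmsd_bins:
        sccs = []
        excluded = 0
        for ds in decoy_sets:
            sel = [
                p
                for p in ds.poses
                if p.rmsd_real is not None and lo <= p.rmsd_real < hi
            ]
            if len(sel) < min_count:
                excluded += 1
                continue
            scores = [p.score for p in sel]
            rmsds = [p.rmsd_real for p in sel]
            if len(set(scores)) == 1 or len(set(rmsds)) == 1:
                excluded += 1
                continue
            sccs.append(float(stats.spearmanr(scores, rmsds).statistic))
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "mean_scc": float(np.mean(sccs)) if sccs else float("nan"),
                "n_targets": len(sccs),
                "n_excluded": excluded,
            }
        )
    return pd.DataFrame(rows)
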