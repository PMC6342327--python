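"""Evaluation of drug rankings against known longevity labels.

A ranking is good if drugs already shown to extend (or shorten) lifespan
in model organisms concentrate near its top.  The cumulative enrichment
curve plots the fraction of labelled drugs recovered (y) against the
fraction of the ranked list scanned (x, rank scaled to [0, 1]); its
trapezoid AUC is 0.5 under random ordering.  Significance comes from the
permutation ensemble built for the bias analysis: the p-value is the
fraction of null rankings whose AUC is at least the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom, kendalltau

from .association import LevelRanking
from .bias import NullRankingEnsemble

__all__ = [
    "EnrichmentCurve",
    "enrichment_curve",
    "curve_auc",
    "auc_pvalue",
    "top_k_overlap",
    "concordance",
    "kendalls_w",
    "significant_overlap_test",
]


@dataclass
class EnrichmentCurve:
    """Cumulative label-recovery curve with its trapezoid AUC."""

    x: np.ndarray  # fraction of drugs considered, starts at 0
    y: np.ndarray  # fraction of labelled drugs recovered
    auc: float
    n_drugs: int
    n_labelled: int


def _labelled_mask(
    ordered_drugs: Sequence[str], labels: Mapping[str, str], which: str
) -> np.ndarray:
    if which not in ("pro", "anti"):
        raise ValueError("label must be 'pro' or 'anti'")
    return np.array([labels.get(d) == which for d in ordered_drugs])


def _curve_from_mask(mask: np.ndarray) -> EnrichmentCurve:
    n = mask.size
    n_lab = int(mask.sum())
    if n_lab == 0:
        raise ValueError("no labelled drug in the ranking")
    x = np.arange(0, n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(mask) / n_lab])
    auc = float(np.trapezoid(y, x))
    return EnrichmentCurve(x, y, auc, n, n_lab)


def enrichment_curve(
    ranking: LevelRanking | Sequence[str],
    labels: Mapping[str, str],
    which: str = "pro",
) -> EnrichmentCurve:
    """Cumulative recovery of ``which``-labelled drugs along the ranking.

    Rank i maps to x = i/N; y(x) is the fraction of the ranking's labelled
    drugs found in the top i.  The curve starts at (0, 0) and ends at
    (1, 1).  Drugs without a label count as unlabelled negatives.
    """
    drugs = ranking.drugs if isinstance(ranking, LevelRanking) else list(ranking)
    return _curve_from_mask(_labelled_mask(drugs, labels, which))


def curve_auc(curve: EnrichmentCurve) -> float:
    """Trapezoid area under the enrichment curve (0.5 = chance)."""
    return curve.auc


def auc_pvalue(
    observed: float,
    ensemble: NullRankingEnsemble,
    labels: Mapping[str, str],
    which: str = "pro",
) -> float:
    """Permutation p: fraction of null rankings with AUC >= observed.

    Zero means no null replicate reached the observed AUC and should be
    reported as "< 1/n_reps".
    """
    if ensemble.n_reps == 0:
        raise ValueError("empty ensemble")
    null_aucs = np.array(
        [
            _curve_from_mask(_labelled_mask(r, labels, which)).auc
            for r in ensemble.rankings
        ]
    )
    return float(np.mean(null_aucs >= observed))


def top_k_overlap(
    ranking: LevelRanking | Sequence[str],
    labels: Mapping[str, str],
    which: str = "pro",
    k: int = 20,
) -> tuple[int, float]:
    """Count and fraction of labelled drugs among the top k."""
    drugs = ranking.drugs if isinstance(ranking, LevelRanking) else list(ranking)
    if k > len(drugs):
        raise ValueError("k exceeds the ranking length")
    count = int(_labelled_mask(drugs[:k], labels, which).sum())
    return count, count / k


def kendalls_w(rank_matrix: np.ndarray) -> float:
    """Kendall's coefficient of concordance W, corrected for ties.

    ``rank_matrix`` has one row per ranked list (judge) and one column per
    drug; entries are 1-based ranks.  W = 1 means all lists agree exactly,
    0 means no agreement.
    """
    r = np.asarray(rank_matrix, dtype=float)
    m, n = r.shape
    if m < 2 or n < 2:
        raise ValueError("need >=2 rankings of >=2 items")
    totals = r.sum(axis=0)
    s = float(np.sum((totals - totals.mean()) ** 2))
    ties = 0.0
    for row in r:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:
        raise ValueError("degenerate rankings (all items tied)")
    return 12.0 * s / denom


def concordance(
    rankings: Sequence[LevelRanking],
) -> tuple[np.ndarray, float]:
    """Agreement between per-level rankings on their common drugs.

    Returns the pairwise Kendall tau-b matrix and Kendall's W (tie
    corrected) across all lists, both computed on the drugs present in
    every ranking.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    common: set[str] | None = None
    for r in rankings:
        common = set(r.drugs) if common is None else common & set(r.drugs)
    assert common is not None
    if len(common) < 2:
        raise ValueError("fewer than two drugs shared by all rankings")
    drugs = sorted(common)
    # re-rank within the common set, preserving each list's order
    mat = np.empty((len(rankings), len(drugs)))
    for i, r in enumerate(rankings):
        order = [d for d in r.drugs if d in common]
        pos = {d: j + 1 for j, d in enumerate(order)}
        mat[i] = [pos[d] for d in drugs]
    k = len(rankings)
    tau = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            tau[i, j] = tau[j, i] = kendalltau(mat[i], mat[j]).statistic
    return tau, kendalls_w(mat)


def significant_overlap_test(
    significant: set[str],
    labels: Mapping[str, str],
    which: str = "pro",
    universe_size: int | None = None,
    labelled_in_universe: int | None = None,
) -> tuple[float, float]:
    """Hypergeometric test of label overlap among significant drugs.

    With N drugs tested, K of them labelled and s called significant, the
    expected labelled count among the significant drugs under the null is
    s*K/N and the p-value is the upper hypergeometric tail
    P(overlap >= observed).  Returns (expected, p).
    """
    if universe_size is None:
        raise ValueError("universe_size is required")
    K = (
        labelled_in_universe
        if labelled_in_universe is not None
        else sum(1 for v in labels.values() if v == which)
    )
    s = len(significant)
    if s > universe_size or K > universe_size:
        raise ValueError("counts exceed the universe size")
    observed = sum(1 for d in significant if labels.get(d) == which)
    expected = s * K / universe_size
    p = float(hypergeom.sf(observed - 1, universe_size, K, s))
    return expected, min(1.0, p)
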