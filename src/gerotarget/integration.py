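"""Integration of per-level rankings into one candidate list.

The seven level rankings (gene, PPI, GO:BP/CC/MF, KEGG, Reactome) capture
different tiers of a drug's action and only agree moderately; averaging a
drug's rank across lists rewards drugs consistently near the top at every
tier.  A cutoff-sensitivity sweep reruns the whole pipeline over a grid of
the upstream thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .association import LevelRanking

__all__ = ["CombinedRanking", "combine_rankings", "cutoff_sweep"]


@dataclass
class CombinedRanking:
    """Drugs ordered by their average rank across levels."""

    levels: list[str]
    policy: str
    table: pd.DataFrame  # columns: drug, <level ranks...>, avg_rank, final_rank

    def ranks(self) -> dict[str, int]:
        return dict(zip(self.table["drug"], self.table["final_rank"]))


def combine_rankings(
    rankings: Sequence[LevelRanking], policy: str = "intersect"
) -> CombinedRanking:
    """Average each drug's rank over the per-level lists.

    ``intersect`` keeps only drugs present in every list (the average is
    then over all levels); ``penalize_max`` keeps every drug seen anywhere
    and charges a missing level its list length + 1.  The output is sorted
    by ascending average rank, ties broken by drug id, with consecutive
    final ranks from 1.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    if policy not in ("intersect", "penalize_max"):
        raise ValueError(f"unknown policy {policy!r}")
    levels = [r.level for r in rankings]
    per_level = [r.ranks() for r in rankings]
    if policy == "intersect":
        drugs: set[str] | None = None
        for ranks in per_level:
            drugs = set(ranks) if drugs is None else drugs & set(ranks)
        assert drugs is not None
        if not drugs:
            raise ValueError(
                "no drug appears in every ranking; use policy='penalize_max'"
            )
    else:
        drugs = set()
        for ranks in per_level:
            drugs |= set(ranks)
    rows = []
    for drug in sorted(drugs):
        vals = []
        for r, ranks in zip(rankings, per_level):
            vals.append(ranks.get(drug, len(r) + 1))
        rows.append(
            {"drug": drug, **dict(zip(levels, vals)),
             "avg_rank": sum(vals) / len(vals)}
        )
    df = pd.DataFrame(rows).sort_values(
        ["avg_rank", "drug"], kind="stable", ignore_index=True
    )
    df["final_rank"] = range(1, len(df) + 1)
    return CombinedRanking(levels, policy, df)


def average_ranks(ranks: Sequence[int]) -> float:
    """Arithmetic mean of per-level ranks, full precision.

    Reports round this to 2 decimals; internal ordering uses the exact
    value.
    """
    if not ranks:
        raise ValueError("empty rank list")
    return sum(ranks) / len(ranks)


def cutoff_sweep(
    run,
    grid: Mapping[str, Sequence],
) -> pd.DataFrame:
    """Re-run a pipeline callable over a Cartesian grid of cutoffs.

    ``run`` is called once per grid point with the point's keyword
    arguments (e.g. ``interaction_min_score``, ``ppi_min_score``,
    ``ora_alpha``) and must return a flat mapping of metric name to value;
    the result has one row per point with the grid values as columns.
    Deterministic whenever ``run`` is.
    """
    if not grid:
        raise ValueError("empty grid")
    keys = sorted(grid)
    for key in keys:
        if not len(grid[key]):
            raise ValueError(f"empty value list for grid key {key!r}")
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, combo))
        metrics = run(**point)
        bad = set(point) & set(metrics)
        if bad:
            raise ValueError(f"metric names collide with grid keys: {bad}")
        rows.append({**point, **metrics})
    return pd.DataFrame(rows)
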