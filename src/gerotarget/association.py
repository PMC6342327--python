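"""Per-drug, per-level association statistics and ranking.

For one biological level, each drug contributes a 2x2 contingency table
over the level's term universe (all terms hit by at least one drug):

======================  =======================  ====================
                        ageing-related           not ageing-related
======================  =======================  ====================
drug-related            k                        l
not drug-related        m                        n
======================  =======================  ====================

The drug's p-value is a Fisher exact test on this table, its effect size
the conditional-MLE odds ratio, and the family of tests at the level is
Benjamini-Yekutieli corrected.  Drugs are ranked by ascending p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .stats import (
    adjust_by,
    conditional_mle_odds_ratio,
    fisher_exact,
    sample_odds_ratio,
)

__all__ = [
    "ContingencyTable",
    "DrugAssociation",
    "LevelRanking",
    "build_contingency",
    "rank_level",
]

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class ContingencyTable:
    """The k/l/m/n 2x2 of one drug at one level (see module docstring)."""

    k: int
    l: int
    m: int
    n: int

    def __post_init__(self) -> None:
        if min(self.k, self.l, self.m, self.n) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.k + self.l + self.m + self.n

    def as_cells(self) -> tuple[int, int, int, int]:
        return self.k, self.l, self.m, self.n


@dataclass(frozen=True)
class DrugAssociation:
    """One ranked row: a drug's table, test results and rank at a level."""

    drug: str
    level: str
    table: ContingencyTable
    odds_ratio: float  # conditional MLE; may be +inf
    odds_ratio_sample: float
    p: float
    adjusted_p: float
    rank: int
    significant: bool


@dataclass
class LevelRanking:
    """All drug associations at one level, sorted by ascending p."""

    level: str
    associations: list[DrugAssociation]
    m_tests: int

    def __len__(self) -> int:
        return len(self.associations)

    @property
    def drugs(self) -> list[str]:
        return [a.drug for a in self.associations]

    def ranks(self) -> dict[str, int]:
        return {a.drug: a.rank for a in self.associations}

    def significant_drugs(self) -> set[str]:
        return {a.drug for a in self.associations if a.significant}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": [a.drug for a in self.associations],
                "k": [a.table.k for a in self.associations],
                "l": [a.table.l for a in self.associations],
                "m": [a.table.m for a in self.associations],
                "n": [a.table.n for a in self.associations],
                "OR_cmle": [a.odds_ratio for a in self.associations],
                "OR_sample": [a.odds_ratio_sample for a in self.associations],
                "p": [a.p for a in self.associations],
                "adj_p": [a.adjusted_p for a in self.associations],
                "rank": [a.rank for a in self.associations],
                "significant": [a.significant for a in self.associations],
            }
        )


def build_contingency(
    drug_terms: frozenset[str] | set[str],
    ageing_terms: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
) -> ContingencyTable:
    """Count the 2x2 overlap of a drug's terms with the ageing terms.

    The ageing set is intersected with the universe before counting; the
    drug's terms must already lie inside the universe (the universe is the
    union of all drugs' terms, so this holds by construction).
    """
    drug_terms = set(drug_terms)
    if not drug_terms <= set(universe):
        raise ValueError("drug terms outside the universe")
    ageing = set(ageing_terms) & set(universe)
    k = len(drug_terms & ageing)
    l = len(drug_terms) - k
    m = len(ageing) - k
    n = len(universe) - k - l - m
    return ContingencyTable(k, l, m, n)


def _sort_key(a: DrugAssociation) -> tuple:
    # ascending p, ties by descending OR (inf first), then drug id
    or_ = a.odds_ratio if not math.isnan(a.odds_ratio) else a.odds_ratio_sample
    if math.isnan(or_):
        or_ = 1.0
    return (a.p, -or_ if math.isfinite(or_) else -math.inf, a.drug)


def rank_level(
    profiles: Mapping[str, frozenset[str]],
    ageing_terms: frozenset[str] | set[str],
    universe: frozenset[str] | set[str] | None = None,
    level: str = "gene",
    sidedness: str = "greater",
    alpha: float = ALPHA_DEFAULT,
    min_terms: int = 1,
    compute_or: bool = True,
) -> LevelRanking:
    """Test and rank every drug at one level.

    ``profiles`` maps each drug to its term set; the universe defaults to
    the union of all profiles.  Drugs with fewer than ``min_terms`` terms
    in the universe are not tested.  P-values are BY-adjusted across all
    tested drugs and the significance flag is ``adjusted_p < alpha``.
    ``compute_or=False`` skips the conditional-MLE root-finding (the rank
    order then breaks p ties by the sample odds ratio instead), which
    speeds up permutation re-runs where only the order matters.
    """
    if not profiles:
        raise ValueError("no drug profiles to rank")
    if universe is None:
        uni: set[str] = set()
        for terms in profiles.values():
            uni |= terms
    else:
        uni = set(universe)
    tested = {
        drug: set(terms) & uni
        for drug, terms in profiles.items()
        if len(set(terms) & uni) >= min_terms
    }
    if not tested:
        raise ValueError("no drug has terms inside the universe")
    rows = []
    for drug in sorted(tested):
        t = build_contingency(tested[drug], ageing_terms, uni)
        p = fisher_exact(*t.as_cells(), sidedness=sidedness)
        rows.append((drug, t, p))
    adjusted = adjust_by([r[2] for r in rows])
    assoc = [
        DrugAssociation(
            drug=drug,
            level=level,
            table=t,
            odds_ratio=(
                conditional_mle_odds_ratio(*t.as_cells())
                if compute_or
                else math.nan
            ),
            odds_ratio_sample=sample_odds_ratio(*t.as_cells()),
            p=p,
            adjusted_p=adj,
            rank=0,
            significant=adj < alpha,
        )
        for (drug, t, p), adj in zip(rows, adjusted)
    ]
    assoc.sort(key=_sort_key)
    assoc = [
        DrugAssociation(
            a.drug, a.level, a.table, a.odds_ratio, a.odds_ratio_sample,
            a.p, a.adjusted_p, i, a.significant,
        )
        for i, a in enumerate(assoc, start=1)
    ]
    return LevelRanking(level, assoc, m_tests=len(assoc))
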