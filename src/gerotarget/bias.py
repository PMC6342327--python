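"""Research-bias assessment by permutation of the ageing term set.

Heavily studied drugs have more recorded targets and so hit more terms at
every level; they could rank high against *any* gene set, not specifically
the ageing one.  To measure this, the ageing-related term set is replaced
by random term sets of the same size drawn from the level universe, the
full ranking is recomputed for each draw, and each drug's observed rank is
compared with its null rank distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .association import rank_level

__all__ = ["NullRankingEnsemble", "null_rankings", "bias_fraction"]


@dataclass
class NullRankingEnsemble:
    """Per-replicate drug rankings against random term sets."""

    level: str
    n_reps: int
    seed: int
    n_terms: int
    #: per replicate, drug ids ordered by ascending p (rank 1 first)
    rankings: list[list[str]]

    def null_ranks(self, drug: str) -> np.ndarray:
        """The drug's rank in every replicate (absent -> length + 1)."""
        out = np.empty(self.n_reps, dtype=float)
        for i, ranking in enumerate(self.rankings):
            try:
                out[i] = ranking.index(drug) + 1
            except ValueError:
                out[i] = len(ranking) + 1
        return out


def null_rankings(
    profiles: Mapping[str, frozenset[str]],
    universe: frozenset[str] | set[str],
    n_terms: int,
    n_reps: int = 1000,
    seed: int = 0,
    level: str = "gene",
    sidedness: str = "greater",
) -> NullRankingEnsemble:
    """Re-rank all drugs against ``n_reps`` random term sets.

    Each replicate draws ``n_terms`` terms uniformly without replacement
    from the level universe and reruns the full ranking.  A master seed
    spawns one substream per replicate, so results are reproducible and
    replicates are independent.
    """
    uni = sorted(universe)
    if n_terms > len(uni):
        raise ValueError("n_terms exceeds the universe size")
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    rankings = []
    uni_arr = np.array(uni, dtype=object)
    for ss in streams:
        rng = np.random.default_rng(ss)
        draw = frozenset(rng.choice(uni_arr, size=n_terms, replace=False))
        ranking = rank_level(
            profiles,
            draw,
            universe=frozenset(uni),
            level=level,
            sidedness=sidedness,
            compute_or=False,
        )
        rankings.append(ranking.drugs)
    return NullRankingEnsemble(level, n_reps, seed, n_terms, rankings)


def bias_fraction(
    drug: str, observed_rank: int, ensemble: NullRankingEnsemble
) -> float:
    """Fraction of null replicates ranking the drug as well or better.

    A small fraction means the drug's observed rank is specific to the
    ageing term set; a large one flags a drug that ranks high against
    random term sets too (research bias).  Zero should be read as
    "< 1/n_reps".
    """
    if ensemble.n_reps == 0:
        raise ValueError("empty ensemble")
    ranks = ensemble.null_ranks(drug)
    return float(np.mean(ranks <= observed_rank))


def bias_report(
    ranking_ranks: Mapping[str, int],
    ensemble: NullRankingEnsemble,
    drugs: list[str] | None = None,
) -> pd.DataFrame:
    """Bias fractions for the given drugs (default: all ranked drugs)."""
    if drugs is None:
        drugs = sorted(ranking_ranks)
    rows = [
        {
            "drug": d,
            "level": ensemble.level,
            "observed_rank": ranking_ranks[d],
            "bias_fraction": bias_fraction(d, ranking_ranks[d], ensemble),
            "n_reps": ensemble.n_reps,
            "seed": ensemble.seed,
        }
        for d in drugs
    ]
    return pd.DataFrame(rows)
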