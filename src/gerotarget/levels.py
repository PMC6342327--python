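"""Expansion of gene sets into terms at each biological level.

A drug acts through its protein targets, but its physiological effect is
mediated by the pathways, functions and interaction neighbourhoods those
targets belong to.  Each *level* therefore re-expresses a gene set as a set
of *terms*:

* ``gene`` — the identity level: every gene is its own term;
* ``ppi`` — first neighbours in a protein-protein interaction network at
  high confidence (score >= 900, i.e. 0.9);
* ``go_bp`` / ``go_cc`` / ``go_mf`` / ``kegg`` / ``reactome`` — annotation
  levels given as GMT gene sets.

On the ageing side the expansion is an over-representation analysis (ORA)
with Benjamini-Yekutieli control; on the drug side a target hits every term
that contains it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom

from .io_ingest import FormatError, GeneSet, read_gene_sets
from .stats import adjust_by

logger = logging.getLogger(__name__)

__all__ = [
    "LEVELS",
    "ANNOTATION_LEVELS",
    "AnnotationLevel",
    "EnrichedTerm",
    "PPINetwork",
    "read_ppi",
    "ora_enrich",
    "ppi_interactors",
    "drug_related_terms",
    "level_universe",
]

#: Annotation levels backed by GMT gene-set files.
ANNOTATION_LEVELS = ("go_bp", "go_cc", "go_mf", "kegg", "reactome")
#: All seven biological levels of the analysis.
LEVELS = ("gene", "ppi") + ANNOTATION_LEVELS


@dataclass
class AnnotationLevel:
    """Named gene sets (terms) for one biological level."""

    name: str
    terms: dict[str, GeneSet]

    @property
    def annotated_universe(self) -> frozenset[str]:
        """All genes annotated to at least one term."""
        out: set[str] = set()
        for gs in self.terms.values():
            out |= gs.genes
        return frozenset(out)

    @classmethod
    def from_gmt(cls, name: str, path: str | Path) -> "AnnotationLevel":
        return cls(name, read_gene_sets(path))


@dataclass(frozen=True)
class EnrichedTerm:
    """One ORA result row: overlap x of a size-q query with a size-t term
    drawn from a size-U universe, with its hypergeometric tail p."""

    term_id: str
    overlap: int
    term_size: int
    query_size: int
    universe_size: int
    p: float
    adjusted_p: float


@dataclass
class PPINetwork:
    """Undirected protein-protein interaction graph with 0-1000 scores."""

    #: adjacency: protein -> {neighbour: score}; kept symmetric, no loops
    adjacency: dict[str, dict[str, int]] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, score: int) -> None:
        if a == b:
            return
        if not 0 <= score <= 1000:
            raise ValueError(f"edge score {score} outside [0, 1000]")
        cur = self.adjacency.setdefault(a, {}).get(b, -1)
        if score > cur:
            self.adjacency.setdefault(a, {})[b] = score
            self.adjacency.setdefault(b, {})[a] = score

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.adjacency.values()) // 2

    def edges(self) -> list[tuple[str, str, int]]:
        seen = []
        for a, nbrs in self.adjacency.items():
            for b, s in nbrs.items():
                if a < b:
                    seen.append((a, b, s))
        return sorted(seen)


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a STRING-links dialect TSV (protein1, protein2, combined_score)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"protein1", "protein2", "combined_score"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    net = PPINetwork()
    for i, (a, b, s) in enumerate(
        zip(df["protein1"], df["protein2"], df["combined_score"]), start=1
    ):
        try:
            score = int(s)
        except ValueError:
            raise FormatError(f"{path} row {i}: non-integer score {s!r}") from None
        if not a or not b:
            raise FormatError(f"{path} row {i}: empty protein id")
        net.add_edge(a, b, score)
    return net


def write_ppi(net: PPINetwork, path: str | Path) -> None:
    pd.DataFrame(
        net.edges(), columns=["protein1", "protein2", "combined_score"]
    ).to_csv(path, sep="\t", index=False)


def ora_enrich(
    query: GeneSet,
    level: AnnotationLevel,
    universe: GeneSet | None = None,
    alpha: float = 0.05,
    cap: int | None = None,
) -> list[EnrichedTerm]:
    """Over-representation analysis of ``query`` against a level's terms.

    For each term the overlap ``x = |query ∩ term ∩ universe|`` is scored by
    the upper-tail hypergeometric probability ``P(X >= x | U, t, q)``;
    p-values are Benjamini-Yekutieli adjusted across all terms of the level,
    and terms with adjusted p <= ``alpha`` are returned sorted by ascending
    adjusted p (ties by raw p, then term id), truncated to ``cap`` if given.

    The default universe is the level's annotated universe (all genes in at
    least one term); query genes outside it are dropped with a warning.
    """
    if universe is None:
        uni = set(level.annotated_universe)
    else:
        uni = set(universe.genes)
    if not uni:
        raise ValueError("empty universe")
    q_genes = set(query.genes) & uni
    dropped = len(query.genes) - len(q_genes)
    if dropped:
        warnings.warn(
            f"{dropped} query genes outside the universe were dropped",
            stacklevel=2,
        )
    if not q_genes:
        raise ValueError("empty query after intersecting with universe")

    U, q = len(uni), len(q_genes)
    rows = []
    for term_id in sorted(level.terms):
        term_genes = level.terms[term_id].genes & uni
        t = len(term_genes)
        if t == 0:
            continue
        x = len(q_genes & term_genes)
        # upper tail P(X >= x); sf(x-1) is exact for integer support
        p = float(hypergeom.sf(x - 1, U, t, q))
        rows.append((term_id, x, t, p))
    adjusted = adjust_by([r[3] for r in rows])
    enriched = [
        EnrichedTerm(term_id, x, t, q, U, p, adj)
        for (term_id, x, t, p), adj in zip(rows, adjusted)
        if adj <= alpha
    ]
    enriched.sort(key=lambda e: (e.adjusted_p, e.p, e.term_id))
    if cap is not None and len(enriched) > cap:
        logger.info(
            "level %s: %d enriched terms capped to %d",
            level.name,
            len(enriched),
            cap,
        )
        enriched = enriched[:cap]
    return enriched


def ppi_interactors(
    genes: GeneSet, net: PPINetwork, min_score: int = 900
) -> frozenset[str]:
    """First neighbours of ``genes`` at confidence >= ``min_score``.

    Members of ``genes`` are excluded from their own interactor set, so the
    result is the strict one-hop neighbourhood.
    """
    out: set[str] = set()
    for g in genes.genes:
        for nb, score in net.adjacency.get(g, {}).items():
            if score >= min_score:
                out.add(nb)
    return frozenset(out - set(genes.genes))


def drug_related_terms(
    targets: GeneSet,
    level: AnnotationLevel | None = None,
    *,
    level_name: str = "annotation",
    net: PPINetwork | None = None,
    ppi_min_score: int = 900,
) -> frozenset[str]:
    """Map a drug's target set to the terms it touches at one level.

    At the gene level the mapping is the identity (targets are terms); at
    the PPI level it is the target neighbourhood; at annotation levels a
    target hits every term whose gene set contains it.
    """
    if level_name == "gene":
        return frozenset(targets.genes)
    if level_name == "ppi":
        if net is None:
            raise ValueError("ppi level requires a network")
        return ppi_interactors(targets, net, min_score=ppi_min_score)
    if level is None:
        raise ValueError("annotation level requires term definitions")
    hit = set()
    for term_id, gs in level.terms.items():
        if targets.genes & gs.genes:
            hit.add(term_id)
    return frozenset(hit)


def level_universe(
    profiles: Mapping[str, frozenset[str]]
) -> frozenset[str]:
    """The sampling frame: all terms associated with at least one drug."""
    out: set[str] = set()
    for terms in profiles.values():
        out |= terms
    return frozenset(out)
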