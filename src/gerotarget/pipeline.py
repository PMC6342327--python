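"""End-to-end orchestration: study bundle in, ranked candidate list out.

Ties the modules together in the order of the analysis: ingest and filter
the interaction table, derive the ageing-related and drug-related term
sets at each biological level, rank the drugs per level by the exact test,
evaluate against longevity labels, and average the per-level ranks into
one combined list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import io_ingest
from .association import LevelRanking, rank_level
from .evaluation import concordance, enrichment_curve, top_k_overlap
from .integration import CombinedRanking, combine_rankings
from .io_ingest import GeneSet
from .levels import (
    ANNOTATION_LEVELS,
    AnnotationLevel,
    PPINetwork,
    drug_related_terms,
    level_universe,
    ora_enrich,
    ppi_interactors,
    read_ppi,
)

__all__ = ["PipelineConfig", "StudyInputs", "PipelineResult", "run_study"]


@dataclass
class PipelineConfig:
    """All tunable cutoffs of the analysis, at their study defaults."""

    interaction_min_score: int = 700  # STITCH high-confidence (0.7)
    ppi_min_score: int = 900  # STRING highest-confidence (0.9)
    ora_alpha: float = 0.05
    bp_cap: int | None = 500  # top-terms cap, GO:BP only
    min_categories: int = 2  # ageing-gene evidence filter
    sidedness: str = "greater"
    alpha: float = 0.05
    policy: str = "intersect"
    top_k: int = 20


@dataclass
class StudyInputs:
    """In-memory study: filtered profiles plus the side tables."""

    profiles: dict[str, GeneSet]  # drug -> target set
    ageing: GeneSet
    annotations: dict[str, AnnotationLevel]
    ppi: PPINetwork
    labels: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineResult:
    rankings: dict[str, LevelRanking]
    ageing_terms: dict[str, frozenset[str]]
    combined: CombinedRanking
    evaluation: dict[str, dict[str, float]]
    concordance_w: float | None


def load_study(
    bundle_dir: str | Path, config: PipelineConfig | None = None
) -> StudyInputs:
    """Read a study bundle (as written by the synthetic generator) and
    apply the ingest filters."""
    config = config or PipelineConfig()
    d = Path(bundle_dir)
    table = io_ingest.read_interactions(d / "interactions.tsv")
    id_map_path = d / "id_map.tsv"
    if id_map_path.exists():
        table = io_ingest.map_drug_ids(table, io_ingest.read_id_map(id_map_path))
    table = io_ingest.filter_interactions(
        table, min_score=config.interaction_min_score
    )
    profiles = io_ingest.drug_target_profiles(table)
    ageing = io_ingest.read_ageing_genes(
        d / "ageing_genes.tsv", min_categories=config.min_categories
    )
    annotations = {
        name: AnnotationLevel.from_gmt(name, d / f"{name}.gmt")
        for name in ANNOTATION_LEVELS
        if (d / f"{name}.gmt").exists()
    }
    ppi = read_ppi(d / "ppi.tsv") if (d / "ppi.tsv").exists() else PPINetwork()
    labels_path = d / "labels.tsv"
    labels = io_ingest.read_labels(labels_path) if labels_path.exists() else {}
    return StudyInputs(profiles, ageing, annotations, ppi, labels)


def ageing_terms_at_level(
    inputs: StudyInputs, level_name: str, config: PipelineConfig
) -> frozenset[str]:
    """The ageing-related term set at one level.

    Genes map to themselves at the gene level, to their high-confidence
    network neighbours at the PPI level, and to ORA-enriched terms
    (BY-adjusted p <= alpha; GO:BP capped) at annotation levels.
    """
    if level_name == "gene":
        return frozenset(inputs.ageing.genes)
    if level_name == "ppi":
        return ppi_interactors(
            inputs.ageing, inputs.ppi, min_score=config.ppi_min_score
        )
    level = inputs.annotations[level_name]
    cap = config.bp_cap if level_name == "go_bp" else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # query genes outside annotation
        enriched = ora_enrich(
            inputs.ageing, level, alpha=config.ora_alpha, cap=cap
        )
    return frozenset(e.term_id for e in enriched)


def drug_terms_at_level(
    inputs: StudyInputs, level_name: str, config: PipelineConfig
) -> dict[str, frozenset[str]]:
    """Each drug's term profile at one level (empty profiles dropped)."""
    out = {}
    for drug, targets in inputs.profiles.items():
        if level_name == "gene":
            terms = drug_related_terms(targets, level_name="gene")
        elif level_name == "ppi":
            terms = drug_related_terms(
                targets,
                level_name="ppi",
                net=inputs.ppi,
                ppi_min_score=config.ppi_min_score,
            )
        else:
            terms = drug_related_terms(
                targets, inputs.annotations[level_name], level_name=level_name
            )
        if terms:
            out[drug] = terms
    return out


def run_study(
    inputs: StudyInputs, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run the multi-level association analysis on an in-memory study."""
    config = config or PipelineConfig()
    level_names = ["gene", "ppi"] + sorted(inputs.annotations)
    rankings: dict[str, LevelRanking] = {}
    ageing_terms: dict[str, frozenset[str]] = {}
    for name in level_names:
        a_terms = ageing_terms_at_level(inputs, name, config)
        profiles = drug_terms_at_level(inputs, name, config)
        if not profiles or not a_terms:
            continue
        rankings[name] = rank_level(
            profiles,
            a_terms,
            level=name,
            sidedness=config.sidedness,
            alpha=config.alpha,
        )
        ageing_terms[name] = a_terms
    if not rankings:
        raise ValueError("no level produced a ranking")
    combined = combine_rankings(list(rankings.values()), policy=config.policy)
    evaluation: dict[str, dict[str, float]] = {}
    for name, ranking in rankings.items():
        row: dict[str, float] = {}
        for which in ("pro", "anti"):
            if any(v == which for v in inputs.labels.values()):
                try:
                    row[f"auc_{which}"] = enrichment_curve(
                        ranking, inputs.labels, which
                    ).auc
                except ValueError:
                    continue
        if inputs.labels and len(ranking) >= config.top_k:
            count, frac = top_k_overlap(
                ranking, inputs.labels, "pro", k=config.top_k
            )
            row["topk_count"] = count
            row["topk_fraction"] = frac
        evaluation[name] = row
    w = None
    if len(rankings) >= 2:
        try:
            _, w = concordance(list(rankings.values()))
        except ValueError:
            w = None
    return PipelineResult(rankings, ageing_terms, combined, evaluation, w)
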