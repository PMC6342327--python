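"""Synthetic study generator with known ground truth.

Emulates every input of the pipeline — gene universe, annotation levels,
PPI network, drug-target interactions, ageing-gene evidence table,
longevity labels and an identifier map — at a configurable scale, with a
*planted* subset of drugs whose targets are enriched for the ageing set.

Planting uses a Fisher noncentral hypergeometric draw: a planted drug with
T targets picks its ageing-related target count from the biased urn with
odds ``theta``, so the generative odds parameter is exactly the quantity
the conditional-MLE odds-ratio estimator targets.  With ``theta = 1`` the
generator is an exact null.

Default sizes follow the shape of the real study at reduced scale: about
a thousand drugs with a handful of targets each drawn from a few thousand
proteins, an ageing set of roughly 15% of the gene-level universe, and
annotation levels from tens to hundreds of terms.
"""

from __future__ import annotations

import json
import shutil
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import nchypergeom_fisher

from .io_ingest import (
    CATEGORIES,
    Action,
    GeneSet,
    InteractionRecord,
    InteractionTable,
    write_interactions,
)
from .levels import AnnotationLevel, PPINetwork, write_ppi
from .io_ingest import write_gene_sets

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_annotation_level",
    "generate_ppi",
    "generate_drug_interactions",
    "generate_ageing_table",
    "generate_labels",
    "generate_study",
]

#: terms per annotation level, mirroring the relative richness of the
#: real annotation sources (BP much larger than the pathway databases)
DEFAULT_LEVEL_SIZES = {
    "go_bp": 400,
    "go_cc": 100,
    "go_mf": 100,
    "kegg": 80,
    "reactome": 60,
}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_genes: int = 3000
    n_drugs: int = 1000
    n_ageing_genes: int = 450
    #: log-normal parameters of the targets-per-drug distribution; the
    #: default mean of ~7.4 targets per drug matches the filtered
    #: chemical-protein dataset the generator emulates
    targets_mu: float = 1.68
    targets_sigma: float = 0.8
    max_targets: int = 250
    level_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_SIZES)
    )
    #: log-normal parameters of term sizes (mean ~ 20 genes)
    term_mu: float = 2.8
    term_sigma: float = 0.7
    #: fraction of terms whose members favour ageing genes, and the odds
    #: of the bias — real pathway annotations cluster the ageing set, and
    #: without this no term would ever be enriched
    biased_term_fraction: float = 0.2
    term_ageing_odds: float = 8.0
    ppi_mean_degree: float = 4.0
    ppi_score_low: int = 700
    ppi_score_high: int = 1000
    #: fraction of drugs with targets enriched for the ageing set
    planted_fraction: float = 0.1
    #: biased-urn odds of a planted target being ageing-related
    theta: float = 5.0
    #: fraction of pro labels reassigned to random unplanted drugs
    label_noise: float = 0.1
    n_anti: int = 30
    score_low: int = 700
    score_high: int = 1000
    #: fraction of additional sub-threshold edges (exercises filtering)
    score_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must lie in [0, 1]")
        if min(self.n_genes, self.n_drugs, self.n_ageing_genes) <= 0:
            raise ValueError("counts must be positive")
        if self.n_ageing_genes > self.n_genes:
            raise ValueError("more ageing genes than genes")

    def genes(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    def drugs(self) -> list[str]:
        return [f"D{i:04d}" for i in range(1, self.n_drugs + 1)]

    def chemicals(self) -> list[str]:
        return [f"CID{i:05d}" for i in range(1, self.n_drugs + 1)]


@dataclass
class SyntheticTruth:
    """Ground truth of one generated study."""

    planted: list[str]
    overlaps: dict[str, int]  # planted drug -> realized ageing-target count
    theta: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    # independent, named substream per artefact (crc32 is process-stable,
    # unlike the builtin str hash)
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def generate_annotation_level(
    config: SyntheticConfig, name: str, ageing: GeneSet | None = None
) -> AnnotationLevel:
    """Random gene sets with log-normal sizes.

    Most terms draw genes uniformly; a ``biased_term_fraction`` of them
    draw ageing genes with ``term_ageing_odds``-fold weight (when an
    ageing set is supplied), emulating the clustering of ageing genes in
    real pathway annotations that over-representation analysis detects.
    """
    n_terms = config.level_sizes.get(name, 0)
    rng = _rng(config, f"level:{name}")
    genes = np.array(config.genes(), dtype=object)
    weights = None
    if ageing is not None and config.term_ageing_odds != 1.0:
        w = np.ones(len(genes))
        w[[g in ageing.genes for g in genes]] = config.term_ageing_odds
        weights = w / w.sum()
    terms = {}
    for i in range(1, n_terms + 1):
        size = int(
            np.clip(
                np.round(rng.lognormal(config.term_mu, config.term_sigma)),
                1,
                config.n_genes,
            )
        )
        biased = weights is not None and rng.random() < config.biased_term_fraction
        members = rng.choice(
            genes, size=size, replace=False, p=weights if biased else None
        )
        term_id = f"{name.upper()}:{i:04d}"
        terms[term_id] = GeneSet(term_id, frozenset(members))
    return AnnotationLevel(name, terms)


def generate_ppi(config: SyntheticConfig) -> PPINetwork:
    """Erdős–Rényi network over the gene universe with uniform scores."""
    if config.ppi_mean_degree >= config.n_genes:
        raise ValueError("mean degree must be below the number of genes")
    rng = _rng(config, "ppi")
    genes = config.genes()
    n = len(genes)
    n_edges = int(round(config.ppi_mean_degree * n / 2))
    net = PPINetwork()
    if n_edges == 0:
        return net
    seen: set[tuple[int, int]] = set()
    while len(seen) < n_edges:
        a, b = rng.integers(0, n, size=2)
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        score = int(rng.integers(config.ppi_score_low, config.ppi_score_high + 1))
        net.add_edge(genes[key[0]], genes[key[1]], score)
    return net


def generate_ageing_set(config: SyntheticConfig) -> GeneSet:
    rng = _rng(config, "ageing")
    picked = rng.choice(
        np.array(config.genes(), dtype=object),
        size=config.n_ageing_genes,
        replace=False,
    )
    return GeneSet("ageing", frozenset(picked))


def generate_drug_interactions(
    config: SyntheticConfig, ageing: GeneSet
) -> tuple[InteractionTable, SyntheticTruth]:
    """Drug-target edges with a planted ageing-enriched drug subset.

    Non-planted drugs draw targets uniformly; planted drugs draw their
    ageing-target count from the Fisher noncentral hypergeometric with
    odds ``theta`` and fill the rest uniformly.  Edge scores are at or
    above the default confidence filter unless ``score_noise`` adds
    sub-threshold edges.
    """
    genes = config.genes()
    ageing_list = sorted(set(genes) & ageing.genes)
    if len(ageing_list) != len(ageing.genes):
        raise ValueError("ageing genes must lie inside the gene universe")
    other_list = sorted(set(genes) - ageing.genes)
    rng = _rng(config, "interactions")
    drugs = config.drugs()
    n_planted = int(round(config.planted_fraction * config.n_drugs))
    planted = sorted(
        rng.choice(np.array(drugs, dtype=object), size=n_planted, replace=False)
    )
    planted_set = set(planted)
    K = len(ageing_list)
    N = config.n_genes
    records = []
    overlaps: dict[str, int] = {}
    for drug in drugs:
        n_targets = int(
            np.clip(
                np.round(rng.lognormal(config.targets_mu, config.targets_sigma)),
                1,
                config.max_targets,
            )
        )
        if drug in planted_set and config.theta > 1:
            x = int(
                nchypergeom_fisher.rvs(
                    N, K, n_targets, config.theta, random_state=rng
                )
            )
            targets = list(
                rng.choice(np.array(ageing_list, dtype=object), x, replace=False)
            ) + list(
                rng.choice(
                    np.array(other_list, dtype=object),
                    n_targets - x,
                    replace=False,
                )
            )
            overlaps[drug] = x
        else:
            targets = list(
                rng.choice(np.array(genes, dtype=object), n_targets, replace=False)
            )
            if drug in planted_set:
                overlaps[drug] = sum(1 for t in targets if t in ageing.genes)
        for t in targets:
            records.append(
                InteractionRecord(
                    chemical_id=drug,
                    protein_id=t,
                    action=Action.activation
                    if rng.random() < 0.5
                    else Action.inhibition,
                    chemical_is_acting=True,
                    combined_score=int(
                        rng.integers(config.score_low, config.score_high + 1)
                    ),
                )
            )
        if config.score_noise > 0:
            n_noise = rng.binomial(n_targets, config.score_noise)
            extra = rng.choice(np.array(genes, dtype=object), n_noise, replace=False)
            for t in extra:
                records.append(
                    InteractionRecord(
                        chemical_id=drug,
                        protein_id=t,
                        action=Action.other,
                        chemical_is_acting=bool(rng.random() < 0.5),
                        combined_score=int(rng.integers(0, config.score_low)),
                    )
                )
    truth = SyntheticTruth(planted, overlaps, config.theta, config.seed)
    return InteractionTable(records), truth


def generate_ageing_table(
    config: SyntheticConfig, ageing: GeneSet
) -> pd.DataFrame:
    """Evidence-category table: ageing genes carry >= 2 categories,
    distractor genes exactly one, so the >=2-category filter recovers the
    ageing set exactly."""
    rng = _rng(config, "ageing-table")
    rows = []
    for g in sorted(ageing.genes):
        n_cat = int(rng.integers(2, len(CATEGORIES) + 1))
        cats = set(rng.choice(CATEGORIES, size=n_cat, replace=False))
        rows.append({"gene": g, **{c: int(c in cats) for c in CATEGORIES}})
    others = sorted(set(config.genes()) - ageing.genes)
    n_distract = min(len(others), config.n_ageing_genes)
    for g in rng.choice(np.array(others, dtype=object), n_distract, replace=False):
        cat = str(rng.choice(CATEGORIES))
        rows.append({"gene": g, **{c: int(c == cat) for c in CATEGORIES}})
    return pd.DataFrame(rows).sort_values("gene", ignore_index=True)


def generate_labels(
    config: SyntheticConfig, truth: SyntheticTruth
) -> dict[str, str]:
    """Longevity labels derived from the planted truth with noise.

    Planted drugs are labelled ``pro``; a ``label_noise`` fraction of those
    labels are reassigned to random unplanted drugs, and ``n_anti``
    unplanted, unlabelled drugs are labelled ``anti``.
    """
    rng = _rng(config, "labels")
    drugs = config.drugs()
    planted = list(truth.planted)
    unplanted = sorted(set(drugs) - set(planted))
    n_flip = int(round(config.label_noise * len(planted)))
    pro = set(planted)
    if n_flip and unplanted:
        drop = rng.choice(np.array(planted, dtype=object), n_flip, replace=False)
        gain = rng.choice(np.array(unplanted, dtype=object), n_flip, replace=False)
        pro = (pro - set(drop)) | set(gain)
    remaining = sorted(set(unplanted) - pro)
    n_anti = min(config.n_anti, len(remaining))
    anti = set(rng.choice(np.array(remaining, dtype=object), n_anti, replace=False))
    labels = {d: "pro" for d in pro}
    labels.update({d: "anti" for d in anti})
    return labels


def generate_study(config: SyntheticConfig, out_dir: str | Path) -> dict:
    """Write a complete study bundle readable by the ingest module.

    Files: ``interactions.tsv`` (STITCH dialect, chemical ids),
    ``id_map.tsv`` (chemical -> drug ids), one ``<level>.gmt`` per
    annotation level, ``ppi.tsv`` (STRING dialect), ``ageing_genes.tsv``,
    ``labels.tsv`` and ``truth.json``.  Returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        ageing = generate_ageing_set(config)
        table, truth = generate_drug_interactions(config, ageing)
        # present interactions under chemical ids; the id map restores drugs
        chem_of = dict(zip(config.drugs(), config.chemicals()))
        chem_records = [
            InteractionRecord(
                chem_of[r.chemical_id],
                r.protein_id,
                r.action,
                r.chemical_is_acting,
                r.combined_score,
            )
            for r in table.records
        ]
        paths = {}

        def register(name: str) -> Path:
            p = out / name
            written.append(p)
            paths[name.split(".")[0]] = p
            return p

        write_interactions(InteractionTable(chem_records), register("interactions.tsv"))
        pd.DataFrame(
            {"chemical": config.chemicals(), "drug": config.drugs()}
        ).to_csv(register("id_map.tsv"), sep="\t", index=False)
        for name in config.level_sizes:
            level = generate_annotation_level(config, name, ageing)
            write_gene_sets(level.terms, register(f"{name}.gmt"))
        write_ppi(generate_ppi(config), register("ppi.tsv"))
        generate_ageing_table(config, ageing).to_csv(
            register("ageing_genes.tsv"), sep="\t", index=False
        )
        labels = generate_labels(config, truth)
        pd.DataFrame(
            sorted(labels.items()), columns=["drug", "label"]
        ).to_csv(register("labels.tsv"), sep="\t", index=False)
        truth.to_json(register("truth.json"))
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        if not any(out.iterdir()):
            shutil.rmtree(out, ignore_errors=True)
        raise
    return paths
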