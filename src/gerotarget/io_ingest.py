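"""Reading, validation and filtering of the external tables.

Every input is a plain tab-separated text file:

* chemical-protein interactions in the STITCH-links dialect
  (``item_id_a``, ``item_id_b``, ``mode``, ``a_is_acting``, ``score``);
* gene sets in GMT format (one term per line);
* the ageing-gene table with boolean evidence-category columns;
* a two-column identifier map (chemical id -> drug id);
* a drug longevity-label table (drug id, label in {pro, anti}).

Scores are integer confidences on the 0-1000 scale used by STITCH and
STRING, where 700 corresponds to the usual "high confidence" 0.7 cutoff.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Action",
    "InteractionRecord",
    "InteractionTable",
    "GeneSet",
    "FormatError",
    "CATEGORIES",
    "read_interactions",
    "write_interactions",
    "filter_interactions",
    "read_gene_sets",
    "read_ageing_genes",
    "read_id_map",
    "read_labels",
    "map_drug_ids",
    "drug_target_profiles",
]

#: The four evidence classes of the ageing-gene meta-analysis: manually
#: curated longevity databases, age/CR differential expression, age-related
#: DNA methylation, and age-related disease associations.
CATEGORIES = ("curated", "expression", "methylation", "disease")


class FormatError(ValueError):
    """Raised when an input file violates its dialect."""


class Action(str, enum.Enum):
    """Mode of a chemical-protein interaction."""

    activation = "activation"
    inhibition = "inhibition"
    other = "other"

    @classmethod
    def parse(cls, raw: str) -> "Action":
        raw = raw.strip().lower()
        if raw in ("activation", "inhibition"):
            return cls(raw)
        return cls.other


@dataclass(frozen=True)
class InteractionRecord:
    """One chemical-protein edge with its mode and combined confidence."""

    chemical_id: str
    protein_id: str
    action: Action
    chemical_is_acting: bool
    combined_score: int

    def __post_init__(self) -> None:
        if not self.chemical_id or not self.protein_id:
            raise ValueError("interaction ids must be non-empty")
        if not 0 <= self.combined_score <= 1000:
            raise ValueError(
                f"combined_score {self.combined_score} outside [0, 1000]"
            )


@dataclass
class InteractionTable:
    """A set of interaction records plus the id sets they span."""

    records: list[InteractionRecord] = field(default_factory=list)

    @property
    def drugs(self) -> set[str]:
        return {r.chemical_id for r in self.records}

    @property
    def proteins(self) -> set[str]:
        return {r.protein_id for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id_a": [r.chemical_id for r in self.records],
                "item_id_b": [r.protein_id for r in self.records],
                "mode": [r.action.value for r in self.records],
                "a_is_acting": [
                    "t" if r.chemical_is_acting else "f" for r in self.records
                ],
                "score": [r.combined_score for r in self.records],
            }
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


#: Column names of the STITCH-links dialect; override via ``dialect=``.
DEFAULT_DIALECT = {
    "chemical": "item_id_a",
    "protein": "item_id_b",
    "mode": "mode",
    "acting": "a_is_acting",
    "score": "score",
}

_TRUTHY = {"t", "true", "1", "yes", "y"}
_FALSY = {"f", "false", "0", "no", "n", ""}


def _parse_acting(raw: str, row: int) -> bool:
    raw = raw.strip().lower()
    if raw in _TRUTHY:
        return True
    if raw in _FALSY:
        return False
    raise FormatError(f"row {row}: cannot parse acting flag {raw!r}")


def read_interactions(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> InteractionTable:
    """Parse a STITCH-links dialect TSV into an :class:`InteractionTable`.

    All rows are returned unfiltered; modes other than activation or
    inhibition are mapped to :attr:`Action.other`.  Malformed rows raise
    :class:`FormatError` naming the offending 1-based data row.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw_score = getattr(row, cols["score"])
        try:
            score = int(raw_score)
        except ValueError:
            raise FormatError(
                f"row {i}: score {raw_score!r} is not an integer"
            ) from None
        try:
            records.append(
                InteractionRecord(
                    chemical_id=getattr(row, cols["chemical"]),
                    protein_id=getattr(row, cols["protein"]),
                    action=Action.parse(getattr(row, cols["mode"])),
                    chemical_is_acting=_parse_acting(
                        getattr(row, cols["acting"]), i
                    ),
                    combined_score=score,
                )
            )
        except ValueError as exc:
            raise FormatError(f"row {i}: {exc}") from None
    return InteractionTable(records)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    """Write a table in the same dialect :func:`read_interactions` reads."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def _dedup_max_score(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    best: dict[tuple[str, str], InteractionRecord] = {}
    for r in records:
        key = (r.chemical_id, r.protein_id)
        if key not in best or r.combined_score > best[key].combined_score:
            best[key] = r
    return list(best.values())


def filter_interactions(
    table: InteractionTable,
    min_score: int = 700,
    allowed_actions: set[Action] | None = None,
    require_chemical_acting: bool = True,
) -> InteractionTable:
    """Apply the confidence/mode/direction filters.

    Keeps records with ``combined_score >= min_score`` (default 700, the
    high-confidence 0.7 cutoff), an allowed action (default activation or
    inhibition), and — unless disabled — the chemical as the acting partner.
    Duplicate (chemical, protein) pairs collapse to the maximum-score record.
    Idempotent.
    """
    if not 0 <= min_score <= 1000:
        raise ValueError("min_score must lie in [0, 1000]")
    if allowed_actions is None:
        allowed_actions = {Action.activation, Action.inhibition}
    kept = [
        r
        for r in table.records
        if r.combined_score >= min_score
        and r.action in allowed_actions
        and (r.chemical_is_acting or not require_chemical_acting)
    ]
    return InteractionTable(_dedup_max_score(kept))


def read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT file into a mapping term id -> :class:`GeneSet`.

    GMT lines are ``term_id <tab> description <tab> gene1 <tab> gene2 ...``.
    Duplicate genes within a term are collapsed; duplicate term ids and
    lines with fewer than three fields are rejected.
    """
    terms: dict[str, GeneSet] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path} line {i}: GMT line needs >=3 fields"
                )
            term_id = fields[0]
            if term_id in terms:
                raise FormatError(
                    f"{path} line {i}: duplicate term id {term_id!r}"
                )
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path} line {i}: term {term_id!r} empty")
            terms[term_id] = GeneSet(term_id, genes)
    return terms


def write_gene_sets(
    terms: Mapping[str, GeneSet], path: str | Path, description: str = "na"
) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            genes = "\t".join(sorted(terms[term_id].genes))
            fh.write(f"{term_id}\t{description}\t{genes}\n")


def read_ageing_genes(
    path: str | Path, min_categories: int = 2
) -> GeneSet:
    """Select ageing-related genes supported by enough evidence classes.

    The table has a ``gene`` column and one 0/1 column per evidence
    category (curated, expression, methylation, disease).  Genes present in
    at least ``min_categories`` categories are retained — the default of 2
    is the reliability filter of the ageing-gene meta-analysis.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene" not in df.columns:
        raise FormatError(f"{path}: missing 'gene' column")
    unknown = [
        c for c in df.columns if c != "gene" and c not in CATEGORIES
    ]
    if unknown:
        raise FormatError(f"{path}: unknown category columns {unknown}")
    present = [c for c in CATEGORIES if c in df.columns]
    counts = df[present].astype(int).sum(axis=1)
    genes = frozenset(df.loc[counts >= min_categories, "gene"])
    return GeneSet("ageing", genes)


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column source-id -> target-id TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: id map needs two columns")
    src, dst = df.columns[:2]
    if (df[src] == "").any() or (df[dst] == "").any():
        raise FormatError(f"{path}: empty identifier in id map")
    return dict(zip(df[src], df[dst]))


def read_labels(path: str | Path) -> dict[str, str]:
    """Read the longevity-label table: drug id -> 'pro' | 'anti'."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"drug", "label"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns 'drug' and 'label'")
    bad = set(df["label"]) - {"pro", "anti"}
    if bad:
        raise FormatError(f"{path}: unknown labels {sorted(bad)}")
    if df["drug"].duplicated().any():
        raise FormatError(f"{path}: duplicate drug label rows")
    return dict(zip(df["drug"], df["label"]))


def map_drug_ids(
    table: InteractionTable,
    idmap: Mapping[str, str],
    keep_unmapped: bool = False,
) -> InteractionTable:
    """Replace chemical ids via the map, dropping unmapped drugs by default.

    Stands in for the chemical-vocabulary to drug-vocabulary resolution
    step; when two source ids map to one drug the target profiles are
    unioned (duplicates keep the maximum score).
    """
    out = []
    for r in table.records:
        if r.chemical_id in idmap:
            out.append(
                InteractionRecord(
                    idmap[r.chemical_id],
                    r.protein_id,
                    r.action,
                    r.chemical_is_acting,
                    r.combined_score,
                )
            )
        elif keep_unmapped:
            out.append(r)
    return InteractionTable(_dedup_max_score(out))


def drug_target_profiles(table: InteractionTable) -> dict[str, GeneSet]:
    """Collect each drug's target set; drugs with no targets are absent."""
    targets: dict[str, set[str]] = {}
    for r in table.records:
        targets.setdefault(r.chemical_id, set()).add(r.protein_id)
    return {
        drug: GeneSet(drug, frozenset(genes))
        for drug, genes in targets.items()
        if genes
    }
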