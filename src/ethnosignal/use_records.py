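"""Use-record tables and binary trait matrices.

Ethnobotanical use reports arrive as one row per (species, use) pair, coded
with the Economic Botany Data Collection Standard (EBDCS): a level-1 state
category (``medicines``, ``vertebrate_poisons``, ``animal_food`` ...) and,
for medicinal records, a level-2 state category (``inflammation``, ``pain``
...).  Each record additionally carries a biological-response class that
says whether the described treatment can be related to an inflammatory
response.  This module loads such tables, joins species names against tree
tip labels, and turns the records into binary species-by-category trait
tables with per-category counts and prevalence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSE_CLASSES",
    "UseRecord",
    "TraitTable",
    "normalize_name",
    "load_use_records",
    "build_trait_table",
    "category_summary",
    "DEFAULT_AUTHORITIES",
]

#: Allowed values of the per-record biological-response class.
RESPONSE_CLASSES = (
    "inflammatory_response",
    "no_inflammatory_response",
    "unknown",
    "not_applicable",
)

#: Level-1 categories whose records are eligible for response-class screening.
#: Toxicity reports (vertebrate poisons) are included alongside medicinal
#: records because toxicity is separated from medicinality only by dosage.
RESPONSE_ELIGIBLE_L1 = ("medicines", "vertebrate_poisons")

#: Botanical authority strings stripped from binomials during normalization.
#: List-driven rather than heuristic so that epithets are never mangled;
#: extend via the ``authorities`` argument of :func:`normalize_name`.
DEFAULT_AUTHORITIES = (
    "L.",
    "Lam.",
    "Mill.",
    "Thunb.",
    "Willd.",
    "Boiss.",
    "Haw.",
    "Aiton",
    "Burm.f.",
    "Sm.",
)

_WS = re.compile(r"\s+")


def normalize_name(raw: str, authorities: Sequence[str] = DEFAULT_AUTHORITIES) -> str:
    """Canonicalize a species name so tree tips and records can be joined.

    Trims and collapses whitespace, replaces underscores with spaces, strips
    a trailing authority string when it matches the configured list, and
    capitalizes the genus.  Idempotent.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("species name is empty")
    name = _WS.sub(" ", raw.replace("_", " ")).strip()
    parts = name.split(" ")
    if len(parts) > 2:
        tail = " ".join(parts[2:])
        if tail in authorities:
            parts = parts[:2]
    parts[0] = parts[0][:1].upper() + parts[0][1:].lower()
    return " ".join(parts)


@dataclass(frozen=True)
class UseRecord:
    """One use report for one species."""

    species: str
    description: str
    ebdcs_l1: str
    ebdcs_l2: str
    response_class: str
    row: int = 0

    def __post_init__(self) -> None:
        if self.response_class not in RESPONSE_CLASSES:
            raise ValueError(
                f"row {self.row}: unknown response class {self.response_class!r}"
            )
        if (
            self.response_class != "not_applicable"
            and self.ebdcs_l1 not in RESPONSE_ELIGIBLE_L1
        ):
            raise ValueError(
                f"row {self.row}: response class {self.response_class!r} is only "
                f"valid for level-1 categories {RESPONSE_ELIGIBLE_L1}, "
                f"got {self.ebdcs_l1!r}"
            )


_REQUIRED_COLUMNS = ("species", "description", "ebdcs_l1", "ebdcs_l2", "response_class")


def load_use_records(path: str | Path) -> list[UseRecord]:
    """Load a delimited use-record file (CSV or TSV, by extension).

    The file must carry the columns ``species, description, ebdcs_l1,
    ebdcs_l2, response_class``.  Unknown response classes are rejected with
    the offending row number.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        records.append(
            UseRecord(
                species=row.species,
                description=row.description,
                ebdcs_l1=row.ebdcs_l1.strip(),
                ebdcs_l2=row.ebdcs_l2.strip(),
                response_class=row.response_class.strip(),
                row=i,
            )
        )
    return records


CategorySpec = Literal["ebdcs_l1", "ebdcs_l2", "response_class"]


@dataclass
class TraitTable:
    """Binary species-by-category membership restricted to tree tips.

    ``matrix`` is a 0/1 DataFrame indexed by tip label with one column per
    category.  ``counts[c]`` is the number of member species of category
    ``c`` among the tips, and ``prevalence[c] = counts[c] / n_tips``.
    """

    matrix: pd.DataFrame
    spec: str = "custom"

    @property
    def tips(self) -> tuple[str, ...]:
        return tuple(self.matrix.index)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)

    @property
    def counts(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    @property
    def prevalence(self) -> pd.Series:
        return self.counts / len(self.matrix.index)

    def members(self, category: str) -> frozenset[str]:
        col = self.matrix[category]
        return frozenset(col.index[col == 1])


def _category_of(rec: UseRecord, spec: CategorySpec) -> str | None:
    """Category a record contributes to under the given spec, or None."""
    if spec == "ebdcs_l1":
        return rec.ebdcs_l1 or None
    if spec == "ebdcs_l2":
        # level-2 states exist only within medicines; vertebrate-poison
        # records never contribute here.
        if rec.ebdcs_l1 == "medicines" and rec.ebdcs_l2:
            return rec.ebdcs_l2
        return None
    if spec == "response_class":
        # medicinal and toxicity records both participate in the screen
        if rec.response_class != "not_applicable":
            return rec.response_class
        return None
    raise ValueError(f"unknown category spec {spec!r}")


def build_trait_table(
    records: Iterable[UseRecord],
    categories: CategorySpec,
    tips: Sequence[str],
) -> TraitTable:
    """Build a binary trait table over the given tree tips.

    A species is a member of a category if at least one of its records maps
    to it; species with no matching record are 0 everywhere.  Records for
    species absent from ``tips`` are dropped.  Insensitive to record order
    and duplicate rows.
    """
    tips = list(tips)
    if not tips:
        raise ValueError("tip list is empty")
    tip_set = {normalize_name(t): t for t in tips}
    membership: dict[str, set[str]] = {}
    for rec in records:
        cat = _category_of(rec, categories)
        if cat is None:
            continue
        sp = normalize_name(rec.species)
        if sp not in tip_set:
            continue
        membership.setdefault(cat, set()).add(tip_set[sp])
    cats = sorted(membership)
    mat = pd.DataFrame(0, index=pd.Index(tips, name="species"), columns=cats, dtype=np.int8)
    for cat in cats:
        mat.loc[sorted(membership[cat]), cat] = 1
    return TraitTable(matrix=mat, spec=categories)


def matched_species_fraction(records: Iterable[UseRecord], tips: Sequence[str]) -> tuple[int, int, float]:
    """(n matched, n total, fraction) of record species present among tips."""
    record_species = {normalize_name(r.species) for r in records}
    tip_names = {normalize_name(t) for t in tips}
    matched = record_species & tip_names
    return len(matched), len(record_species), len(matched) / len(record_species)


def category_summary(table: TraitTable) -> pd.DataFrame:
    """Per-category N, prevalence (2 dp) and member list, machine-readable."""
    rows = []
    n_tips = len(table.tips)
    for cat in table.categories:
        members = sorted(table.members(cat))
        rows.append(
            {
                "category": cat,
                "N": len(members),
                "prevalence": round(len(members) / n_tips, 2),
                "members": ";".join(members),
            }
        )
    return pd.DataFrame(rows, columns=["category", "N", "prevalence", "members"])
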