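"""Packaged localization table of the Tetrahymena Rab family.

GFP-tagging in live cells assigned each of the 56 TtRabs a primary localization
category from GFP-tagging in live cells (a Rab with two equally strong
primary signals appears under both categories, so the table has 57 rows).
Conserved Rabs — those falling into clades with non-ciliate Rabs by
phylogenetic analysis — are flagged, as are the four family members that
could not be cloned.  Summaries over category groups reproduce the
family-level counts: 56 Rabs total, 15 conserved (27%), 9 endocytic,
11 phagosomal, 5 oral-apparatus, 5 Golgi, 3 contractile-vacuole.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

_FIXTURE_NAME = "rab_localization_table.tsv"
_FIXTURE_SHA256 = "586db08f963a0fd40c3ceac4c5ea609137e6eab39dc29a96b7d16bae3f579820"

#: The closed set of primary-localization categories, in table order.
CATEGORIES = (
    "Parasomal sacs",
    "Endocytic vesicles",
    "Posterior (recycling?) endosomes",
    "Lysosomes/phagosomes",
    "Oral apparatus",
    "All phagosomes",
    "Selected phagosomes",
    "Cytoproct-localized phagosomes",
    "Cytoproct region",
    "Contractile vacuole Rabs",
    "ER-to-Golgi",
    "Golgi",
    "Dense core granule docking",
    "Basal bodies",
    "Cortical cytoskeleton",
    "Plasma membrane vicinity",
    "Nuclear envelope",
    "Indeterminate structures",
    "Not cloned",
)

#: Category groups used for the family-level counts.
CATEGORY_GROUPS: dict[str, tuple[str, ...]] = {
    "endocytic": (
        "Parasomal sacs",
        "Endocytic vesicles",
        "Posterior (recycling?) endosomes",
    ),
    "phagosomal": (
        "Lysosomes/phagosomes",
        "All phagosomes",
        "Selected phagosomes",
        "Cytoproct-localized phagosomes",
    ),
    "oral_apparatus": ("Oral apparatus",),
    "golgi": ("Golgi",),
    "contractile_vacuole": ("Contractile vacuole Rabs",),
    "all": CATEGORIES,
}


class FixtureError(RuntimeError):
    """Packaged table missing or corrupted (checksum mismatch)."""


@dataclass(frozen=True)
class LocalizationRecord:
    rab: str
    category: str
    conserved: bool
    cloned: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def load_localization_table() -> list[LocalizationRecord]:
    """The packaged localization table of the 56-member TtRab family."""
    ref = resources.files("tetrarab").joinpath("data", _FIXTURE_NAME)
    try:
        raw = ref.read_bytes()
    except FileNotFoundError as exc:
        raise FixtureError("localization table fixture missing") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureError(
            f"localization table checksum mismatch ({digest[:12]}…)"
        )
    lines = raw.decode().splitlines()
    header = lines[0].split("\t")
    if header != ["rab", "category", "conserved", "cloned"]:
        raise FixtureError("unexpected fixture header")
    records = []
    for line in lines[1:]:
        rab, category, conserved, cloned = line.split("\t")
        records.append(
            LocalizationRecord(rab, category, conserved == "1", cloned == "1")
        )
    return records


def summarize_localization(
    records: Sequence[LocalizationRecord],
    category_groups: Mapping[str, Iterable[str]] | None = None,
) -> dict:
    """Family-level counts from localization records.

    Group counts deduplicate Rabs listed under more than one member
    category.  The conserved percentage is rounded to the nearest integer.
    """
    if not records:
        raise ValueError("empty record list")
    groups = dict(category_groups) if category_groups is not None else dict(
        CATEGORY_GROUPS
    )
    for name, cats in groups.items():
        unknown = set(cats) - set(CATEGORIES)
        if unknown:
            raise ValueError(
                f"group {name!r} names unknown categories {sorted(unknown)!r}"
            )
    distinct = {r.rab for r in records}
    conserved = {r.rab for r in records if r.conserved}
    per_category = {
        cat: len({r.rab for r in records if r.category == cat})
        for cat in CATEGORIES
    }
    group_counts = {
        name: len({r.rab for r in records if r.category in set(cats)})
        for name, cats in groups.items()
    }
    return {
        "distinct_rabs": len(distinct),
        "per_category": per_category,
        "group_counts": group_counts,
        "conserved_count": len(conserved),
        "conserved_percent": round(100 * len(conserved) / len(distinct)),
        "not_cloned_count": len({r.rab for r in records if not r.cloned}),
    }
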