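"""Geocoded literature database: reading, validation, citation allocation, filtering.

The core record is one row per (article, sampling location).  Each article
carries a total citation count; influence is attributed to individual field
sites by dividing an article's citations equally among its sampling locations
("citation allocation").  Locations in heavily human-modified habitats (urban,
agricultural) can be filtered out to focus on relatively natural environments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "HABITATS",
    "HABITAT_SYNONYMS",
    "LiteratureTable",
    "FilterReport",
    "Counts",
    "read_literature_table",
    "allocate_citations",
    "filter_natural_habitats",
    "summarize_counts",
    "write_literature_csv",
    "normalize_habitat",
]

#: Canonical habitat vocabulary.
HABITATS = frozenset(
    {"forest", "grassland", "wetland", "desert", "rocky",
     "agricultural", "urban", "lake", "river"}
)

#: Accepted synonyms, mapped to the canonical label (matching is
#: case-insensitive and whitespace-stripped before lookup).
HABITAT_SYNONYMS: dict[str, str] = {
    "rocky area": "rocky",
    "rocky areas": "rocky",
    "agriculture": "agricultural",
    "cropland": "agricultural",
    "forests": "forest",
    "grasslands": "grassland",
    "wetlands": "wetland",
    "lakes": "lake",
    "rivers": "river",
}

MAX_HABITATS = 3

#: Default column mapping for CSV input (canonical name -> file column).
DEFAULT_SCHEMA: dict[str, str] = {
    "article_id": "article_id",
    "citations": "citations",
    "longitude": "longitude",
    "latitude": "latitude",
    "habitat1": "habitat1",
    "habitat2": "habitat2",
    "habitat3": "habitat3",
}


class SchemaError(ValueError):
    """A required column could not be resolved in the input file."""


class ValidationError(ValueError):
    """Row-level content violates the database invariants."""


class Counts(NamedTuple):
    n_articles: int
    n_locations: int
    total_citations: int


@dataclass
class FilterReport:
    """Before/after counts for a habitat filter pass."""

    excluded: tuple[str, ...]
    before: Counts
    after: Counts

    def to_dict(self) -> dict:
        return {
            "excluded_habitats": list(self.excluded),
            "before": self.before._asdict(),
            "after": self.after._asdict(),
        }


def normalize_habitat(label: str) -> str:
    """Map a raw habitat string onto the canonical vocabulary.

    Raises ``ValidationError`` naming the label when it is unknown.
    """
    lab = str(label).strip().lower()
    lab = HABITAT_SYNONYMS.get(lab, lab)
    if lab not in HABITATS:
        raise ValidationError(f"unknown habitat label: {label!r}")
    return lab


@dataclass
class LiteratureTable:
    """A validated literature database.

    Attributes
    ----------
    locations : DataFrame
        One row per (article, location): columns ``article_id``, ``longitude``,
        ``latitude``, ``habitats`` (frozenset of 1-3 canonical labels),
        ``allocated_citations``.  Stage outputs may add ``biome`` /
        ``ecoregion`` columns.
    articles : DataFrame
        One row per article: ``article_id``, ``total_citations``,
        ``n_locations``.
    provenance : str
        Free-text source note.
    """

    locations: pd.DataFrame
    articles: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        loc, art = self.locations, self.articles
        for col in ("article_id", "longitude", "latitude", "habitats"):
            if col not in loc.columns:
                raise ValidationError(f"locations missing column {col!r}")
        for col in ("article_id", "total_citations", "n_locations"):
            if col not in art.columns:
                raise ValidationError(f"articles missing column {col!r}")

        bad_lon = ~loc["longitude"].between(-180.0, 180.0)
        bad_lat = ~loc["latitude"].between(-90.0, 90.0)
        if bad_lon.any() or bad_lat.any():
            rows = loc.index[bad_lon | bad_lat].tolist()
            raise ValidationError(f"coordinates out of range in rows {rows}")

        for i, habs in loc["habitats"].items():
            if not habs or len(habs) > MAX_HABITATS:
                raise ValidationError(
                    f"row {i}: a location must carry 1-{MAX_HABITATS} habitats, "
                    f"got {sorted(habs)}"
                )
            unknown = set(habs) - HABITATS
            if unknown:
                raise ValidationError(f"row {i}: unknown habitat label: {unknown}")

        if (art["total_citations"] < 0).any():
            raise ValidationError("negative total_citations")
        if "allocated_citations" in loc.columns:
            if (loc["allocated_citations"] < 0).any():
                raise ValidationError("negative allocated_citations")

        counts = loc["article_id"].value_counts()
        for _, row in art.iterrows():
            if counts.get(row["article_id"], 0) != row["n_locations"]:
                raise ValidationError(
                    f"article {row['article_id']!r}: n_locations="
                    f"{row['n_locations']} disagrees with location rows"
                )
        extra = set(loc["article_id"]) - set(art["article_id"])
        if extra:
            raise ValidationError(f"location rows reference unknown articles {extra}")

    @property
    def is_allocated(self) -> bool:
        return "allocated_citations" in self.locations.columns

    def copy(self) -> "LiteratureTable":
        return dataclasses.replace(
            self, locations=self.locations.copy(), articles=self.articles.copy()
        )


def _resolve_schema(columns: Iterable[str], schema: Mapping[str, str] | None) -> dict:
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    cols = set(columns)
    required = ("article_id", "citations", "longitude", "latitude", "habitat1")
    for key in required:
        if mapping[key] not in cols:
            raise SchemaError(
                f"required column {mapping[key]!r} (for {key}) not found; "
                f"available: {sorted(cols)}"
            )
    return mapping


def read_literature_table(
    path, schema: Mapping[str, str] | None = None, provenance: str | None = None
) -> LiteratureTable:
    """Read a literature database from CSV and validate it.

    The file holds one row per (article, location) with the article's total
    citation count repeated on each of its rows.  Habitat labels are
    normalized to the canonical lower-case vocabulary; up to three habitat
    columns are read.  Citations are allocated to locations on read.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = _resolve_schema(raw.columns, schema)

    bad_rows: list[int] = []
    lon = pd.to_numeric(raw[mapping["longitude"]], errors="coerce")
    lat = pd.to_numeric(raw[mapping["latitude"]], errors="coerce")
    cit = pd.to_numeric(raw[mapping["citations"]], errors="coerce")
    for series in (lon, lat, cit):
        bad_rows.extend(raw.index[series.isna()].tolist())
    if bad_rows:
        raise ValidationError(
            f"unparseable coordinate or citation value in rows {sorted(set(bad_rows))}"
        )

    habitat_cols = [
        mapping[k] for k in ("habitat1", "habitat2", "habitat3")
        if mapping[k] in raw.columns
    ]
    habitats: list[frozenset] = []
    for i, row in raw.iterrows():
        labels = []
        for col in habitat_cols:
            for part in str(row[col]).replace(",", ";").split(";"):
                if part.strip():
                    labels.append(part)
        if len(labels) > MAX_HABITATS:
            raise ValidationError(
                f"row {i}: {len(labels)} habitat labels; at most "
                f"{MAX_HABITATS} may be assigned to one location"
            )
        if not labels:
            raise ValidationError(f"row {i}: no habitat label")
        habitats.append(frozenset(normalize_habitat(x) for x in labels))

    locations = pd.DataFrame(
        {
            "article_id": raw[mapping["article_id"]].astype(str),
            "longitude": lon.astype(float),
            "latitude": lat.astype(float),
            "habitats": habitats,
        }
    )
    per_article = locations.groupby("article_id", sort=False)
    articles = pd.DataFrame(
        {
            "article_id": list(per_article.groups),
            "total_citations": [
                int(cit[idx].iloc[0]) for idx in per_article.groups.values()
            ],
            "n_locations": [len(idx) for idx in per_article.groups.values()],
        }
    )
    table = LiteratureTable(
        locations=locations,
        articles=articles,
        provenance=provenance or str(path),
    )
    return allocate_citations(table)


def allocate_citations(table: LiteratureTable) -> LiteratureTable:
    """Attribute each article's citations equally to its sampling locations.

    ``allocated_citations = total_citations / n_locations``; the per-article
    sum is conserved exactly up to floating point.
    """
    if (table.articles["n_locations"] <= 0).any():
        bad = table.articles.loc[
            table.articles["n_locations"] <= 0, "article_id"
        ].tolist()
        raise ValidationError(f"articles with zero locations: {bad}")
    per_loc = (
        table.articles.set_index("article_id")["total_citations"]
        / table.articles.set_index("article_id")["n_locations"]
    )
    out = table.copy()
    out.locations["allocated_citations"] = (
        out.locations["article_id"].map(per_loc).astype(float)
    )
    out.validate()
    return out


def filter_natural_habitats(
    table: LiteratureTable,
    excluded: Iterable[str] = ("urban", "agricultural"),
    reallocate: bool = True,
) -> tuple[LiteratureTable, FilterReport]:
    """Drop locations in excluded habitats; drop articles left with none.

    A location is removed if *any* of its habitats is in ``excluded``
    (conservative definition of "natural").  With ``reallocate=True``
    (default) citations are re-divided among the article's remaining
    locations so the filtered totals still represent whole-article influence;
    with ``False`` the original per-location allocation is kept.
    """
    excluded = frozenset(normalize_habitat(x) for x in excluded)
    before = summarize_counts(table)

    keep = ~table.locations["habitats"].map(lambda h: bool(h & excluded))
    locations = table.locations[keep].reset_index(drop=True)
    remaining = locations["article_id"].value_counts()
    articles = table.articles[
        table.articles["article_id"].isin(remaining.index)
    ].reset_index(drop=True)
    articles = articles.assign(
        n_locations=articles["article_id"].map(remaining).astype(int)
    )
    out = LiteratureTable(locations, articles, table.provenance)
    if reallocate or not table.is_allocated:
        out = allocate_citations(out)
    after = summarize_counts(out)
    return out, FilterReport(tuple(sorted(excluded)), before, after)


def write_literature_csv(table: LiteratureTable, path) -> None:
    """Serialize a table to the CSV layout ``read_literature_table`` accepts."""
    totals = table.articles.set_index("article_id")["total_citations"]
    records = []
    for _, row in table.locations.iterrows():
        habs = sorted(row["habitats"])
        records.append(
            {
                "article_id": row["article_id"],
                "citations": int(totals[row["article_id"]]),
                "longitude": row["longitude"],
                "latitude": row["latitude"],
                "habitat1": habs[0],
                "habitat2": habs[1] if len(habs) > 1 else "",
                "habitat3": habs[2] if len(habs) > 2 else "",
            }
        )
    pd.DataFrame(records).to_csv(path, index=False)


def summarize_counts(table: LiteratureTable) -> Counts:
    """Exact totals: (n_articles, n_locations, total_citations)."""
    return Counts(
        n_articles=int(len(table.articles)),
        n_locations=int(len(table.locations)),
        total_citations=int(table.articles["total_citations"].sum()),
    )
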