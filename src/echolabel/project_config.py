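"""Per-site species lists, class-list management, BTO codes, site metadata.

An annotation project is configured by three read-only CSV tables, all
tolerant of a UTF-8 byte-order mark (spreadsheet exports commonly add one):

* ``species_list.csv`` — one column per study site, the header cell holding
  the site name; columns may be ragged.  Species are deduplicated and sorted
  alphabetically at load time.
* ``bto_codes.csv`` — columns ``bto_code`` and ``species_name``: the British
  Trust for Ornithology two-letter species codes, used to compact class
  labels in displays.
* ``location_list.csv`` — one row per deployed recorder with site metadata
  (coordinates, county, habitat type, distance to coastline); unknown
  columns are preserved verbatim.

The class list an annotator chooses from is built from the selected site's
species (core, green border), global miscellaneous noise categories (orange)
and manually added classes (blue); a label whose class is in none of these
renders grey.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .audio_io import parse_filename

logger = logging.getLogger("echolabel")

__all__ = [
    "ClassEntry",
    "SpeciesLists",
    "SiteMetadata",
    "CATEGORY_COLOURS",
    "DEFAULT_MISC_CLASSES",
    "load_species_lists",
    "merge_species_lists",
    "build_class_list",
    "add_class",
    "remove_class",
    "classify_label",
    "load_bto_codes",
    "apply_bto_codes",
    "load_locations",
    "match_recorder",
]

#: border colour role per class category
CATEGORY_COLOURS = {"core": "green", "custom": "blue", "misc": "orange", "unknown": "grey"}

#: shipped default miscellaneous (non-species) sound categories; configurable
DEFAULT_MISC_CLASSES = ["Human noise", "Insect noise", "Weather noise"]

_LOCATION_FIELDS = (
    "recorder_name",
    "lat",
    "long",
    "location_name",
    "location_county",
    "habitat_type",
    "dist_to_coastline",
)


@dataclass(frozen=True)
class ClassEntry:
    """A selectable class with its category (colour role) and display code."""

    name: str
    category: str = "core"
    display_code: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("class name must be non-empty")
        if self.category not in CATEGORY_COLOURS:
            raise ValueError(f"category must be one of {sorted(CATEGORY_COLOURS)}")
        if not self.display_code:
            object.__setattr__(self, "display_code", self.name)

    @property
    def colour(self) -> str:
        return CATEGORY_COLOURS[self.category]


@dataclass(frozen=True)
class SpeciesLists:
    """Ordered map of site name -> alphabetically sorted species names."""

    sites: dict[str, list[str]]

    def __post_init__(self) -> None:
        cleaned = {
            site: sorted(dict.fromkeys(s for s in names if s))
            for site, names in self.sites.items()
        }
        object.__setattr__(self, "sites", cleaned)

    @property
    def site_names(self) -> list[str]:
        return list(self.sites)


@dataclass(frozen=True)
class SiteMetadata:
    """Metadata for one deployed recorder; blank fields render as empty."""

    recorder_name: str
    lat: str = ""
    long: str = ""
    location_name: str = ""
    location_county: str = ""
    habitat_type: str = ""
    dist_to_coastline: str = ""
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.recorder_name:
            raise ValueError("recorder_name must be non-empty")


def _read_header(path: Path) -> list[str]:
    with open(path, encoding="utf-8-sig", newline="") as fh:
        return next(csv.reader(fh), [])


def load_species_lists(path: str | Path) -> SpeciesLists:
    """Load species_list.csv: header row holds site names, columns may be ragged."""
    path = Path(path)
    header = [h.strip() for h in _read_header(path)]
    duplicates = {h for h in header if header.count(h) > 1}
    if duplicates:
        raise ValueError(f"duplicate site column(s) in {path}: {', '.join(sorted(duplicates))}")
    df = pd.read_csv(path, encoding="utf-8-sig", dtype=str, keep_default_na=False)
    sites = {
        site: [cell.strip() for cell in df[col] if cell.strip()]
        for site, col in zip(header, df.columns)
    }
    return SpeciesLists(sites=sites)


def merge_species_lists(existing: SpeciesLists, uploaded: SpeciesLists) -> SpeciesLists:
    """Append uploaded site columns whose names are new; existing sites are untouched."""
    merged = dict(existing.sites)
    for site, names in uploaded.sites.items():
        if site not in merged:
            merged[site] = names
    return SpeciesLists(sites=merged)


def build_class_list(
    lists: SpeciesLists,
    site: str,
    custom: list[str] | None = None,
    misc: list[str] | None = None,
) -> list[ClassEntry]:
    """Assemble the selectable class list for one site.

    Order: the site's species (core), then miscellaneous categories (misc),
    then manually added classes (custom).
    """
    if site not in lists.sites:
        raise KeyError(f"unknown site {site!r}; available sites: {', '.join(lists.site_names)}")
    if misc is None:
        misc = DEFAULT_MISC_CLASSES
    entries = [ClassEntry(name=s, category="core") for s in lists.sites[site]]
    entries += [ClassEntry(name=m, category="misc") for m in misc]
    entries += [ClassEntry(name=c, category="custom") for c in (custom or [])]
    return entries


def add_class(entries: list[ClassEntry], name: str) -> list[ClassEntry]:
    """Append a manually added class; a class already present is an error."""
    if not name:
        raise ValueError("class name must be non-empty")
    if any(e.name == name for e in entries):
        raise ValueError(f"class {name!r} is already present in the list")
    return entries + [ClassEntry(name=name, category="custom")]


def remove_class(entries: list[ClassEntry], name: str) -> list[ClassEntry]:
    if not any(e.name == name for e in entries):
        raise ValueError(f"class {name!r} is not in the list")
    return [e for e in entries if e.name != name]


def classify_label(class_label: str, entries: list[ClassEntry]) -> ClassEntry:
    """Resolve a label's class against the list; unlisted classes are 'unknown' (grey)."""
    for entry in entries:
        if entry.name == class_label:
            return entry
    return ClassEntry(name=class_label, category="unknown")


def load_bto_codes(path: str | Path) -> pd.DataFrame:
    """Load the two-letter species-code lookup with columns bto_code, species_name."""
    df = pd.read_csv(path, encoding="utf-8-sig", dtype=str, keep_default_na=False)
    missing = [c for c in ("bto_code", "species_name") if c not in df.columns]
    if missing:
        raise ValueError(f"code lookup {path} is missing column(s): {', '.join(missing)}")
    return df


def apply_bto_codes(entries: list[ClassEntry], lookup: pd.DataFrame) -> list[ClassEntry]:
    """Set display codes from the species-code lookup; unmatched names are untouched.

    Only ``display_code`` changes — the underlying class name never does —
    so applying the same lookup twice is a no-op.
    """
    missing = [c for c in ("bto_code", "species_name") if c not in lookup.columns]
    if missing:
        raise ValueError(f"code lookup is missing column(s): {', '.join(missing)}")
    code_by_name = dict(zip(lookup["species_name"], lookup["bto_code"]))
    return [
        replace(e, display_code=code_by_name[e.name]) if e.name in code_by_name else e
        for e in entries
    ]


def load_locations(path: str | Path) -> list[SiteMetadata]:
    """Load location_list.csv; unknown columns go verbatim into ``extras``."""
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8-sig", dtype=str, keep_default_na=False)
    if "recorder_name" not in df.columns:
        raise ValueError(f"location list {path} is missing required column 'recorder_name'")
    extra_cols = [c for c in df.columns if c not in _LOCATION_FIELDS]
    records = []
    for row in df.to_dict(orient="records"):
        records.append(
            SiteMetadata(
                **{f: row.get(f, "") for f in _LOCATION_FIELDS},
                extras={c: row[c] for c in extra_cols},
            )
        )
    return records


def match_recorder(file_name: str, locations: list[SiteMetadata]) -> SiteMetadata | None:
    """Link an audio filename to its recorder's metadata; None when unmatched."""
    identity = parse_filename(file_name)
    if identity is None:
        return None
    for record in locations:
        if record.recorder_name == identity.recorder:
            return record
    logger.warning("no recorder metadata for %r (from %r)", identity.recorder, file_name)
    return None
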