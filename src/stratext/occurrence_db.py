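"""Fossil occurrence database: loading, vetting, stratigraphic ranges.

Occurrences are taxon-by-bed records compiled from the literature.  After
vetting (synonymy, habitat and palynomorph filters, duplicate collapse)
each taxon's occurrences define a stratigraphic range from its first
appearance datum (FAD) to its last appearance datum (LAD).  Range-end
uncertainty is quantified with the classical uniform-recovery confidence
interval: with H sampled horizons over a range of length r, the range
extends above the LAD by

    extension = r * ((1 - C)^(-1/(H-1)) - 1)

at confidence C, the Strauss–Sadler form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .column import Bed, StratColumn

CLADES = (
    "Arthropoda",
    "Brachiopoda",
    "Bryozoa",
    "Chlorophyta",
    "Chordata",
    "Cnidaria",
    "Foraminifera",
    "Mollusca",
    "Radiolaria",
    "Rhodophyta",
    "Problematica",
)

QUALIFIERS = ("none", "quotes", "question", "aff", "cf", "informal")
HABITATS = ("marine", "freshwater")

OCCURRENCE_COLUMNS = (
    "taxon",
    "clade",
    "bed_id",
    "qualifier",
    "habitat",
    "palynomorph",
    "source",
    "resolved",
)


class SchemaError(ValueError):
    """An input table does not have the required headers."""


@dataclass(frozen=True)
class Occurrence:
    """One fossil record: a taxon observed in a single bed/sub-bed."""

    taxon: str
    clade: str
    bed_id: str
    qualifier: str = "none"
    habitat: str = "marine"
    is_palynomorph: bool = False
    source: str = ""
    resolved: bool = True

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValueError("occurrence with empty taxon name")
        if self.qualifier not in QUALIFIERS:
            raise ValueError(f"unknown qualifier {self.qualifier!r}")
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}")


@dataclass
class TaxonRange:
    """A taxon's stratigraphic range over the column's bed grid.

    FAD/LAD heights are the midpoints of the first and last occupied beds
    (sub-bed precision is the data's resolution; midpoints avoid spurious
    zero-length gaps between adjacent sub-beds).
    """

    taxon: str
    clade: str
    horizons: list[int]  # bed order indices with >= 1 occurrence, sorted
    fad_height: float
    lad_height: float

    @property
    def n_horizons(self) -> int:
        return len(self.horizons)

    @property
    def range_length(self) -> float:
        return self.lad_height - self.fad_height

    @property
    def is_singleton(self) -> bool:
        return len(self.horizons) == 1

    @property
    def fad_index(self) -> int:
        return self.horizons[0]

    @property
    def lad_index(self) -> int:
        return self.horizons[-1]


@dataclass(frozen=True)
class RangeCI:
    """Uniform-recovery confidence extension above a taxon's LAD."""

    taxon: str
    confidence: float
    extension: float


def load_occurrences(path, column: StratColumn) -> list[Occurrence]:
    """Load an occurrence CSV against a stratigraphic column.

    Required headers: taxon, clade, bed_id, qualifier, habitat,
    palynomorph, source, resolved.  Rows whose ``bed_id`` does not
    resolve in *column* are rejected with a located error report.
    The loader does not deduplicate; that is vetting's job.
    """
    df = pd.read_csv(path, dtype={"bed_id": str, "taxon": str})
    missing = set(OCCURRENCE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"occurrence CSV missing headers: {sorted(missing)}")
    if df.empty:
        warnings.warn("occurrence CSV is empty", stacklevel=2)
        return []
    bad = [
        (i + 2, str(b))  # +2: header line plus 1-based numbering
        for i, b in zip(df.index, df["bed_id"])
        if str(b) not in column
    ]
    if bad:
        lines = ", ".join(f"line {ln}: bed {b!r}" for ln, b in bad[:10])
        raise ValueError(f"{len(bad)} occurrence rows with unknown bed ids ({lines})")
    return [
        Occurrence(
            taxon=str(r.taxon),
            clade=str(r.clade),
            bed_id=str(r.bed_id),
            qualifier=str(r.qualifier),
            habitat=str(r.habitat),
            is_palynomorph=_as_bool(r.palynomorph),
            source=str(r.source),
            resolved=_as_bool(r.resolved),
        )
        for r in df.itertuples(index=False)
    ]


def _as_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "t", "yes", "y")
    return bool(x)


def resolve_synonyms(name: str, synonyms: dict[str, str]) -> str:
    """Follow a flat synonym map to the current name; cycles are an error."""
    seen = [name]
    while name in synonyms:
        name = synonyms[name]
        if name in seen:
            cycle = " -> ".join(seen + [name])
            raise ValueError(f"synonym cycle: {cycle}")
        seen.append(name)
    return name


def vet_occurrences(
    occs: list[Occurrence], synonyms: dict[str, str] | None = None
) -> list[Occurrence]:
    """Apply the database vetting rules.

    Freshwater and palynomorph records are removed; names are mapped
    through the synonym table; exact duplicate (taxon, bed) pairs
    collapse to one record.  Open-nomenclature qualifiers (quotes, ?,
    aff., cf., informal) are retained — ranges use those occurrences.
    Idempotent: vetting vetted output is a no-op.
    """
    synonyms = synonyms or {}
    out: list[Occurrence] = []
    seen: set[tuple[str, str]] = set()
    for occ in occs:
        if occ.habitat == "freshwater" or occ.is_palynomorph:
            continue
        name = resolve_synonyms(occ.taxon, synonyms)
        key = (name, occ.bed_id)
        if key in seen:
            continue
        seen.add(key)
        if name != occ.taxon:
            occ = Occurrence(
                name, occ.clade, occ.bed_id, occ.qualifier, occ.habitat,
                occ.is_palynomorph, occ.source, occ.resolved,
            )
        out.append(occ)
    return out


def drop_unresolved(occs: list[Occurrence]) -> tuple[list[Occurrence], int]:
    """Drop records not constrained to a single current bed/sub-bed.

    Occurrences reported in older literature against superseded bed
    schemes cannot be placed on today's sub-bed grid; their extinction
    timing is poorly constrained, so they are excluded.  Returns the
    kept records and the number dropped.
    """
    kept = [o for o in occs if o.resolved]
    return kept, len(occs) - len(kept)


def compute_ranges(occs: list[Occurrence], column: StratColumn) -> list[TaxonRange]:
    """One TaxonRange per distinct taxon, horizons sorted bottom-up."""
    by_taxon: dict[str, list[Occurrence]] = {}
    for occ in occs:
        by_taxon.setdefault(occ.taxon, []).append(occ)
    ranges = []
    for taxon in sorted(by_taxon):
        group = by_taxon[taxon]
        horizons = sorted({column.bed(o.bed_id).order_index for o in group})
        ranges.append(
            TaxonRange(
                taxon=taxon,
                clade=group[0].clade,
                horizons=horizons,
                fad_height=column.bed_at(horizons[0]).midpoint,
                lad_height=column.bed_at(horizons[-1]).midpoint,
            )
        )
    return ranges


def range_ci(rng: TaxonRange, confidence: float = 0.95) -> RangeCI:
    """Classical uniform-recovery range extension above the LAD.

    Assumes the H observed horizons are uniform over the true range;
    the extension is the C-quantile of the gap between the top
    occurrence and the true extinction height.  Undefined for
    singletons (H < 2).
    """
    if rng.n_horizons < 2:
        raise ValueError(
            f"range CI undefined for {rng.taxon!r}: needs >= 2 horizons, has {rng.n_horizons}"
        )
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    ext = rng.range_length * ((1.0 - confidence) ** (-1.0 / (rng.n_horizons - 1)) - 1.0)
    return RangeCI(taxon=rng.taxon, confidence=confidence, extension=ext)


def richness_per_bed(
    ranges: list[TaxonRange],
    window: list[Bed],
    counting: str = "range_through",
) -> pd.Series:
    """Per-bed species richness over a bed window.

    ``range_through`` (default) counts taxa whose FAD–LAD interval spans
    the bed whether or not sampled there; ``sampled`` counts only taxa
    with an occurrence in the bed.
    """
    if counting not in ("range_through", "sampled"):
        raise ValueError(f"unknown counting convention {counting!r}")
    idx = [b.order_index for b in window]
    counts = np.zeros(len(window), dtype=int)
    for rng in ranges:
        for j, i in enumerate(idx):
            if counting == "range_through":
                if rng.fad_index <= i <= rng.lad_index:
                    counts[j] += 1
            else:
                if i in rng.horizons:
                    counts[j] += 1
    return pd.Series(counts, index=[b.id for b in window], name="richness")


def extinction_rate_per_bed(ranges: list[TaxonRange], window: list[Bed]) -> pd.Series:
    """Per-bed extinction rate: LAD count over range-through richness.

    Beds with no range-through taxa get rate 0 (the 0/0 convention);
    the window's terminal bed is treated the same way, with no edge
    correction.
    """
    richness = richness_per_bed(ranges, window)
    idx = {b.order_index: j for j, b in enumerate(window)}
    lads = np.zeros(len(window), dtype=int)
    for rng in ranges:
        j = idx.get(rng.lad_index)
        if j is not None:
            lads[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(richness.to_numpy() > 0, lads / np.maximum(richness.to_numpy(), 1), 0.0)
    return pd.Series(rate, index=richness.index, name="extinction_rate")


def load_synonyms(path) -> dict[str, str]:
    """Read a synonym CSV with columns old_name, current_name."""
    df = pd.read_csv(path, dtype=str)
    missing = {"old_name", "current_name"} - set(df.columns)
    if missing:
        raise SchemaError(f"synonym CSV missing headers: {sorted(missing)}")
    return dict(zip(df["old_name"], df["current_name"]))
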