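"""Stratigraphic column: beds, sub-beds, heights, and ordering.

A column is a stack of named beds (e.g. "24d", "27c") tiling a height
interval with half-open spans [base, top).  Heights are metres, positive
up, measured from an arbitrary datum; at Meishan-style sections the
conventional datum is the base of bed 27c (the biostratigraphic
Permian/Triassic boundary).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

LITHOLOGIES = ("limestone", "silty_limestone", "clay", "other")

_BED_LABEL_RE = re.compile(r"^(\d+)([a-z]*)$")


def bed_sort_key(label: str) -> tuple[int, str]:
    """Ordering key for Meishan-style bed labels: 24a < 24b < ... < 24e < 25.

    The numeric part sorts numerically, the letter suffix lexically.
    """
    m = _BED_LABEL_RE.match(str(label).strip())
    if not m:
        raise ValueError(f"unparseable bed label: {label!r}")
    return int(m.group(1)), m.group(2)


@dataclass(frozen=True)
class Bed:
    """One lithostratigraphic bed or sub-bed."""

    id: str
    base_height: float
    top_height: float
    lithology: str = "other"
    formation: str = ""
    order_index: int = 0

    def __post_init__(self) -> None:
        if not self.base_height < self.top_height:
            raise ValueError(
                f"bed {self.id!r}: base {self.base_height} must lie below top {self.top_height}"
            )
        if self.lithology not in LITHOLOGIES:
            raise ValueError(f"bed {self.id!r}: unknown lithology {self.lithology!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.base_height + self.top_height)

    @property
    def thickness(self) -> float:
        return self.top_height - self.base_height

    def contains(self, height: float) -> bool:
        """Half-open membership: base <= height < top."""
        return self.base_height <= height < self.top_height


@dataclass
class StratColumn:
    """An ordered, gap-free stack of beds.

    Beds are stored bottom-up; ``order_index`` is the rank by base height.
    Construction validates that beds tile the column without overlap.
    """

    beds: list[Bed] = field(default_factory=list)
    _by_id: dict[str, Bed] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        beds = sorted(self.beds, key=lambda b: b.base_height)
        self.beds = [
            Bed(b.id, b.base_height, b.top_height, b.lithology, b.formation, i)
            for i, b in enumerate(beds)
        ]
        self._by_id = {}
        for bed in self.beds:
            if bed.id in self._by_id:
                raise ValueError(f"duplicate bed id {bed.id!r}")
            self._by_id[bed.id] = bed
        for lower, upper in zip(self.beds, self.beds[1:]):
            if abs(lower.top_height - upper.base_height) > 1e-9:
                raise ValueError(
                    f"beds {lower.id!r} and {upper.id!r} do not tile: "
                    f"top {lower.top_height} vs base {upper.base_height}"
                )

    def __len__(self) -> int:
        return len(self.beds)

    def __iter__(self) -> Iterator[Bed]:
        return iter(self.beds)

    def __contains__(self, bed_id: str) -> bool:
        return bed_id in self._by_id

    def bed(self, bed_id: str) -> Bed:
        try:
            return self._by_id[bed_id]
        except KeyError:
            raise KeyError(f"bed id {bed_id!r} not in column") from None

    def bed_at(self, order_index: int) -> Bed:
        return self.beds[order_index]

    def bed_for_height(self, height: float) -> Bed:
        """The bed whose half-open [base, top) span contains *height*."""
        for bed in self.beds:
            if bed.contains(height):
                return bed
        raise ValueError(f"height {height} m outside column span")

    @property
    def base(self) -> float:
        return self.beds[0].base_height

    @property
    def top(self) -> float:
        return self.beds[-1].top_height

    def window(self, low_bed: str, high_bed: str) -> list[Bed]:
        """Inclusive bed window from *low_bed* to *high_bed*."""
        lo = self.bed(low_bed).order_index
        hi = self.bed(high_bed).order_index
        if lo > hi:
            raise ValueError(f"window {low_bed!r}–{high_bed!r} is inverted")
        return self.beds[lo : hi + 1]

    @classmethod
    def from_csv(cls, path) -> "StratColumn":
        """Read a column definition CSV: bed_id, base_m, top_m, lithology, formation."""
        df = pd.read_csv(path, dtype={"bed_id": str})
        required = {"bed_id", "base_m", "top_m"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"column CSV missing headers: {sorted(missing)}")
        beds = [
            Bed(
                id=str(row.bed_id),
                base_height=float(row.base_m),
                top_height=float(row.top_m),
                lithology=getattr(row, "lithology", "other") or "other",
                formation=str(getattr(row, "formation", "") or ""),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(beds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bed_id": [b.id for b in self.beds],
                "base_m": [b.base_height for b in self.beds],
                "top_m": [b.top_height for b in self.beds],
                "lithology": [b.lithology for b in self.beds],
                "formation": [b.formation for b in self.beds],
                "order_index": [b.order_index for b in self.beds],
            }
        )


def column_from_thicknesses(
    labels: Iterable[str],
    thicknesses: Iterable[float],
    base: float = 0.0,
    lithologies: Iterable[str] | None = None,
) -> StratColumn:
    """Build a column bottom-up from bed thicknesses (metres)."""
    labels = list(labels)
    thicknesses = list(thicknesses)
    if len(labels) != len(thicknesses):
        raise ValueError("labels and thicknesses differ in length")
    liths = list(lithologies) if lithologies is not None else ["other"] * len(labels)
    beds = []
    h = base
    for lab, th, lith in zip(labels, thicknesses, liths):
        beds.append(Bed(id=str(lab), base_height=h, top_height=h + th, lithology=lith))
        h += th
    return StratColumn(beds)
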