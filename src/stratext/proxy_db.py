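"""Geochemical proxy series: height standardization, core-to-outcrop
scaling, bed-level aggregation, and segmented-curve imputation.

Proxy measurements arrive either at absolute sample heights or tied to
beds; all heights are standardized to metres relative to the section
datum (base of bed 27c at a Meishan-style section).  Core samples are
mapped onto outcrop heights through monotone tie points, because bed
thicknesses vary between the core and the outcrop.  For statistical
comparison with the fossil data, samples are aggregated to bed/sub-bed
means, and beds without samples are imputed from the proxy's fitted
segmented-regression curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .column import Bed, StratColumn
from .segmented import SegmentedFit, predict_segmented

PROXY_COLUMNS = ("proxy", "height_m", "bed_id", "value", "units", "source_section", "reference")


@dataclass
class ProxySeries:
    """One proxy as height-sorted (height, value) samples."""

    proxy: str
    heights: np.ndarray
    values: np.ndarray
    units: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.heights) != len(self.values):
            raise ValueError("heights and values differ in length")
        if len(self.heights) == 0:
            raise ValueError(f"proxy {self.proxy!r}: empty series")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"proxy {self.proxy!r}: non-finite values")
        order = np.argsort(self.heights, kind="stable")
        self.heights = self.heights[order]
        self.values = self.values[order]

    def __len__(self) -> int:
        return len(self.heights)


@dataclass
class TiePointMap:
    """Monotone (core_height, outcrop_height) correlation tie points."""

    core: np.ndarray
    outcrop: np.ndarray

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core, dtype=float)
        self.outcrop = np.asarray(self.outcrop, dtype=float)
        if len(self.core) != len(self.outcrop) or len(self.core) < 2:
            raise ValueError("tie-point map needs >= 2 aligned pairs")
        if np.any(np.diff(self.core) <= 0) or np.any(np.diff(self.outcrop) <= 0):
            raise ValueError("tie points must be strictly increasing in both coordinates")


def load_proxies(path, column: StratColumn, allow_merge: bool = False) -> dict[str, ProxySeries]:
    """Read a proxy CSV; each row has height_m OR bed_id, never both.

    One dataset per proxy: rows for the same proxy from different
    references are rejected unless *allow_merge* — mixing datasets
    collected from the same beds by different studies conflates
    inter-laboratory offsets with the signal.
    """
    df = pd.read_csv(path, dtype={"bed_id": str, "proxy": str})
    missing = {"proxy", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"proxy CSV missing headers: {sorted(missing)}")
    if "height_m" not in df.columns and "bed_id" not in df.columns:
        raise ValueError("proxy CSV needs a height_m or bed_id column")
    out: dict[str, ProxySeries] = {}
    for proxy, grp in df.groupby("proxy", sort=True):
        refs = set(grp.get("reference", pd.Series(dtype=str)).dropna())
        if len(refs) > 1 and not allow_merge:
            raise ValueError(
                f"proxy {proxy!r} mixes references {sorted(refs)}; pass allow_merge to override"
            )
        series = standardize_heights(grp, column)
        series.units = str(grp["units"].iloc[0]) if "units" in grp else ""
        series.reference = sorted(refs)[0] if refs else ""
        out[proxy] = series
    return out


def standardize_heights(samples: pd.DataFrame, column: StratColumn) -> ProxySeries:
    """Express every sample height in metres relative to the column datum.

    Absolute heights pass through; bed-referenced samples are placed at
    their bed's midpoint (unbiased under uniform within-bed deposition).
    """
    heights = []
    for row in samples.itertuples(index=False):
        h = getattr(row, "height_m", None)
        if h is not None and pd.notna(h):
            heights.append(float(h))
            continue
        bed_id = getattr(row, "bed_id", None)
        if bed_id is None or pd.isna(bed_id):
            raise ValueError("sample with neither height_m nor bed_id")
        heights.append(column.bed(str(bed_id)).midpoint)
    proxy = str(samples["proxy"].iloc[0]) if "proxy" in samples else ""
    return ProxySeries(proxy=proxy, heights=np.array(heights), values=samples["value"].to_numpy(float))


def map_core_to_outcrop(series: ProxySeries, ties: TiePointMap) -> ProxySeries:
    """Rescale core sample heights onto the outcrop height scale.

    Piecewise-linear interpolation through the tie points; heights
    beyond the first/last tie are extrapolated along the nearest
    segment with a warning.
    """
    h = series.heights
    below, above = h < ties.core[0], h > ties.core[-1]
    if np.any(below | above):
        warnings.warn(
            f"proxy {series.proxy!r}: {int(np.sum(below | above))} sample(s) outside the "
            "tie-point span; extrapolating from the nearest segment",
            stacklevel=2,
        )
    mapped = np.interp(h, ties.core, ties.outcrop)
    # np.interp clamps; extend the terminal segment slopes instead
    if np.any(below):
        s0 = (ties.outcrop[1] - ties.outcrop[0]) / (ties.core[1] - ties.core[0])
        mapped[below] = ties.outcrop[0] + s0 * (h[below] - ties.core[0])
    if np.any(above):
        s1 = (ties.outcrop[-1] - ties.outcrop[-2]) / (ties.core[-1] - ties.core[-2])
        mapped[above] = ties.outcrop[-1] + s1 * (h[above] - ties.core[-1])
    return ProxySeries(series.proxy, mapped, series.values.copy(), series.units, series.reference)


def aggregate_to_beds(series: ProxySeries, window: list[Bed]) -> pd.Series:
    """Arithmetic per-bed mean of samples in each bed's [base, top) span.

    Beds with no samples are NaN (missing); a sample exactly at a bed
    top belongs to the bed above (half-open convention).
    """
    vals = np.full(len(window), np.nan)
    for j, bed in enumerate(window):
        in_bed = (series.heights >= bed.base_height) & (series.heights < bed.top_height)
        if np.any(in_bed):
            vals[j] = series.values[in_bed].mean()
    return pd.Series(vals, index=[b.id for b in window], name=series.proxy)


def impute_missing(
    per_bed: pd.Series, fit: SegmentedFit, window: list[Bed]
) -> tuple[pd.Series, pd.Series]:
    """Fill missing bed means from the segmented-regression curve.

    Observed bed means are never altered; missing beds take the fitted
    curve's value at the bed midpoint.  Returns the completed series
    and a parallel observed/imputed tag series.
    """
    if list(per_bed.index) != [b.id for b in window]:
        raise ValueError("per-bed series index does not match window beds")
    out = per_bed.copy()
    tags = pd.Series("observed", index=per_bed.index, name="status")
    for bed in window:
        if pd.isna(per_bed[bed.id]):
            mid = bed.midpoint
            if not (fit.span[0] <= mid <= fit.span[1]):
                raise ValueError(
                    f"segmented fit span {fit.span} does not cover bed {bed.id!r} "
                    f"midpoint {mid:.3f} m"
                )
            out[bed.id] = float(predict_segmented(fit, mid)[0])
            tags[bed.id] = "imputed"
    return out, tags


def load_tie_points(path) -> TiePointMap:
    """Read a tie-point CSV with columns core_m, outcrop_m."""
    df = pd.read_csv(path)
    missing = {"core_m", "outcrop_m"} - set(df.columns)
    if missing:
        raise ValueError(f"tie-point CSV missing headers: {sorted(missing)}")
    return TiePointMap(df["core_m"].to_numpy(float), df["outcrop_m"].to_numpy(float))
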