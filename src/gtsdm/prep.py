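"""Occurrence cleaning, analogue augmentation, study extent and background.

The cleaning rules mirror standard presence-background practice for
heterogeneous database records: drop records off the raster or on nodata,
drop records on excluded land-cover classes (open water and the like), drop
records outside a supplied known-range polygon, and thin to one record per
raster cell.  The study extent is a fixed-radius buffer (default 50 km)
around the retained records, and background points are drawn uniformly from
the extent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .raster import CovariateStack
from .records import OccurrenceSet

__all__ = [
    "StudyExtent",
    "BackgroundSet",
    "filter_occurrences",
    "augment_with_analogue",
    "build_study_extent",
    "sample_background",
]

OUTSIDE_RASTER = "outside_raster"
EXCLUDED_LANDCOVER = "excluded_landcover"
OUTSIDE_KNOWN_RANGE = "outside_known_range"
DUPLICATE_CELL = "duplicate_cell"


@dataclass
class StudyExtent:
    """Buffered study area as a cell mask on the covariate stack."""

    mask: np.ndarray
    buffer_distance: float
    n_source_occurrences: int

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def contains(self, stack: CovariateStack, x, y) -> np.ndarray:
        row, col = stack.cell_index(x, y)
        ok = (row >= 0) & (col >= 0)
        out = np.zeros_like(ok)
        out[ok] = self.mask[row[ok], col[ok]]
        return out


@dataclass
class BackgroundSet:
    """Random background (pseudo-absence) points within a study extent."""

    points: np.ndarray  # (n, 2)
    seed: int

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return self.points


def filter_occurrences(
    raw: OccurrenceSet,
    stack: CovariateStack,
    exclusion_codes: set[int] | None = None,
    exclusion_layer: str | None = None,
    known_range: BaseGeometry | None = None,
) -> tuple[OccurrenceSet, pd.DataFrame]:
    """Clean an occurrence set against a covariate stack.

    Removal reasons, applied in order per record: ``outside_raster`` (off
    grid or on nodata), ``excluded_landcover`` (categorical code of
    ``exclusion_layer`` in ``exclusion_codes``), ``outside_known_range``
    (outside the optional polygon), ``duplicate_cell`` (another record
    already retained in the same raster cell).  Duplicates keep the record
    with the earliest date, ties broken by lowest input index.

    Returns the kept set and a removal report with columns x, y, reason.
    Conservation holds: len(kept) + len(report) == len(raw).
    """
    exclusion_codes = set(exclusion_codes or ())
    if exclusion_codes:
        if exclusion_layer is None:
            cats = [l.name for l in stack.layers if l.kind == "categorical"]
            if len(cats) != 1:
                raise ValueError("exclusion_layer required when codes are given")
            exclusion_layer = cats[0]
        declared = set(stack.layer(exclusion_layer).codes or ())
        bad = exclusion_codes - declared
        if bad:
            raise ValueError(f"exclusion codes {sorted(bad)} not declared on {exclusion_layer!r}")
    df = raw.records
    n = len(df)
    reasons = np.full(n, "", dtype=object)
    row, col = stack.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
    off = (row < 0) | (col < 0)
    on_grid = ~off
    nodata = np.zeros(n, dtype=bool)
    nodata[on_grid] = stack.nodata_mask[row[on_grid], col[on_grid]]
    reasons[off | nodata] = OUTSIDE_RASTER
    if exclusion_codes:
        vals = np.full(n, np.nan)
        ok = reasons == ""
        vals[ok] = stack.layer(exclusion_layer).values[row[ok], col[ok]]
        excluded = np.isin(vals, list(exclusion_codes)) & (reasons == "")
        reasons[excluded] = EXCLUDED_LANDCOVER
    if known_range is not None:
        ok = np.flatnonzero(reasons == "")
        for i in ok:
            if not known_range.covers(Point(df["x"].iloc[i], df["y"].iloc[i])):
                reasons[i] = OUTSIDE_KNOWN_RANGE
    # cell deduplication: earliest date wins, then lowest input index
    candidates = np.flatnonzero(reasons == "")
    if len(candidates):
        sub = df.iloc[candidates].copy()
        sub["_row"] = row[candidates]
        sub["_col"] = col[candidates]
        sub["_idx"] = candidates
        dates = pd.to_datetime(sub["date"], errors="coerce")
        sub["_date"] = dates.fillna(pd.Timestamp.max)
        keep = (
            sub.sort_values(["_date", "_idx"])
            .groupby(["_row", "_col"], sort=False)
            .head(1)["_idx"]
            .to_numpy()
        )
        dup = np.setdiff1d(candidates, keep)
        reasons[dup] = DUPLICATE_CELL
    kept_idx = np.flatnonzero(reasons == "")
    kept = OccurrenceSet(
        raw.species_id,
        df.iloc[kept_idx],
        notes=raw.notes + [f"filtered: kept {len(kept_idx)} of {n}"],
    )
    removed_idx = np.flatnonzero(reasons != "")
    report = pd.DataFrame(
        {
            "x": df["x"].iloc[removed_idx].to_numpy(),
            "y": df["y"].iloc[removed_idx].to_numpy(),
            "reason": reasons[removed_idx],
        }
    )
    return kept, report


def augment_with_analogue(
    occ: OccurrenceSet,
    analogue: OccurrenceSet,
    extent: StudyExtent,
    stack: CovariateStack,
) -> OccurrenceSet:
    """Append analogue-species records falling inside the study extent.

    Used when a rare species has too few records for stable validation:
    records of a closely related species within the study area are added
    (tagged ``analogue``), then the combined set is re-thinned to one record
    per cell with the original records winning ties.
    """
    inside = extent.contains(stack, analogue.records["x"].to_numpy(),
                             analogue.records["y"].to_numpy())
    extra = analogue.records.iloc[np.flatnonzero(inside)].copy()
    extra["source"] = "analogue"
    combined = pd.concat([occ.records, extra], ignore_index=True)
    merged = OccurrenceSet(occ.species_id, combined, notes=list(occ.notes))
    # original records come first, so the index tie-break keeps them; ignore
    # dates here — precedence of the modelled species is the contract
    df = merged.records
    row, col = stack.cell_index(df["x"].to_numpy(), df["y"].to_numpy())
    order = np.arange(len(df))
    keep = (
        pd.DataFrame({"_row": row, "_col": col, "_idx": order})
        .sort_values("_idx")
        .groupby(["_row", "_col"], sort=False)
        .head(1)["_idx"]
        .to_numpy()
    )
    keep.sort()
    out = OccurrenceSet(
        occ.species_id,
        df.iloc[keep],
        notes=merged.notes + [f"augmented with {int(inside.sum())} analogue records"],
    )
    return out


def build_study_extent(
    occ: OccurrenceSet,
    stack: CovariateStack,
    buffer_distance: float = 50_000.0,
) -> StudyExtent:
    """Union of discs of radius ``buffer_distance`` around the occurrences,
    intersected with valid-data cells.  A cell belongs to the extent iff its
    centre lies within the buffer."""
    if len(occ) == 0:
        raise ValueError("cannot build a study extent from zero occurrences")
    if buffer_distance < 0:
        raise ValueError("buffer_distance must be >= 0")
    rows, cols = np.indices(stack.shape)
    cx, cy = stack.cell_center(rows.ravel(), cols.ravel())
    tree = cKDTree(occ.xy)
    dist, _ = tree.query(np.column_stack([cx, cy]), k=1)
    within = (dist.reshape(stack.shape) <= buffer_distance) & stack.valid_mask
    if buffer_distance == 0:
        # degenerate buffer: exactly the cells containing occurrences
        within = np.zeros(stack.shape, dtype=bool)
        r, c = stack.cell_index(occ.xy[:, 0], occ.xy[:, 1])
        ok = (r >= 0) & (c >= 0)
        within[r[ok], c[ok]] = True
        within &= stack.valid_mask
    return StudyExtent(within, float(buffer_distance), len(occ))


def sample_background(
    extent: StudyExtent,
    stack: CovariateStack,
    n: int = 10_000,
    seed: int = 0,
    cell_unique: bool = False,
) -> BackgroundSet:
    """Draw ``n`` background points uniformly over the extent's cells.

    A cell is chosen uniformly (with replacement unless ``cell_unique``),
    then the point is positioned uniformly within it, so every point lies on
    valid data by construction.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cells = np.flatnonzero(extent.mask.ravel())
    if len(cells) == 0:
        raise ValueError("study extent is empty")
    rng = np.random.default_rng(seed)
    if cell_unique:
        if n > len(cells):
            raise ValueError(f"cell-unique sampling of {n} from {len(cells)} cells")
        chosen = rng.choice(cells, size=n, replace=False)
    else:
        chosen = rng.choice(cells, size=n, replace=True)
    row, col = np.unravel_index(chosen, stack.shape)
    cx, cy = stack.cell_center(row, col)
    x = cx + (rng.random(n) - 0.5) * stack.cell_size
    y = cy + (rng.random(n) - 0.5) * stack.cell_size
    return BackgroundSet(np.column_stack([x, y]), seed)
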