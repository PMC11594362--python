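"""Rabinowitz rarity classification from predicted occupancy surfaces.

Each modelled species is reduced to three attributes over its occupied
1-km grid cells (posterior-mean occupancy > 0.5):

* geographic range — the area of grid cells intersecting the minimum
  convex polygon around the occupied cells' square footprints (an extent-
  of-occurrence analogue; species occupying <= 2 cells use the summed cell
  area instead, since a hull of two squares would understate nothing);
* local population size — the area of occupancy (AOO), the count of
  occupied cells;
* habitat specificity — the Shannon entropy of habitat-cluster labels
  over occupied cells (0 = single habitat, ln(n_clusters) = even spread).

Median splits of the three attributes give the 2 x 2 x 2 Rabinowitz
classes from NRS (narrow range, restricted habitat, small population —
the rarest form) to WBL (the commonest).  Checklist species without
records are Not Observed (NO); species with records but no modelable
occupancy — too few detections, or occupancy never exceeding 0.5 — are
Data Deficient (DD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, box
from shapely.prepared import prep

__all__ = [
    "RarityAttributes",
    "RarityAssignment",
    "RARITY_CLASSES",
    "occupied_cells",
    "range_area",
    "habitat_specificity",
    "median_split",
    "classify",
    "assign_data_status",
    "status_summary",
]

#: the eight Rabinowitz classes plus the two data-status groups
RARITY_CLASSES = ("NRS", "NRL", "NBS", "NBL", "WRS", "WRL", "WBS", "WBL")
STATUSES = ("NO", "DD") + RARITY_CLASSES


@dataclass
class RarityAttributes:
    species: str
    occupied_cells: set[tuple[int, int]]
    range_area_km2: float
    aoo: int
    hs: float

    def __post_init__(self) -> None:
        if self.aoo != len(self.occupied_cells):
            raise ValueError("aoo must equal the occupied-cell count")
        if self.hs < 0:
            raise ValueError("habitat specificity entropy must be >= 0")


@dataclass
class RarityAssignment:
    species: str
    status: str
    splits: dict | None = None  # {'range': 'narrow'|'wide', ...} when classified

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.splits is None) != (self.status in ("NO", "DD")):
            raise ValueError("splits must be present iff the species is classified")


def occupied_cells(
    psi_mean: np.ndarray,
    coords: np.ndarray,
    threshold: float = 0.5,
) -> list[set[tuple[int, int]]]:
    """Cells with posterior-mean occupancy strictly above the threshold.

    ``psi_mean`` is (N, J); ``coords`` the (J, 2) integer cell indices.
    psi = threshold exactly is *not* occupied.
    """
    out = []
    for i in range(psi_mean.shape[0]):
        sel = np.flatnonzero(psi_mean[i] > threshold)
        out.append({(int(coords[j, 0]), int(coords[j, 1])) for j in sel})
    return out


def _cell_square(x: int, y: int, side: float = 1.0):
    return box(x * side, y * side, (x + 1) * side, (y + 1) * side)


def range_area(occupied: set[tuple[int, int]], cell_area_km2: float = 1.0) -> float:
    """Geographic-range area from the minimum convex polygon of cell footprints.

    The MCP is the convex hull of the union of the occupied cells' unit
    squares (footprints, not centroids, so collinear cells still span a
    positive area); the range is the number of grid cells whose square
    intersects the hull, times the cell area.  Species with <= 2 occupied
    cells use the summed occupied-cell area directly.
    """
    if not occupied:
        raise ValueError("empty occupied set; species should be routed to DD")
    if len(occupied) <= 2:
        return len(occupied) * cell_area_km2
    side = np.sqrt(cell_area_km2)
    hull = MultiPolygon([_cell_square(x, y, side) for x, y in occupied]).convex_hull
    minx, miny, maxx, maxy = hull.bounds
    x0, x1 = int(np.floor(minx / side)), int(np.ceil(maxx / side))
    y0, y1 = int(np.floor(miny / side)), int(np.ceil(maxy / side))
    prepared = prep(hull)
    count = 0
    for x in range(x0, x1):
        for y in range(y0, y1):
            cell = _cell_square(x, y, side)
            if prepared.intersects(cell) and hull.intersection(cell).area > 1e-12:
                count += 1
    return count * cell_area_km2


def habitat_specificity(
    occupied: set[tuple[int, int]],
    cluster_labels: dict[tuple[int, int], int],
) -> float:
    """Shannon entropy -sum p_hc ln p_hc of habitat clusters over occupied cells."""
    if not occupied:
        raise ValueError("empty occupied set; species should be routed to DD")
    labels = [cluster_labels[c] for c in occupied]
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def median_split(values: np.ndarray | list[float]) -> np.ndarray:
    """Binary upper/lower grouping at the sample median.

    Returns a boolean array: True = strictly above the median (the
    wide/broad/large group); ties at the median fall in the lower (rarer)
    group, mirroring the strict occupancy threshold.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("median split needs at least 2 species")
    med = np.median(values)
    upper = values > med
    if not upper.any():
        warnings.warn("degenerate median split: all values in the lower group", stacklevel=2)
    return upper


def classify(attributes: list[RarityAttributes]) -> list[RarityAssignment]:
    """Median-split the three attributes and map to the eight rarity classes."""
    if len(attributes) < 2:
        raise ValueError("classification needs at least 2 species")
    wide = median_split([a.range_area_km2 for a in attributes])
    broad = median_split([a.hs for a in attributes])
    large = median_split([a.aoo for a in attributes])
    out = []
    for a, w, b, l in zip(attributes, wide, broad, large):
        status = ("W" if w else "N") + ("B" if b else "R") + ("L" if l else "S")
        out.append(
            RarityAssignment(
                species=a.species,
                status=status,
                splits={
                    "range": "wide" if w else "narrow",
                    "habitat": "broad" if b else "restricted",
                    "population": "large" if l else "small",
                },
            )
        )
    return out


def assign_data_status(
    checklist: list[str],
    detection_counts: dict[str, int],
    modeled_attributes: list[RarityAttributes],
) -> list[RarityAssignment]:
    """Full-checklist partition into NO / DD / eight rarity classes.

    NO: never recorded; DD: recorded but not modelable (filtered out) or
    modeled with no occupied cell (max occupancy <= 0.5 everywhere, i.e.
    absent from ``modeled_attributes`` despite detections, or present with
    an empty occupied set).  Everything else is classified.
    """
    known = set(checklist)
    by_name = {a.species: a for a in modeled_attributes}
    missing = set(by_name) - known
    if missing:
        raise ValueError(f"modeled species missing from checklist: {sorted(missing)}")

    classifiable = [a for a in by_name.values() if a.occupied_cells]
    classified = {a.species: r for a, r in zip(classifiable, classify(classifiable))} if len(classifiable) >= 2 else {}

    out = []
    for sp in checklist:
        if detection_counts.get(sp, 0) == 0:
            out.append(RarityAssignment(species=sp, status="NO"))
        elif sp in classified:
            out.append(classified[sp])
        else:
            out.append(RarityAssignment(species=sp, status="DD"))
    return out


def status_summary(assignments: list[RarityAssignment] | list[str]) -> pd.DataFrame:
    """Status x count x percent table over a full checklist partition.

    Accepts assignment objects or bare status strings (useful for
    summarizing an externally supplied status vector).
    """
    total = len(assignments)
    rows = []
    counts = {s: 0 for s in STATUSES}
    for a in assignments:
        counts[a if isinstance(a, str) else a.status] += 1
    for s in STATUSES:
        rows.append({"status": s, "n": counts[s], "percent": round(100.0 * counts[s] / total, 1)})
    return pd.DataFrame(rows)
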