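"""Detection/non-detection histories on a 1-km grid, with survey filters.

Presence records are collapsed onto integer grid-cell indices and survey
replicates; the resulting species x site x replicate binary array is the
input of the occupancy models.  Filtering follows the survey-preparation
rules: species with fewer than three detections are unmodelable, and
zero-detection sites are dropped unless their total visit effort is high
enough (above the upper 95% threshold) to be informative absences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PresenceRecord",
    "DetectionArray",
    "CovariateCandidate",
    "build_detection_histories",
    "filter_species",
    "filter_sites",
    "screen_covariates",
    "standardize",
    "from_synthetic",
]


@dataclass(frozen=True)
class PresenceRecord:
    species: str
    x: int
    y: int
    replicate: str
    visit_count: int = 1

    def __post_init__(self) -> None:
        if self.visit_count < 1:
            raise ValueError("visit_count must be >= 1")


@dataclass
class DetectionArray:
    """Binary detections y[i, j, k] with per-(site, replicate) visit counts.

    A (site, replicate) cell with ``visits == 0`` was never surveyed; its y
    entries are structurally zero and are skipped by the model likelihood.
    """

    y: np.ndarray  # (N, J, K) int8
    visits: np.ndarray  # (J, K) int
    species_names: list[str]
    site_coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), int))

    def __post_init__(self) -> None:
        N, J, K = self.y.shape
        if self.visits.shape != (J, K):
            raise ValueError("visits shape must match (J, K)")
        if np.any((self.visits == 0) & (self.y.sum(axis=0) > 0)):
            raise ValueError("detections recorded in unsurveyed (visits=0) cells")

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_sites(self) -> int:
        return self.y.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.y.shape[2]

    def detections_per_species(self) -> np.ndarray:
        return self.y.sum(axis=(1, 2))


@dataclass
class CovariateCandidate:
    name: str
    usage_count: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.usage_count < 0:
            raise ValueError("usage_count must be >= 0")
        self.values = np.asarray(self.values, dtype=float)


def build_detection_histories(
    records: list[PresenceRecord], replicate_order: list[str]
) -> DetectionArray:
    """Aggregate presence records into detection histories.

    One site per distinct grid cell, sorted by (x, y); y[i, j, k] = 1 iff at
    least one record of species i fell in cell j during replicate k (duplicate
    records collapse).  Visit counts per (cell, replicate) aggregate by
    maximum over records, treating each record as a survey-event summary.
    """
    k_index = {label: k for k, label in enumerate(replicate_order)}
    for r in records:
        if r.replicate not in k_index:
            raise ValueError(f"unknown replicate label: {r.replicate!r}")

    cells = sorted({(r.x, r.y) for r in records})
    j_index = {c: j for j, c in enumerate(cells)}
    species = sorted({r.species for r in records})
    s_index = {s: i for i, s in enumerate(species)}

    N, J, K = len(species), len(cells), len(replicate_order)
    y = np.zeros((N, J, K), dtype=np.int8)
    visits = np.zeros((J, K), dtype=int)
    for r in records:
        j, k = j_index[(r.x, r.y)], k_index[r.replicate]
        y[s_index[r.species], j, k] = 1
        visits[j, k] = max(visits[j, k], r.visit_count)
    return DetectionArray(
        y=y,
        visits=visits,
        species_names=species,
        site_coords=np.array(cells, dtype=int).reshape(J, 2),
    )


def filter_species(
    arr: DetectionArray, min_detections: int = 3
) -> tuple[DetectionArray, list[str]]:
    """Drop species with fewer than ``min_detections`` total detections."""
    if min_detections < 1:
        raise ValueError("min_detections must be >= 1")
    counts = arr.detections_per_species()
    keep = counts >= min_detections
    removed = [s for s, k in zip(arr.species_names, keep) if not k]
    out = replace(
        arr,
        y=arr.y[keep],
        species_names=[s for s, k in zip(arr.species_names, keep) if k],
    )
    return out, removed


def filter_sites(
    arr: DetectionArray, effort_quantile: float = 0.95
) -> tuple[DetectionArray, list[int]]:
    """Drop zero-detection sites unless their effort is in the upper tail.

    Sites with at least one detection are always kept.  An all-zero site
    survives only if its total visit count strictly exceeds the
    ``effort_quantile`` quantile (linear interpolation) of total visits over
    all sites.  Returns the filtered array and the original indices of the
    retained empty sites.
    """
    if not 0 < effort_quantile < 1:
        raise ValueError("effort_quantile must lie in (0, 1)")
    total_visits = arr.visits.sum(axis=1)
    threshold = np.quantile(total_visits, effort_quantile)
    has_detection = arr.y.sum(axis=(0, 2)) > 0
    high_effort = total_visits > threshold
    keep = has_detection | high_effort
    retained_empty = [int(j) for j in np.flatnonzero(~has_detection & high_effort)]
    out = replace(
        arr,
        y=arr.y[:, keep, :],
        visits=arr.visits[keep],
        site_coords=arr.site_coords[keep] if len(arr.site_coords) else arr.site_coords,
    )
    return out, retained_empty


def screen_covariates(
    candidates: list[CovariateCandidate],
    min_usage: int = 4,
    corr_threshold: float = 0.75,
) -> list[str]:
    """Literature-usage and collinearity screening of candidate covariates.

    Candidates used in fewer than ``min_usage`` prior studies are dropped.
    Then, while any surviving pair has |Pearson r| > ``corr_threshold``, the
    lower-usage member of the first offending pair (input order) is dropped;
    usage ties drop the later-input member.  Constant covariates (undefined
    correlation) are dropped with a warning.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    lengths = {len(c.values) for c in candidates}
    if len(lengths) > 1:
        raise ValueError("all candidate value vectors must have equal length")

    kept: list[CovariateCandidate] = []
    for c in candidates:
        if c.usage_count < min_usage:
            continue
        if np.std(c.values) == 0:
            warnings.warn(f"covariate {c.name!r} is constant; dropped", stacklevel=2)
            continue
        kept.append(c)

    def first_offending() -> tuple[int, int] | None:
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                r = np.corrcoef(kept[a].values, kept[b].values)[0, 1]
                if abs(r) > corr_threshold:
                    return a, b
        return None

    while (pair := first_offending()) is not None:
        a, b = pair
        # drop the less-supported covariate; on a tie the later-input one
        drop = b if kept[a].usage_count >= kept[b].usage_count else a
        kept.pop(drop)
    return [c.name for c in kept]


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each column (population sd); returns (X_std, means, sds)."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise ValueError(f"constant covariate column(s): {bad.tolist()}")
    return (X - means) / sds, means, sds


def from_synthetic(dataset) -> DetectionArray:
    """View a simulated community as a DetectionArray."""
    return DetectionArray(
        y=dataset.y.astype(np.int8),
        visits=dataset.visits,
        species_names=list(dataset.species_names),
        site_coords=dataset.coords,
    )
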