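"""Protected-area records and cohort inclusion filters.

A PA enters the analysed cohort only if it (1) has a recorded GIS area of at
least 10 km^2 (small PAs are of the same order as a single 1 km land-cover
pixel, so zonal estimates there are unreliable), (2) contains at least ten
1-km^2 pixels classed as forest, and (3) has forest pixels covering at least
50% of its recorded area — i.e. it is plausibly a *forest* PA.  The rules are
applied in that order and each removed PA carries the first rule it failed,
giving an auditable removal log.

The area rule is inclusive (>= 10 km^2): the smallest PAs the analysis is
meant to admit are exactly 10 km^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .grids import Grid, zonal_stats

__all__ = [
    "IUCN_CATEGORIES",
    "PARecord",
    "RemovalReason",
    "FilterOutcome",
    "forest_predicate",
    "count_forest_pixels",
    "apply_inclusion_filters",
    "outcomes_to_frame",
]

IUCN_CATEGORIES = ("Ia", "Ib", "II", "III", "IV", "V", "VI")
_STATUSES = ("designated", "proposed")


@dataclass(frozen=True)
class PARecord:
    """One protected area: polygon plus WDPA-style attributes."""

    pa_id: str
    name: str
    country: str
    iucn_cat: str
    status: str
    gis_area_km2: float
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.iucn_cat not in IUCN_CATEGORIES:
            raise ValueError(f"unknown IUCN category {self.iucn_cat!r}")
        if self.status not in _STATUSES:
            raise ValueError(f"status must be one of {_STATUSES}, got {self.status!r}")
        if self.gis_area_km2 <= 0:
            raise ValueError("recorded GIS area must be positive")
        if not self.geometry.is_valid:
            raise ValueError(f"invalid geometry for PA {self.pa_id}")


class RemovalReason(str, Enum):
    NONE = "none"
    TOO_SMALL = "too_small"
    TOO_FEW_FOREST_PIXELS = "too_few_forest_pixels"
    FOREST_FRACTION_BELOW_HALF = "forest_fraction_below_half"
    STATUS_EXCLUDED = "status_excluded"


@dataclass(frozen=True)
class FilterOutcome:
    """Result of the inclusion rules for one PA."""

    pa: PARecord
    kept: bool
    reason: RemovalReason
    forest_pixels: int
    forest_fraction: float  # forest pixel area / recorded GIS area, capped at 1

    def __post_init__(self) -> None:
        assert self.kept == (self.reason is RemovalReason.NONE)


def forest_predicate(values: np.ndarray) -> np.ndarray:
    """True for land-cover classes 1-8 (the forest classes)."""
    return (values >= 1) & (values <= 8)


def count_forest_pixels(landcover: Grid, pa: PARecord) -> int:
    """Number of forest-class pixels whose centres fall inside the PA."""
    if landcover.kind != "categorical":
        raise ValueError("count_forest_pixels requires a categorical land-cover grid")
    res = zonal_stats(landcover, pa.geometry, predicate=forest_predicate)
    return res.predicate_count or 0


def apply_inclusion_filters(
    records: list[PARecord],
    landcover: Grid,
    area_threshold_km2: float = 10.0,
    min_forest_pixels: int = 10,
    min_forest_fraction: float = 0.5,
    coarse_pixel_area_km2: float | None = None,
    include_proposed: bool = True,
) -> list[FilterOutcome]:
    """Apply the three inclusion rules, in order, to every PA.

    ``min_forest_pixels`` counts 1-km^2-equivalent forest pixels.  When the
    supplied land-cover grid is at a finer working resolution, pass the
    original coarse pixel area via ``coarse_pixel_area_km2`` and the pixel
    count is converted through forest *area*; with ``None`` the raw pixel
    count of the supplied grid is used.

    The forest fraction (forest pixel area over recorded GIS area) can exceed
    1 when the rasterised forest slightly overshoots the vector area; it is
    capped at 1.0 so the downstream correction multiplier never drops below 1.
    """
    if area_threshold_km2 <= 0 or min_forest_pixels <= 0 or min_forest_fraction <= 0:
        raise ValueError("filter thresholds must be positive")
    if landcover.kind != "categorical":
        raise ValueError("inclusion filters require a categorical land-cover grid")
    outcomes: list[FilterOutcome] = []
    pixel_area_km2 = landcover.pixel_area / 1e6
    for pa in records:
        res = zonal_stats(landcover, pa.geometry, predicate=forest_predicate)
        n_forest = res.predicate_count or 0
        forest_area_km2 = n_forest * pixel_area_km2
        if coarse_pixel_area_km2 is not None:
            eff_pixels = forest_area_km2 / coarse_pixel_area_km2
        else:
            eff_pixels = n_forest
        fraction = min(forest_area_km2 / pa.gis_area_km2, 1.0)
        if not include_proposed and pa.status == "proposed":
            reason = RemovalReason.STATUS_EXCLUDED
        elif pa.gis_area_km2 < area_threshold_km2:
            reason = RemovalReason.TOO_SMALL
        elif eff_pixels < min_forest_pixels:
            reason = RemovalReason.TOO_FEW_FOREST_PIXELS
        elif fraction < min_forest_fraction:
            reason = RemovalReason.FOREST_FRACTION_BELOW_HALF
        else:
            reason = RemovalReason.NONE
        outcomes.append(FilterOutcome(
            pa=pa,
            kept=reason is RemovalReason.NONE,
            reason=reason,
            forest_pixels=n_forest,
            forest_fraction=fraction,
        ))
    return outcomes


def outcomes_to_frame(outcomes: list[FilterOutcome]) -> pd.DataFrame:
    """Audit table: one row per input PA with its kept flag and reason."""
    return pd.DataFrame([
        {
            "pa_id": o.pa.pa_id,
            "name": o.pa.name,
            "country": o.pa.country,
            "iucn_cat": o.pa.iucn_cat,
            "status": o.pa.status,
            "gis_area_km2": o.pa.gis_area_km2,
            "kept": o.kept,
            "reason": o.reason.value,
            "forest_pixels": o.forest_pixels,
            "forest_fraction": o.forest_fraction,
        }
        for o in outcomes
    ])
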