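"""Protected-area records, protection time frames, and protected-range stats.

PA records mimic the structure of the World Database on Protected Areas:
either a boundary polygon or a centroid with a reported extent, an
establishment year, a status flag and an IUCN management category. Records
survive filtering only if they currently exist, carry an assigned IUCN
category, and are spatially explicit; centroid-only records are realized as
circles of the reported area (r = sqrt(A/pi)).

Every pixel is then assigned one of four protection time frames:

* ``P70``    — covered by a PA established in or before the past reference
               year (1970) and still existing;
* ``P15``    — covered only by PAs established after 1970 and by the recent
               reference year (2015);
* ``BUFFER`` — within one pixel (Moore neighbourhood, ~10 km) of any PA,
               regardless of its vintage, but not protected itself;
* ``NEVER``  — none of the above.

Precedence in overlaps is P70 > P15 > BUFFER > NEVER (earliest protection
wins). The buffer is carved out of NEVER only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .grid import BoolRaster, GridSpec, dilate_one_pixel, rasterize
from .rangechange import RangeChangeMap

logger = logging.getLogger(__name__)

__all__ = [
    "PARecord",
    "ProtectionCategory",
    "ProtectionMap",
    "SpeciesProtection",
    "filter_pa",
    "centroid_to_circle",
    "classify_protection",
    "species_protection_summary",
    "loss_by_protection",
    "pa_records_to_geojson",
    "pa_records_from_geojson",
]

IUCN_CATEGORIES = ("Ia", "Ib", "II", "III", "IV", "V", "VI", "unassigned")


class ProtectionCategory(IntEnum):
    NEVER = 0
    BUFFER = 1
    P15 = 2
    P70 = 3


@dataclass
class PARecord:
    pa_id: str
    year_established: int
    status: str = "current"  # current | other
    iucn_category: str = "unassigned"
    geometry: Polygon | None = None
    centroid: tuple[float, float] | None = None
    reported_area_km2: float | None = None

    def is_spatial(self) -> bool:
        return self.geometry is not None or (
            self.centroid is not None
            and self.reported_area_km2 is not None
            and self.reported_area_km2 > 0
        )


@dataclass
class ProtectionMap:
    grid: GridSpec
    categories: np.ndarray  # int codes from ProtectionCategory

    def mask(self, *cats: ProtectionCategory) -> BoolRaster:
        sel = np.isin(self.categories, [int(c) for c in cats])
        return BoolRaster(self.grid, sel)


@dataclass
class SpeciesProtection:
    species_id: str
    extent_P70_km2: float
    extent_P15only_km2: float
    prop_protected_1970: float  # NaN when past range empty
    prop_protected_2015: float  # NaN when recent range empty

    @property
    def delta_prop(self) -> float:
        return self.prop_protected_2015 - self.prop_protected_1970


def filter_pa(records: Iterable[PARecord]) -> list[PARecord]:
    """Keep only currently existing, IUCN-categorized, spatially explicit PAs."""
    kept: list[PARecord] = []
    for rec in records:
        if rec.status != "current":
            logger.info("PA %s dropped: status %r is not current", rec.pa_id, rec.status)
        elif rec.iucn_category not in IUCN_CATEGORIES or rec.iucn_category == "unassigned":
            logger.info("PA %s dropped: no assigned IUCN category", rec.pa_id)
        elif not rec.is_spatial():
            logger.info("PA %s dropped: no spatially explicit information", rec.pa_id)
        else:
            kept.append(rec)
    return kept


def centroid_to_circle(
    centroid: tuple[float, float], reported_area_km2: float, n_vertices: int = 64
) -> Polygon:
    """Realize a centroid-only PA as a regular 64-gon of the reported area's
    equivalent circle, radius r = sqrt(A / pi)."""
    if reported_area_km2 is None or reported_area_km2 <= 0:
        raise ValueError("centroid-only PA needs a positive reported area")
    r = math.sqrt(reported_area_km2 / math.pi)
    theta = 2.0 * math.pi * np.arange(n_vertices) / n_vertices
    x = centroid[0] + r * np.cos(theta)
    y = centroid[1] + r * np.sin(theta)
    return Polygon(zip(x, y))


def _realize_geometry(rec: PARecord) -> Polygon:
    if rec.geometry is not None:
        return rec.geometry
    return centroid_to_circle(rec.centroid, rec.reported_area_km2)


def classify_protection(
    records: Sequence[PARecord],
    grid: GridSpec,
    year_past: int = 1970,
    year_recent: int = 2015,
) -> ProtectionMap:
    """Assign every pixel a protection time frame.

    Records are assumed pre-filtered and continuously existing since their
    establishment year; ``year_established <= year_past`` means protected
    through the whole study window (P70).
    """
    p70 = np.zeros(grid.shape, dtype=bool)
    p15 = np.zeros(grid.shape, dtype=bool)
    for rec in records:
        if rec.year_established > year_recent:
            continue
        mask = rasterize(_realize_geometry(rec), grid).values
        if rec.year_established <= year_past:
            p70 |= mask
        else:
            p15 |= mask
    protected = p70 | p15
    buffer_band = (
        dilate_one_pixel(BoolRaster(grid, protected)).values & ~protected
    )
    cat = np.full(grid.shape, int(ProtectionCategory.NEVER), dtype=np.int8)
    cat[buffer_band] = ProtectionCategory.BUFFER
    cat[p15] = ProtectionCategory.P15
    cat[p70] = ProtectionCategory.P70
    return ProtectionMap(grid, cat)


def species_protection_summary(
    past: BoolRaster, recent: BoolRaster, pmap: ProtectionMap, species_id: str = ""
) -> SpeciesProtection:
    """Protected extents and proportions of one species' range in both epochs.

    The 1970 snapshot counts only continuously protected pixels (P70) within
    the past range; the 2015 snapshot counts all protected pixels (P70+P15)
    within the recent range. Empty ranges yield NaN proportions.
    """
    if past.grid != pmap.grid or recent.grid != pmap.grid:
        raise ValueError("rasters and protection map must share one grid")
    a = pmap.grid.pixel_area_km2
    p70 = pmap.mask(ProtectionCategory.P70)
    prot_2015 = pmap.mask(ProtectionCategory.P70, ProtectionCategory.P15)
    p15_only = pmap.mask(ProtectionCategory.P15)
    n_past = past.count()
    n_recent = recent.count()
    extent_p70 = (past & p70).count() * a
    extent_p15 = (recent & p15_only).count() * a
    if n_past == 0 or n_recent == 0:
        warnings.warn(
            f"species {species_id!r}: empty range, protected proportions undefined",
            stacklevel=2,
        )
    prop_1970 = (past & p70).count() / n_past if n_past else float("nan")
    prop_2015 = (recent & prot_2015).count() / n_recent if n_recent else float("nan")
    return SpeciesProtection(
        species_id=species_id,
        extent_P70_km2=extent_p70,
        extent_P15only_km2=extent_p15,
        prop_protected_1970=prop_1970,
        prop_protected_2015=prop_2015,
    )


@dataclass
class LossDecomposition:
    """Three-way split of one species' lost range by protection time frame.

    Buffer pixels count in the never-protected stratum: the decomposition has
    exactly three classes (continuously protected / protected later / never
    protected).
    """

    area_lost_P70_km2: float
    area_lost_P15_km2: float
    area_lost_never_km2: float
    share_P70: float
    share_P15: float
    share_never: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.share_never)


def loss_by_protection(change: RangeChangeMap, pmap: ProtectionMap) -> LossDecomposition:
    if change.grid != pmap.grid:
        raise ValueError("change map and protection map must share one grid")
    a = pmap.grid.pixel_area_km2
    lost = change.lost.values
    n_p70 = int((lost & (pmap.categories == ProtectionCategory.P70)).sum())
    n_p15 = int((lost & (pmap.categories == ProtectionCategory.P15)).sum())
    n_never = int(
        (
            lost
            & np.isin(pmap.categories, [ProtectionCategory.NEVER, ProtectionCategory.BUFFER])
        ).sum()
    )
    total = n_p70 + n_p15 + n_never
    if total == 0:
        nan = float("nan")
        return LossDecomposition(0.0, 0.0, 0.0, nan, nan, nan)
    return LossDecomposition(
        area_lost_P70_km2=n_p70 * a,
        area_lost_P15_km2=n_p15 * a,
        area_lost_never_km2=n_never * a,
        share_P70=n_p70 / total,
        share_P15=n_p15 / total,
        share_never=n_never / total,
    )


# ---------------------------------------------------------------------------
# GeoJSON round trip
# ---------------------------------------------------------------------------

def pa_records_to_geojson(records: Sequence[PARecord]) -> dict:
    features = []
    for rec in records:
        props = {
            "pa_id": rec.pa_id,
            "year_established": rec.year_established,
            "status": rec.status,
            "iucn_category": rec.iucn_category,
            "reported_area_km2": rec.reported_area_km2,
        }
        if rec.geometry is not None:
            geom = {
                "type": "Polygon",
                "coordinates": [
                    [list(c) for c in rec.geometry.exterior.coords]
                ]
                + [[list(c) for c in ring.coords] for ring in rec.geometry.interiors],
            }
        else:
            geom = {"type": "Point", "coordinates": list(rec.centroid)}
        features.append({"type": "Feature", "geometry": geom, "properties": props})
    return {"type": "FeatureCollection", "features": features}


def pa_records_from_geojson(obj: dict) -> list[PARecord]:
    records = []
    for feat in obj["features"]:
        props = feat["properties"]
        geom = feat["geometry"]
        rec = PARecord(
            pa_id=str(props["pa_id"]),
            year_established=int(props["year_established"]),
            status=props.get("status", "current"),
            iucn_category=props.get("iucn_category", "unassigned"),
            reported_area_km2=props.get("reported_area_km2"),
        )
        if geom["type"] == "Polygon":
            rings = geom["coordinates"]
            rec.geometry = Polygon(rings[0], rings[1:])
        elif geom["type"] == "Point":
            rec.centroid = tuple(geom["coordinates"])
        else:
            raise ValueError(f"unsupported PA geometry type {geom['type']!r}")
        records.append(rec)
    return records
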