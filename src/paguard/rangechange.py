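"""Range-change accounting: overlay past vs recent presence, richness, and
the per-pixel local-extinction (extirpation) rate.

For each species, the past and recent presence masks partition the grid into
LOST (past only), RETAINED (both), GAINED (recent only) and ABSENT pixels.
Stacking per-species layers yields richness maps, and the extirpation rate
of a pixel is the fraction of its past-present species that lost the pixel:
gains never offset losses, and pixels with no past species carry a missing
value rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import BoolRaster, GridSpec

__all__ = [
    "ChangeCategory",
    "RangeChangeMap",
    "RichnessMap",
    "ExtinctionRateMap",
    "classify_change",
    "richness",
    "extinction_rate",
    "representation_ratio",
    "species_change_summary",
    "summaries_to_frame",
]


class ChangeCategory(IntEnum):
    ABSENT = 0
    LOST = 1
    RETAINED = 2
    GAINED = 3


@dataclass
class RangeChangeMap:
    grid: GridSpec
    categories: np.ndarray  # int codes from ChangeCategory

    @property
    def lost(self) -> BoolRaster:
        return BoolRaster(self.grid, self.categories == ChangeCategory.LOST)

    @property
    def retained(self) -> BoolRaster:
        return BoolRaster(self.grid, self.categories == ChangeCategory.RETAINED)

    @property
    def gained(self) -> BoolRaster:
        return BoolRaster(self.grid, self.categories == ChangeCategory.GAINED)


@dataclass
class RichnessMap:
    grid: GridSpec
    counts: np.ndarray  # non-negative ints


@dataclass
class ExtinctionRateMap:
    """Per-pixel extirpation rate in [0, 1]; NaN where past richness is 0."""

    grid: GridSpec
    rates: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rates)


def classify_change(past: BoolRaster, recent: BoolRaster) -> RangeChangeMap:
    """Overlay one species' past and recent presence into the 4-way partition."""
    if past.grid != recent.grid:
        raise ValueError("past and recent rasters must share one grid")
    cat = np.full(past.grid.shape, int(ChangeCategory.ABSENT), dtype=np.int8)
    cat[past.values & ~recent.values] = ChangeCategory.LOST
    cat[past.values & recent.values] = ChangeCategory.RETAINED
    cat[~past.values & recent.values] = ChangeCategory.GAINED
    return RangeChangeMap(past.grid, cat)


def richness(presences: Sequence[BoolRaster]) -> RichnessMap:
    """Per-pixel count of co-occurring species across presence layers."""
    presences = list(presences)
    if not presences:
        raise ValueError("richness requires at least one presence layer")
    grid = presences[0].grid
    counts = np.zeros(grid.shape, dtype=np.int64)
    for layer in presences:
        if layer.grid != grid:
            raise ValueError("all presence layers must share one grid")
        counts += layer.values
    return RichnessMap(grid, counts)


def extinction_rate(past_rich: RichnessMap, lost_rich: RichnessMap) -> ExtinctionRateMap:
    """Ratio of species lost from a pixel to species present there in the past.

    Defined only where at least one species was present in the past; gains do
    not enter the statistic.
    """
    if past_rich.grid != lost_rich.grid:
        raise ValueError("richness maps must share one grid")
    past = past_rich.counts.astype(float)
    lost = lost_rich.counts.astype(float)
    if np.any(lost > past):
        raise ValueError("lost richness exceeds past richness at some pixel")
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(past >= 1, lost / past, np.nan)
    return ExtinctionRateMap(past_rich.grid, rates)


def representation_ratio(
    sampled_recent_rich: RichnessMap, total_recent_rich: RichnessMap
) -> np.ndarray:
    """Per-pixel share of the extant fauna covered by the sampled species."""
    if sampled_recent_rich.grid != total_recent_rich.grid:
        raise ValueError("richness maps must share one grid")
    sampled = sampled_recent_rich.counts.astype(float)
    total = total_recent_rich.counts.astype(float)
    if np.any(sampled > total):
        raise ValueError("sampled richness exceeds total richness at some pixel")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(total >= 1, sampled / total, np.nan)


@dataclass
class SpeciesChangeSummary:
    species_id: str
    area_past_km2: float
    area_lost_km2: float
    area_gained_km2: float
    pct_lost: float
    pct_gained: float
    net_class: str  # contraction | expansion | no_change


def species_change_summary(change: RangeChangeMap, grid: GridSpec, species_id: str = "") -> SpeciesChangeSummary:
    """Per-species range-change bookkeeping on the 0-100 percentage scale.

    ``no_change`` requires bit-exact equality of past and recent masks
    (zero lost and zero gained); a species losing and gaining equal areas is
    classed ``no_change`` by net sign only when both are zero — otherwise the
    sign of (gained - lost) decides, with exact net zero also ``no_change``.
    """
    a = grid.pixel_area_km2
    n_lost = change.lost.count()
    n_ret = change.retained.count()
    n_gain = change.gained.count()
    n_past = n_lost + n_ret
    if n_past == 0:
        raise ValueError("species absent in the past epoch: summary undefined")
    area_past = n_past * a
    area_lost = n_lost * a
    area_gained = n_gain * a
    net = n_gain - n_lost
    net_class = "expansion" if net > 0 else ("contraction" if net < 0 else "no_change")
    return SpeciesChangeSummary(
        species_id=species_id,
        area_past_km2=area_past,
        area_lost_km2=area_lost,
        area_gained_km2=area_gained,
        pct_lost=100.0 * n_lost / n_past,
        pct_gained=100.0 * n_gain / n_past,
        net_class=net_class,
    )


def summaries_to_frame(summaries: Iterable[SpeciesChangeSummary]) -> pd.DataFrame:
    cols = [
        "species_id",
        "area_past_km2",
        "area_lost_km2",
        "area_gained_km2",
        "pct_lost",
        "pct_gained",
        "net_class",
    ]
    return pd.DataFrame([vars(s) for s in summaries], columns=cols)
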