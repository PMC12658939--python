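"""Matching substrate: bioanthrome classification and the pixel table.

Bioanthromes are the unique observed combinations of a biome class (natural
ecoregion aggregate) and an anthrome class (anthropogenic land-use class);
they act as the categorical landscape stratifier in matching. Continuous
covariates (elevation, slope, population density, travel time to the nearest
city) are coarsened at the quartile cut points of the eligible-pixel
distribution, which reduces covariate variability and eases balance.

The pixel table is the unit-of-analysis container: one row per pixel with a
defined extirpation rate and complete covariates, carrying the outcome
(% species lost, 0-100), the protection time frame, raw and binned
covariates and the bioanthrome id.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec
from .protection import ProtectionCategory, ProtectionMap
from .rangechange import ExtinctionRateMap

logger = logging.getLogger(__name__)

__all__ = [
    "CategoricalRaster",
    "build_bioanthromes",
    "quartile_bin",
    "assemble_pixel_table",
    "CONTINUOUS_COVARIATES",
    "PROTECTION_LABELS",
]

CONTINUOUS_COVARIATES = ("elevation", "slope", "pop_density", "travel_time")

PROTECTION_LABELS = {
    int(ProtectionCategory.NEVER): "NEVER",
    int(ProtectionCategory.BUFFER): "BUFFER",
    int(ProtectionCategory.P15): "P15",
    int(ProtectionCategory.P70): "P70",
}


@dataclass
class CategoricalRaster:
    """Integer class-id lattice with a label table. -1 encodes missing."""

    grid: GridSpec
    ids: np.ndarray
    labels: dict[int, str]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if self.ids.shape != self.grid.shape:
            raise ValueError("categorical raster shape does not match grid")
        observed = set(np.unique(self.ids[self.ids >= 0]).tolist())
        missing = observed - set(self.labels)
        if missing:
            raise ValueError(f"class ids without labels: {sorted(missing)}")


def build_bioanthromes(
    biomes: CategoricalRaster, anthromes: CategoricalRaster
) -> CategoricalRaster:
    """Intersect biome and anthrome classes into bioanthrome ids.

    Each observed (biome, anthrome) pair maps to one consecutive id; the
    label table records the pair as "<biome>|<anthrome>". Pixels missing
    either input are missing (-1) in the output.
    """
    if biomes.grid != anthromes.grid:
        raise ValueError("biome and anthrome rasters must share one grid")
    valid = (biomes.ids >= 0) & (anthromes.ids >= 0)
    pairs = np.stack([biomes.ids[valid], anthromes.ids[valid]], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    ids = np.full(biomes.grid.shape, -1, dtype=np.int64)
    ids[valid] = inverse
    labels = {
        i: f"{biomes.labels[int(b)]}|{anthromes.labels[int(a)]}"
        for i, (b, a) in enumerate(uniq)
    }
    return CategoricalRaster(biomes.grid, ids, labels)


def quartile_bin(values: np.ndarray, eligible: np.ndarray | None = None) -> np.ndarray:
    """Coarsen a continuous layer into quartile classes 1-4.

    Cut points are the 25th/50th/75th percentiles of the eligible-pixel
    distribution; intervals are closed on the right (x <= q1 -> bin 1).
    NaN inputs yield bin 0 (missing). A constant layer collapses to bin 1
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    if eligible is not None:
        mask &= eligible
    pool = values[mask]
    if pool.size < 4:
        raise ValueError("quartile binning needs at least 4 non-missing values")
    q1, q2, q3 = np.percentile(pool, [25, 50, 75])
    if q1 == q3:
        warnings.warn("constant covariate layer: all pixels in bin 1", stacklevel=2)
    bins = np.zeros(values.shape, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        bins[mask] = (
            1
            + (values[mask] > q1).astype(int)
            + (values[mask] > q2).astype(int)
            + (values[mask] > q3).astype(int)
        )
    return bins


def assemble_pixel_table(
    extinction: ExtinctionRateMap,
    pmap: ProtectionMap,
    covariate_layers: dict[str, np.ndarray],
    bioanthromes: CategoricalRaster,
) -> pd.DataFrame:
    """Build the one-row-per-pixel matching table.

    Eligible pixels are exactly those with a defined extirpation rate; rows
    with any missing covariate or missing bioanthrome are dropped and the
    drop count logged. Quartile bins are computed on the pooled eligible
    distribution so treatment and control share one coarsening.
    """
    grid = extinction.grid
    if pmap.grid != grid or bioanthromes.grid != grid:
        raise ValueError("all layers must share one grid")
    for name in CONTINUOUS_COVARIATES:
        if name not in covariate_layers:
            raise ValueError(f"missing covariate layer {name!r}")
        if np.asarray(covariate_layers[name]).shape != grid.shape:
            raise ValueError(f"covariate layer {name!r} shape does not match grid")

    eligible = extinction.defined
    complete = eligible.copy()
    for name in CONTINUOUS_COVARIATES:
        complete &= ~np.isnan(np.asarray(covariate_layers[name], dtype=float))
    complete &= bioanthromes.ids >= 0
    n_dropped = int(eligible.sum() - complete.sum())
    if n_dropped:
        logger.info("assemble_pixel_table: dropped %d eligible pixels with missing covariates", n_dropped)
    if not complete.any():
        raise ValueError("no eligible pixels with complete covariates")

    rows, cols = np.nonzero(complete)
    table = pd.DataFrame(
        {
            "pixel_id": rows * grid.n_cols + cols,
            "row": rows,
            "col": cols,
            "outcome_pct_lost": 100.0 * extinction.rates[complete],
            "protection": pd.Categorical(
                [PROTECTION_LABELS[int(c)] for c in pmap.categories[complete]],
                categories=["NEVER", "BUFFER", "P15", "P70"],
            ),
        }
    )
    for name in CONTINUOUS_COVARIATES:
        layer = np.asarray(covariate_layers[name], dtype=float)
        table[name] = layer[complete]
        bins = quartile_bin(layer, eligible=complete)
        table[f"{name}_bin"] = bins[complete]
    table["bioanthrome_id"] = bioanthromes.ids[complete]
    table.attrs["n_dropped_missing"] = n_dropped
    return table
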