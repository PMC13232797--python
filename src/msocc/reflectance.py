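"""Vegetation indices, buffered raster summaries, and PCA covariates.

Takes six-band surface-reflectance rasters (blue, green, red, nir, swir1,
swir2; unitless reflectance in [0, 1], default 30 m pixels), computes seven
vegetation indices (NDVI, EVI, NBR, NDWI, tasselled-cap brightness/
greenness/wetness), summarises each band and index as the mean and
(population) standard deviation of pixels whose centres fall within a
buffer (default 100 m — roughly a point count's detection radius and a 3x3
pixel window) of each station, and condenses the resulting 26 variables
with a correlation-matrix PCA, retaining a fixed component count (default
5) or a variance target.

NDWI here is the canopy-water variant (nir - swir1)/(nir + swir1); the
open-water green/nir variant is available as ``ndwi_variant="green_nir"``.
Tasselled-cap coefficients are published reflectance-based sets selectable
per sensor (Landsat 5 TM by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "BAND_NAMES",
    "INDEX_NAMES",
    "TASSELED_CAP_COEFFICIENTS",
    "ReflectanceRaster",
    "IndexSet",
    "BufferedStats",
    "PCACovariates",
    "compute_indices",
    "buffer_stats",
    "pca_reduce",
    "median_stack",
]

BAND_NAMES = ("blue", "green", "red", "nir", "swir1", "swir2")
INDEX_NAMES = ("ndvi", "evi", "nbr", "ndwi", "tcb", "tcg", "tcw")

# Published reflectance-factor tasselled-cap coefficient sets, rows ordered
# (tcb, tcg, tcw), columns ordered as BAND_NAMES.
TASSELED_CAP_COEFFICIENTS = {
    # Crist (1985), Landsat 4/5 TM reflectance factors
    "tm": np.array(
        [
            [0.2043, 0.4158, 0.5524, 0.5741, 0.3124, 0.2303],
            [-0.1603, -0.2819, -0.4934, 0.7940, -0.0002, -0.1446],
            [0.0315, 0.2021, 0.3102, 0.1594, -0.6806, -0.6109],
        ]
    ),
    # Huang et al. (2002), Landsat 7 ETM+ at-satellite reflectance
    "etm+": np.array(
        [
            [0.3561, 0.3972, 0.3904, 0.6966, 0.2286, 0.1596],
            [-0.3344, -0.3544, -0.4556, 0.6966, -0.0242, -0.2630],
            [0.2626, 0.2141, 0.0926, 0.0656, -0.7629, -0.5388],
        ]
    ),
    # Baig et al. (2014), Landsat 8 OLI at-satellite reflectance
    "oli": np.array(
        [
            [0.3029, 0.2786, 0.4733, 0.5599, 0.5080, 0.1872],
            [-0.2941, -0.2430, -0.5424, 0.7276, 0.0713, -0.1608],
            [0.1511, 0.1973, 0.3283, 0.3407, -0.7117, -0.4559],
        ]
    ),
}


@dataclass
class ReflectanceRaster:
    """Six co-registered reflectance bands on a regular grid.

    ``origin`` is the planar coordinate of the grid's (row 0, col 0) pixel
    *centre*; rows advance +y, columns +x. Missing pixels are NaN.
    """

    bands: dict  # name -> 2-D float array
    pixel_size: float = 30.0
    origin: tuple = (0.0, 0.0)

    def __post_init__(self):
        missing = [b for b in BAND_NAMES if b not in self.bands]
        if missing:
            raise ValueError(f"missing reflectance bands: {missing}")
        shapes = {self.bands[b].shape for b in BAND_NAMES}
        if len(shapes) != 1:
            raise ValueError("bands must share a common shape")
        for b in BAND_NAMES:
            v = self.bands[b]
            bad = (v < 0) | (v > 1)
            if np.any(bad & np.isfinite(v)):
                raise ValueError(f"band {b!r} has reflectance outside [0, 1]")

    @property
    def shape(self):
        return self.bands[BAND_NAMES[0]].shape

    def pixel_centres(self):
        """(x, y) coordinate grids of pixel centres."""
        ny, nx = self.shape
        xs = self.origin[0] + self.pixel_size * np.arange(nx)
        ys = self.origin[1] + self.pixel_size * np.arange(ny)
        return np.meshgrid(xs, ys)

    def to_csv(self, prefix):
        """Write bands as CSV grids with a JSON georeferencing sidecar."""
        for b in BAND_NAMES:
            np.savetxt(f"{prefix}_{b}.csv", self.bands[b], delimiter=",")
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(
                {"pixel_size": self.pixel_size, "origin": list(self.origin)},
                fh,
            )

    @classmethod
    def from_csv(cls, prefix):
        with open(f"{prefix}_meta.json") as fh:
            meta = json.load(fh)
        bands = {
            b: np.atleast_2d(np.loadtxt(f"{prefix}_{b}.csv", delimiter=","))
            for b in BAND_NAMES
        }
        return cls(
            bands=bands,
            pixel_size=meta["pixel_size"],
            origin=tuple(meta["origin"]),
        )


@dataclass
class IndexSet:
    values: dict  # name -> 2-D array
    raster: ReflectanceRaster


@dataclass
class BufferedStats:
    """Mean and SD of each variable within the buffer of each station."""

    table: pd.DataFrame  # columns <var>_mean, <var>_sd
    radius: float


@dataclass
class PCACovariates:
    scores: np.ndarray  # (n_stations, n_retained)
    loadings: np.ndarray  # (n_variables, n_retained)
    variance_explained: np.ndarray  # all components, non-increasing
    n_retained: int
    variable_names: list = field(default_factory=list)


def _nd(a, b):
    """Normalized difference with zero-denominator pixels set missing."""
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - b) / denom
    out[denom == 0] = np.nan
    return out


def compute_indices(
    raster: ReflectanceRaster,
    tc_coefficient_set: str = "tm",
    ndwi_variant: str = "nir_swir1",
) -> IndexSet:
    """Seven vegetation indices from the six reflectance bands.

    NDVI = (nir-red)/(nir+red); EVI = 2.5 (nir-red)/(nir + 6 red
    - 7.5 blue + 1); NBR = (nir-swir2)/(nir+swir2); NDWI (canopy water) =
    (nir-swir1)/(nir+swir1); TCB/TCG/TCW are the selected published linear
    combinations of all six bands. Missing input propagates.
    """
    b = raster.bands
    nir, red, blue = b["nir"], b["red"], b["blue"]
    ndvi = _nd(nir, red)
    with np.errstate(divide="ignore", invalid="ignore"):
        evi_denom = nir + 6.0 * red - 7.5 * blue + 1.0
        evi = 2.5 * (nir - red) / evi_denom
    evi = np.where(evi_denom == 0, np.nan, evi)
    nbr = _nd(nir, b["swir2"])
    if ndwi_variant == "nir_swir1":
        ndwi = _nd(nir, b["swir1"])
    elif ndwi_variant == "green_nir":
        ndwi = _nd(b["green"], nir)
    else:
        raise ValueError("ndwi_variant must be 'nir_swir1' or 'green_nir'")
    try:
        coefs = TASSELED_CAP_COEFFICIENTS[tc_coefficient_set]
    except KeyError:
        raise ValueError(
            f"unknown tasselled-cap set {tc_coefficient_set!r}; options: "
            f"{sorted(TASSELED_CAP_COEFFICIENTS)}"
        ) from None
    stack = np.stack([b[name] for name in BAND_NAMES])
    tcb, tcg, tcw = np.tensordot(coefs, stack, axes=(1, 0))
    return IndexSet(
        values={
            "ndvi": ndvi,
            "evi": evi,
            "nbr": nbr,
            "ndwi": ndwi,
            "tcb": tcb,
            "tcg": tcg,
            "tcw": tcw,
        },
        raster=raster,
    )


def buffer_stats(
    indices: IndexSet, stations: np.ndarray, radius: float = 100.0
) -> BufferedStats:
    """Mean and population SD of pixels within ``radius`` of each station.

    A pixel is included iff its centre lies within ``radius`` of the
    station coordinate; with 30 m pixels and a 100 m radius this is the 3x3
    neighbourhood plus the edge pixels whose centres qualify. Missing
    pixels are excluded; a station whose buffer holds no valid pixel is an
    error.
    """
    stations = np.atleast_2d(np.asarray(stations, dtype=float))
    raster = indices.raster
    gx, gy = raster.pixel_centres()
    grids = {**{b: raster.bands[b] for b in BAND_NAMES}, **indices.values}
    names = list(BAND_NAMES) + list(INDEX_NAMES)
    rows = []
    empty = []
    for s, (sx, sy) in enumerate(stations):
        inside = (gx - sx) ** 2 + (gy - sy) ** 2 <= radius**2
        row = {}
        for name in names:
            vals = grids[name][inside]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                empty.append(s)
                row[f"{name}_mean"] = np.nan
                row[f"{name}_sd"] = np.nan
            else:
                row[f"{name}_mean"] = float(vals.mean())
                row[f"{name}_sd"] = float(vals.std())  # population SD
        rows.append(row)
    if empty:
        raise ValueError(
            f"stations with no valid pixels in their buffer: {sorted(set(empty))}"
        )
    return BufferedStats(table=pd.DataFrame(rows), radius=radius)


def pca_reduce(
    stats: BufferedStats | pd.DataFrame,
    n_components: int | None = 5,
    variance_target: float | None = None,
) -> PCACovariates:
    """Correlation-matrix PCA of the buffered variables.

    Variables are z-standardized first (bands and indices have
    incommensurate scales); constant columns are dropped with a warning.
    Retains ``n_components`` components, or the smallest count whose
    cumulative variance reaches ``variance_target`` when that is given.
    """
    table = stats.table if isinstance(stats, BufferedStats) else stats
    if len(table) < 2:
        raise ValueError("PCA needs at least 2 stations")
    x = table.to_numpy(dtype=float)
    names = list(table.columns)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        dropped = [names[i] for i in np.nonzero(sd == 0)[0]]
        warnings.warn(f"dropping constant variables: {dropped}", stacklevel=2)
        keep = sd > 0
        x, sd = x[:, keep], sd[keep]
        names = [n for n, k in zip(names, keep) if k]
    x = (x - x.mean(axis=0)) / sd
    pca = PCA()
    scores = pca.fit_transform(x)
    var = pca.explained_variance_ratio_
    if variance_target is not None:
        if not 0 < variance_target <= 1:
            raise ValueError("variance_target must be in (0, 1]")
        n_keep = int(np.searchsorted(np.cumsum(var), variance_target - 1e-12) + 1)
        n_keep = min(n_keep, var.size)
    else:
        n_keep = min(int(n_components), var.size)
    return PCACovariates(
        scores=scores[:, :n_keep],
        loadings=pca.components_[:n_keep].T,
        variance_explained=var,
        n_retained=n_keep,
        variable_names=names,
    )


def median_stack(rasters: list) -> ReflectanceRaster:
    """Pixelwise median composite over co-registered rasters (NaN-aware),
    the stand-in for an annual cloud-masked compositing step."""
    if not rasters:
        raise ValueError("need at least one raster")
    first = rasters[0]
    bands = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for b in BAND_NAMES:
            bands[b] = np.nanmedian(
                np.stack([r.bands[b] for r in rasters]), axis=0
            )
    return ReflectanceRaster(
        bands=bands, pixel_size=first.pixel_size, origin=first.origin
    )
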