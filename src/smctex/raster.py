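"""Multiband reflectance rasters: loading, plot clipping, vegetation masking.

The canonical band order is blue (450 nm), green (555), red (660), red-edge
(720), red-edge (750), NIR (840) — Band1..Band6.  Vegetation pixels are
retained where an NIR-based index (NDVI by default) exceeds a threshold τ
picked from the index histogram within 0.30–0.40, and the mask is refined by
3×3 binary opening then closing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "BAND_NAMES",
    "ReflectancePlot",
    "MaskEmptyError",
    "load_raster",
    "load_plot",
    "plots_from_rectangles",
    "compute_index",
    "select_tau",
    "vegetation_mask",
]

BAND_NAMES = ("blue", "green", "red", "rededge720", "rededge750", "nir")

_STRUCT3 = np.ones((3, 3), dtype=bool)


class MaskEmptyError(ValueError):
    """The vegetation mask came out empty; the threshold needs review."""


@dataclass
class ReflectancePlot:
    """A 6-band reflectance grid clipped to one plot, with vegetation mask.

    ``pixels`` has shape (rows, cols, 6) in canonical band order;
    ``mask`` is boolean with True = vegetation.
    """

    plot_id: str
    pixels: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != len(BAND_NAMES):
            raise ValueError(
                f"plot {self.plot_id!r}: expected (rows, cols, 6) pixels, "
                f"got shape {self.pixels.shape}")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask and pixel grids differ in shape")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError(f"plot {self.plot_id!r}: non-finite reflectance")
        if (self.pixels < 0).any():
            warnings.warn(
                f"plot {self.plot_id!r}: negative reflectance clipped to 0",
                stacklevel=2)
            self.pixels = np.clip(self.pixels, 0.0, None)

    def band(self, b: int) -> np.ndarray:
        """Band b in 1..6 (canonical order)."""
        return self.pixels[..., b - 1]

    @property
    def vegetation_fraction(self) -> float:
        return float(self.mask.mean())


def load_raster(path, band_order=None) -> np.ndarray:
    """Read a multiband TIFF into a (rows, cols, 6) float array.

    ``band_order`` maps file band index (0-based) to canonical position;
    identity by default.  Rasters with more than 6 bands use the first six
    after reordering; fewer than 6 is an error naming the missing bands.
    """
    import tifffile

    arr = np.asarray(tifffile.imread(str(path)))
    if arr.ndim == 2:
        arr = arr[None]
    # accept band-first (6, H, W) or band-last (H, W, 6)
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a multiband raster, got shape {arr.shape}")
    if arr.shape[0] <= 12 and arr.shape[0] < arr.shape[2]:
        arr = np.moveaxis(arr, 0, -1)
    n = arr.shape[2]
    if n < len(BAND_NAMES):
        missing = ", ".join(BAND_NAMES[n:])
        raise ValueError(
            f"{path}: raster has {n} band(s); missing {missing}")
    if band_order is not None:
        arr = arr[..., list(band_order)]
    return arr[..., : len(BAND_NAMES)].astype(np.float32)


def load_plot(raster_path, plot_geometry, band_order=None,
              pixel_size: float | None = None) -> ReflectancePlot:
    """Clip one plot out of a raster.

    ``plot_geometry`` is either a mapping with keys
    ``plot_id, row0, row1, col0, col1`` (half-open pixel rectangle) or a
    GeoJSON-style feature/polygon dict in raster pixel coordinates
    (x = column, y = row); polygon membership is tested at pixel centres.
    """
    arr = load_raster(raster_path, band_order)
    H, W = arr.shape[:2]
    if _is_rectangle(plot_geometry):
        g = plot_geometry
        r0, r1 = int(g["row0"]), int(g["row1"])
        c0, c1 = int(g["col0"]), int(g["col1"])
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, H), min(c1, W)
        if r1 <= r0 or c1 <= c0:
            raise ValueError(
                f"plot {g.get('plot_id')!r}: geometry does not intersect raster")
        return ReflectancePlot(str(g["plot_id"]), arr[r0:r1, c0:c1],
                               pixel_size=pixel_size)
    return _clip_polygon(arr, plot_geometry, pixel_size)


def _is_rectangle(geom) -> bool:
    return isinstance(geom, dict) and {"row0", "row1", "col0", "col1"} <= set(geom)


def _clip_polygon(arr, feature, pixel_size):
    import shapely
    from shapely.geometry import shape

    if isinstance(feature, dict) and feature.get("type") == "Feature":
        props = feature.get("properties") or {}
        plot_id = str(props.get("plot_id", "plot"))
        geom = shape(feature["geometry"])
    else:
        plot_id = "plot"
        geom = shape(feature)
    H, W = arr.shape[:2]
    minx, miny, maxx, maxy = geom.bounds
    c0, c1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)), W)
    r0, r1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)), H)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"plot {plot_id!r}: geometry does not intersect raster")
    sub = arr[r0:r1, c0:c1]
    rr, cc = np.mgrid[r0:r1, c0:c1]
    inside = shapely.contains_xy(geom, cc + 0.5, rr + 0.5)
    if not inside.any():
        raise ValueError(f"plot {plot_id!r}: no pixel centre falls inside geometry")
    return ReflectancePlot(plot_id, sub, mask=inside, pixel_size=pixel_size)


def plots_from_rectangles(raster_path, rect_csv, band_order=None):
    """Load every plot listed in a rectangle CSV (plot_id,row0,row1,col0,col1)."""
    rects = pd.read_csv(rect_csv)
    need = {"plot_id", "row0", "row1", "col0", "col1"}
    if not need <= set(rects.columns):
        raise ValueError(f"{rect_csv}: missing columns {sorted(need - set(rects.columns))}")
    return [load_plot(raster_path, row._asdict() if hasattr(row, "_asdict")
                      else dict(row), band_order)
            for row in rects.to_dict("records")]


# ---------------------------------------------------------------------------
# vegetation masking
# ---------------------------------------------------------------------------

def compute_index(plot: ReflectancePlot, index_name: str = "ndvi") -> np.ndarray:
    """Per-pixel vegetation index from the plot's bands."""
    name = index_name.lower()
    nir = plot.band(6).astype(float)
    red = plot.band(3).astype(float)
    if name == "ndvi":
        num, den = nir - red, nir + red
    elif name == "ndre":
        re = plot.band(4).astype(float)
        num, den = nir - re, nir + re
    else:
        raise ValueError(f"unknown vegetation index {index_name!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(den != 0, num / den, 0.0)
    return idx


def _otsu(values: np.ndarray, nbins: int = 256) -> float:
    """Minimum-intra-class-variance (Otsu) threshold of a value histogram.

    Computed in float64 over ``nbins`` candidate cuts.  When the objective
    is maximal over a plateau (an empty gap between two well-separated
    modes leaves the partition unchanged for every cut inside the gap), the
    plateau midpoint is returned, so the threshold falls between the modes
    rather than at an arbitrary plateau edge.
    """
    v = values.ravel().astype(float)
    counts, edges = np.histogram(v, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(float)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m0 = np.cumsum(counts * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (m0[-1] - m0) / w1
        sb = w0 * w1 * (mu0 - mu1) ** 2
    sb = np.where(np.isfinite(sb), sb, -np.inf)
    best = sb.max()
    tied = np.flatnonzero(sb >= best * (1.0 - 1e-12))
    return float(centers[tied].mean())


def select_tau(plot: ReflectancePlot, index_name: str = "ndvi",
               clamp: tuple[float, float] = (0.30, 0.40)) -> float:
    """Automatic mask threshold: Otsu on the index histogram, clamped.

    The clamp interval (default 0.30–0.40) keeps the threshold inside the
    conventional NDVI vegetation-masking range.
    """
    idx = compute_index(plot, index_name)
    if np.ptp(idx) == 0:
        raise ValueError("vegetation index is constant; cannot select tau")
    tau = _otsu(idx)
    return float(np.clip(tau, clamp[0], clamp[1]))


def _open_close(mask: np.ndarray) -> np.ndarray:
    """3×3 binary opening then closing, with the standard border convention
    (erosion treats outside as True, dilation as False)."""
    er = ndimage.binary_erosion(mask, _STRUCT3, border_value=1)
    opened = ndimage.binary_dilation(er, _STRUCT3, border_value=0)
    di = ndimage.binary_dilation(opened, _STRUCT3, border_value=0)
    closed = ndimage.binary_erosion(di, _STRUCT3, border_value=1)
    return closed


def vegetation_mask(plot: ReflectancePlot, tau: float | str = "auto",
                    index_name: str = "ndvi",
                    morphology: bool = True) -> ReflectancePlot:
    """Mask non-vegetation pixels: index > τ, then 3×3 opening and closing.

    Returns a new plot with the refined mask; reflectance is untouched.
    Raises :class:`MaskEmptyError` when no vegetation pixel survives.
    """
    if tau == "auto":
        tau = select_tau(plot, index_name)
    tau = float(tau)
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    idx = compute_index(plot, index_name)
    mask = idx > tau
    if morphology:
        mask = _open_close(mask)
    if not mask.any():
        raise MaskEmptyError(
            f"plot {plot.plot_id!r}: vegetation mask is empty at tau={tau:.3f}; "
            "review the threshold or index choice")
    out = ReflectancePlot(plot.plot_id, plot.pixels.copy(), mask=mask,
                          pixel_size=plot.pixel_size)
    return out
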