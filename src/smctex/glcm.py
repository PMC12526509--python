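"""Gray-level co-occurrence matrix (GLCM) texture features.

Eight second-order texture statistics — mean (MEA), variance (VAR),
homogeneity (HOM), contrast (CON), dissimilarity (DIS), entropy (ENT),
second moment (SEC) and correlation (COR) — are computed per spectral band
on a sliding window, with the co-occurrence matrix accumulated symmetrically
at a one-pixel offset in four directions (0, 45, 90, 135 degrees) and the
directional results averaged.  One value per (metric, band) pair is reported
per plot: the "position", e.g. ``HOM6`` = homogeneity of band 6 (NIR).

Entropy uses the Shannon form −Σ P log P in natural log, so ENT ≥ 0; the
sign convention is recorded in :data:`TEXTURE_METADATA`.  Gray levels are
0-based (0..G−1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "METRICS",
    "N_BANDS",
    "GLCMParams",
    "GLCMStats",
    "Position",
    "all_positions",
    "quantize",
    "glcm_matrix",
    "glcm_features",
    "plot_textures",
    "textures_for_plots",
    "TEXTURE_METADATA",
]

METRICS = ("MEA", "VAR", "HOM", "CON", "DIS", "ENT", "SEC", "COR")
N_BANDS = 6

TEXTURE_METADATA = {
    "entropy_sign": "shannon (-sum P log P, natural log)",
    "gray_level_origin": 0,
}

# offsets (dr, dc) for 0, 45, 90, 135 degrees; under symmetric accumulation
# the sign of the offset is immaterial.
_DIRECTION_OFFSETS = {
    0: (0, 1),
    45: (1, 1),
    90: (1, 0),
    135: (1, -1),
}


@dataclass(frozen=True)
class GLCMParams:
    """Parameters of the windowed GLCM computation.

    Defaults follow the fixed acquisition protocol: 64 gray levels, a 5x5
    moving window, one-pixel offset, four averaged directions.
    """

    gray_levels: int = 64
    window: int = 5
    offset: int = 1
    directions: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    min_window_valid_frac: float = 0.6
    percentile_clip: tuple[float, float] = (1.0, 99.0)
    scaling_mode: str = "per_plot"  # or "global"
    global_range: dict[int, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if self.window % 2 != 1 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if self.offset < 1:
            raise ValueError("offset must be >= 1")
        unknown = set(self.directions) - set(_DIRECTION_OFFSETS)
        if unknown:
            raise ValueError(f"unsupported directions: {sorted(unknown)}")
        if self.scaling_mode not in ("per_plot", "global"):
            raise ValueError("scaling_mode must be 'per_plot' or 'global'")


@dataclass
class GLCMStats:
    """A normalized co-occurrence matrix with its marginal moments."""

    P: np.ndarray  # (G, G), entries >= 0, sum 1
    mea_i: float
    mea_j: float
    var_i: float
    var_j: float
    u: float  # GLCM mean used by VAR

    @classmethod
    def from_matrix(cls, P: np.ndarray) -> "GLCMStats":
        total = P.sum()
        if not np.isclose(total, 1.0):
            raise ValueError("P must be normalized to sum 1")
        G = P.shape[0]
        levels = np.arange(G, dtype=float)
        p_i = P.sum(axis=1)
        p_j = P.sum(axis=0)
        mea_i = float(levels @ p_i)
        mea_j = float(levels @ p_j)
        var_i = float(((levels - mea_i) ** 2) @ p_i)
        var_j = float(((levels - mea_j) ** 2) @ p_j)
        return cls(P=P, mea_i=mea_i, mea_j=mea_j, var_i=var_i, var_j=var_j,
                   u=mea_i)


@dataclass(frozen=True, order=True)
class Position:
    """One (texture metric, band) identifier, e.g. HOM6 = homogeneity, NIR."""

    metric: str
    band: int  # 1..6

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not 1 <= self.band <= N_BANDS:
            raise ValueError(f"band must be 1..{N_BANDS}, got {self.band}")

    @property
    def label(self) -> str:
        return f"{self.metric}{self.band}"

    @classmethod
    def from_label(cls, label: str) -> "Position":
        metric, band = label[:-1], label[-1:]
        if not band.isdigit():
            raise ValueError(f"malformed position label {label!r}")
        return cls(metric=metric, band=int(band))


def all_positions() -> list[Position]:
    """The 48 positions: 8 metrics x 6 bands, metric-major order."""
    return [Position(m, b) for m in METRICS for b in range(1, N_BANDS + 1)]


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize(
    band_grid: np.ndarray,
    mask: np.ndarray | None,
    gray_levels: int,
    percentile_clip: tuple[float, float] = (1.0, 99.0),
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly scale reflectance to integer gray levels 0..G−1.

    Masked (non-vegetation) pixels are marked invalid.  The scaling range is
    the ``percentile_clip`` percentiles of the valid pixels, or an explicit
    ``value_range`` for cross-flight (global) comparability.  A constant band
    maps every pixel to level 0 with a warning.

    Returns ``(levels, valid)`` with ``levels`` int16 and ``valid`` boolean.
    """
    grid = np.asarray(band_grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("band grid contains non-finite values")
    valid = np.ones(grid.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    if valid.shape != grid.shape:
        raise ValueError("mask shape does not match grid shape")
    vals = grid[valid]
    if vals.size == 0:
        raise ValueError("no valid pixels to quantize")
    if value_range is not None:
        lo, hi = value_range
    else:
        lo, hi = np.percentile(vals, percentile_clip)
    levels = np.zeros(grid.shape, dtype=np.int16)
    if hi <= lo:
        import warnings

        warnings.warn("constant band: all pixels quantized to level 0",
                      stacklevel=2)
    else:
        scaled = (grid - lo) / (hi - lo)
        np.clip(scaled, 0.0, 1.0, out=scaled)
        levels = np.minimum((scaled * gray_levels).astype(np.int16),
                            gray_levels - 1)
    return levels, valid


# ---------------------------------------------------------------------------
# single-window reference path
# ---------------------------------------------------------------------------

class WindowSkipped(Exception):
    """Raised when a window holds no valid pixel pair for a direction."""


def glcm_matrix(
    levels: np.ndarray,
    valid: np.ndarray,
    direction: int,
    gray_levels: int,
    offset: int = 1,
) -> GLCMStats:
    """Build the symmetric, normalized co-occurrence matrix of one window.

    Pairs ``(p, p + offset_vector)`` are counted only when both pixels are
    valid; both orderings are accumulated (symmetric GLCM).  Raises
    :class:`WindowSkipped` when the window has no valid pair.
    """
    dr, dc = _DIRECTION_OFFSETS[direction]
    dr, dc = dr * offset, dc * offset
    H, W = levels.shape
    P = np.zeros((gray_levels, gray_levels), dtype=float)
    n = 0
    for r in range(H):
        r2 = r + dr
        if not 0 <= r2 < H:
            continue
        for c in range(W):
            c2 = c + dc
            if not 0 <= c2 < W:
                continue
            if valid[r, c] and valid[r2, c2]:
                i, j = levels[r, c], levels[r2, c2]
                P[i, j] += 1.0
                P[j, i] += 1.0
                n += 1
    if n == 0:
        raise WindowSkipped(f"no valid pixel pair for direction {direction}")
    P /= P.sum()
    return GLCMStats.from_matrix(P)


def glcm_features(stats: GLCMStats) -> dict[str, float]:
    """Evaluate the eight texture statistics of one co-occurrence matrix.

    COR is undefined (NaN) when either marginal variance is zero.
    """
    P = stats.P
    G = P.shape[0]
    levels = np.arange(G, dtype=float)
    i = levels[:, None]
    j = levels[None, :]
    diff = i - j
    mea = float((i * P).sum())
    var = float((((i - stats.u) ** 2) * P).sum())
    hom = float((P / (1.0 + diff ** 2)).sum())
    con = float((diff ** 2 * P).sum())
    dis = float((np.abs(diff) * P).sum())
    pos = P[P > 0]
    ent = float(-(pos * np.log(pos)).sum())
    sec = float((P ** 2).sum())
    denom = stats.var_i * stats.var_j
    if denom <= 0:
        cor = float("nan")
    else:
        cor = float((((i - stats.mea_j) * (j - stats.mea_i) * P).sum())
                    / np.sqrt(denom))
    return {"MEA": mea, "VAR": var, "HOM": hom, "CON": con,
            "DIS": dis, "ENT": ent, "SEC": sec, "COR": cor}


# ---------------------------------------------------------------------------
# vectorized plot-level path
# ---------------------------------------------------------------------------

def _window_sums(grid: np.ndarray, wr: int, wc: int) -> np.ndarray:
    """Sums over all (wr, wc) sliding blocks via a 2-D integral image."""
    S = np.zeros((grid.shape[0] + 1, grid.shape[1] + 1), dtype=float)
    np.cumsum(np.cumsum(grid, axis=0), axis=1, out=S[1:, 1:])
    return (S[wr:, wc:] - S[:-wr, wc:] - S[wr:, :-wc] + S[:-wr, :-wc])


def _direction_window_metrics(
    levels: np.ndarray,
    valid: np.ndarray,
    direction: int,
    params: GLCMParams,
) -> dict[str, np.ndarray]:
    """Per-window metrics for one direction over every interior window.

    Returns arrays of shape (H−w+1, W−w+1); windows with zero valid pairs
    carry NaN.  COR is NaN where the window GLCM variance is zero.
    """
    w = params.window
    G = params.gray_levels
    dr, dc = _DIRECTION_OFFSETS[direction]
    dr, dc = dr * params.offset, dc * params.offset
    H, W = levels.shape
    if H < w or W < w:
        raise ValueError("plot smaller than the GLCM window")
    adr, adc = abs(dr), abs(dc)
    if w <= adr or w <= adc:
        raise ValueError("offset does not fit inside the window")

    # pair-anchor grids: anchor (r, c) pairs pixel (r, c) with (r+dr, c+dc);
    # stored so that the anchors of window (r0, c0) occupy the contiguous
    # block starting at (r0, c0) of shape (w−|dr|, w−|dc|).
    rows = slice(0, H - adr)
    if dc >= 0:
        a = (slice(rows.start, rows.stop), slice(0, W - adc))
        b = (slice(adr, H), slice(adc, W))
    else:
        a = (slice(rows.start, rows.stop), slice(adc, W))
        b = (slice(adr, H), slice(0, W - adc))
    # shift levels by the plot mean before forming moment sums: differences
    # and (co)variances are shift-invariant and the smaller magnitudes keep
    # the E[x^2] - u^2 cancellation benign; the shift is added back to MEA.
    shift = float(levels[valid].mean()) if valid.any() else 0.0
    I = levels[a].astype(float) - shift
    J = levels[b].astype(float) - shift
    ok = (valid[a] & valid[b])

    okf = ok.astype(float)
    Iv = np.where(ok, I, 0.0)
    Jv = np.where(ok, J, 0.0)
    wr, wc = w - adr, w - adc

    n = _window_sums(okf, wr, wc)
    sI = _window_sums(Iv, wr, wc)
    sJ = _window_sums(Jv, wr, wc)
    sI2 = _window_sums(Iv * Iv, wr, wc)
    sJ2 = _window_sums(Jv * Jv, wr, wc)
    sIJ = _window_sums(Iv * Jv, wr, wc)
    d = np.where(ok, I - J, 0.0)
    sAbs = _window_sums(np.abs(d), wr, wc)
    sSq = _window_sums(d * d, wr, wc)
    sHom = _window_sums(np.where(ok, 1.0 / (1.0 + (I - J) ** 2), 0.0), wr, wc)

    with np.errstate(divide="ignore", invalid="ignore"):
        inv_n = np.where(n > 0, 1.0 / n, np.nan)
        u = 0.5 * (sI + sJ) * inv_n            # symmetric GLCM mean
        var = 0.5 * (sI2 + sJ2) * inv_n - u * u
        var = np.maximum(var, 0.0)
        cov = sIJ * inv_n - u * u
        con = sSq * inv_n
        dis = sAbs * inv_n
        hom = sHom * inv_n
        # smallest nonzero variance of an integer-level GLCM with <= 2*w*w
        # entries is ~1/(2n) >> 1e-6, so the cutoff only absorbs rounding
        cor = np.where(var > 1e-6, cov / var, np.nan)
        u = u + shift

    # ENT and SEC need the pair-value distribution within each window:
    # collect the ≤ 2·(w−|dr|)·(w−|dc|) symmetric pair codes per window,
    # sort, and aggregate run lengths.
    Iq = levels[a].astype(np.int32)
    Jq = levels[b].astype(np.int32)
    code = np.where(ok, Iq * G + Jq, np.int32(-1))
    code_sym = np.where(ok, Jq * G + Iq, np.int32(-1))
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(code, (wr, wc))
    win_sym = sliding_window_view(code_sym, (wr, wc))
    Nr, Nc = win.shape[0], win.shape[1]
    k = 2 * wr * wc
    flat = np.concatenate(
        [win.reshape(Nr * Nc, wr * wc), win_sym.reshape(Nr * Nc, wr * wc)],
        axis=1,
    )
    flat = np.sort(flat, axis=1)
    nw = Nr * Nc
    F = flat.ravel()
    start = np.empty(F.shape, dtype=bool)
    start[0] = True
    start[1:] = F[1:] != F[:-1]
    start[::k][:] = True  # row boundaries
    idx = np.flatnonzero(start)
    run_len = np.diff(np.append(idx, F.size)).astype(float)
    run_row = idx // k
    run_code = F[idx]
    keep = run_code >= 0
    m = run_len[keep]
    rr = run_row[keep]
    tot = np.bincount(rr, weights=m, minlength=nw)  # = 2·n valid entries
    with np.errstate(divide="ignore", invalid="ignore"):
        sec_flat = np.bincount(rr, weights=m * m, minlength=nw)
        sec_flat = np.where(tot > 0, sec_flat / (tot * tot), np.nan)
        ent_flat = np.bincount(rr, weights=m * np.log(m), minlength=nw)
        logtot = np.where(tot > 0, np.log(tot), 0.0)
        ent_flat = np.where(tot > 0, logtot - ent_flat / tot, np.nan)

    return {
        "MEA": u, "VAR": var, "HOM": hom, "CON": con, "DIS": dis,
        "ENT": ent_flat.reshape(Nr, Nc), "SEC": sec_flat.reshape(Nr, Nc),
        "COR": cor, "_n": n,
    }


def _band_textures(
    levels: np.ndarray,
    valid: np.ndarray,
    params: GLCMParams,
) -> dict[str, float]:
    """Plot-level texture statistics of one quantized band.

    Each admissible window (valid-pixel fraction ≥ ``min_window_valid_frac``)
    contributes the average of each metric over the directions that have at
    least one valid pair; the plot value is the mean over admissible windows.
    Windows whose GLCM has zero variance are excluded from COR's mean only.
    """
    w = params.window
    frac = _window_sums(valid.astype(float), w, w) / (w * w)
    admissible = frac >= params.min_window_valid_frac

    per_dir = [
        _direction_window_metrics(levels, valid, d, params)
        for d in params.directions
    ]
    if not admissible.any():
        raise ValueError("no admissible window (mask too sparse for the "
                         "window size)")
    out: dict[str, float] = {}
    import warnings

    for metric in METRICS:
        stack = np.stack([pd[metric] for pd in per_dir])  # (D, Nr, Nc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dir_mean = np.nanmean(stack, axis=0)
        vals = dir_mean[admissible]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            if metric == "COR":  # undefined on zero-variance plots
                out[metric] = float("nan")
                continue
            raise ValueError(
                f"no admissible window produced a defined {metric} value")
        out[metric] = float(vals.mean())
    return out


def plot_textures(plot, params: GLCMParams | None = None):
    """All 48 position values of one plot.

    Parameters
    ----------
    plot : ReflectancePlot
        Six-band reflectance grid with vegetation mask.
    params : GLCMParams, optional
        Window/quantization parameters; defaults to the fixed protocol.

    Returns
    -------
    pandas.Series indexed by position label (``MEA1`` .. ``COR6``).
    """
    import pandas as pd

    params = params or GLCMParams()
    values: dict[str, float] = {}
    for b in range(1, N_BANDS + 1):
        band_grid = plot.pixels[..., b - 1]
        vr = None
        if params.scaling_mode == "global":
            if not params.global_range or b not in params.global_range:
                raise ValueError(f"global scaling requested but no range for band {b}")
            vr = params.global_range[b]
        levels, valid = quantize(
            band_grid, plot.mask, params.gray_levels,
            params.percentile_clip, value_range=vr,
        )
        feats = _band_textures(levels, valid, params)
        for metric in METRICS:
            values[f"{metric}{b}"] = feats[metric]
    order = [p.label for p in all_positions()]
    return pd.Series(values).reindex(order)


def textures_for_plots(plots: Iterable, params: GLCMParams | None = None):
    """Feature table: one row per plot, 48 position columns."""
    import pandas as pd

    rows = {}
    for plot in plots:
        try:
            rows[plot.plot_id] = plot_textures(plot, params)
        except ValueError as exc:
            raise ValueError(f"plot {plot.plot_id!r}: {exc}") from exc
    table = pd.DataFrame(rows).T
    table.index.name = "plot_id"
    return table
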