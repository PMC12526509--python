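"""Correlation-matrix feature screening.

Every position (or every ordered position tuple of an index family) is
correlated with SMC; the maximum-|r| combination is reported per family,
features with p ≥ α are discarded, near-duplicates (inter-feature |r| ≥
0.90) are removed greedily, and the remainder is pruned until every
variance inflation factor (VIF) is ≤ 10.

The exhaustive grids (48² ordered pairs, 48³ ordered triples per family)
are evaluated blockwise and fully vectorised; undefined index values (NaN)
propagate as excluded observations, and a combination with more than 10%
undefined rows is dropped from the ranking altogether.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glcm import Position, all_positions
from .indices import (FAMILIES_2D, FAMILIES_3D, IndexDefinition,
                      batch_indices, eval_2d, eval_3d, parse_index_name)

__all__ = [
    "ScreenResult",
    "pearson_with_p",
    "exhaustive_search",
    "redundancy_filter",
    "vif_filter",
    "screen_family",
    "materialize_features",
]

MAX_UNDEFINED_FRAC = 0.10


@dataclass
class ScreenResult:
    """Outcome of screening one index family (or the raw positions) at one depth."""

    depth_layer: str
    family: str  # "raw" or an index family name
    best_name: str
    r: float
    p: float
    candidates: list[str] = field(default_factory=list)  # significant, pre-filter
    survivors: list[str] = field(default_factory=list)   # after |r| and VIF filters
    grid: pd.DataFrame | None = None  # long-format |r| surface, optional


# ---------------------------------------------------------------------------
# Pearson correlation with p-value
# ---------------------------------------------------------------------------

def _p_from_r(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p via the t-transform t = r sqrt((n−2)/(1−r²)), df = n−2."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = 1.0 - r * r
        t = np.abs(r) * np.sqrt(np.where(denom > 0, (n - 2) / denom, np.inf))
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(t, np.maximum(n - 2, 1)), 0.0)
    p = np.where(np.isnan(r) | (n < 3), np.nan, p)
    return p


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p, dropping undefined (NaN) pairs.

    Returns ``(nan, nan)`` when either column has zero variance or fewer
    than three complete pairs remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, float(_p_from_r(r, x.size))


def _pearson_columns(V: np.ndarray, y: np.ndarray,
                     max_nan_frac: float = MAX_UNDEFINED_FRAC):
    """Column-wise NaN-aware Pearson r of V (n, m) against y (n,).

    Returns ``(r, n_eff)``; columns with too many undefined rows, fewer than
    3 complete pairs, or zero variance carry NaN.
    """
    n = V.shape[0]
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()  # conditioning only; the masked formula is exact
    valid = np.isfinite(V)
    m = valid.sum(axis=0).astype(float)
    Vz = np.where(valid, V, 0.0)
    sy = yc @ valid
    syy = (yc * yc) @ valid
    sv = Vz.sum(axis=0)
    svv = (Vz * Vz).sum(axis=0)
    svy = yc @ Vz
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = svy - sv * sy / m
        varv = svv - sv * sv / m
        vary = syy - sy * sy / m
        r = cov / np.sqrt(varv * vary)
    bad = (m < 3) | (m < (1.0 - max_nan_frac) * n) \
        | ~np.isfinite(r)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    return r, m


# ---------------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------------

def _family_grid_r(X: np.ndarray, labels: list[str], y: np.ndarray,
                   family: str):
    """|r| over the family's full ordered-tuple space.

    Yields ``(names, r, n_eff)`` blockwise (one block per leading index for
    triples) to bound memory.
    """
    p = X.shape[1]
    if family == "raw":
        r, m = _pearson_columns(X, y)
        yield labels, r, m
    elif family in FAMILIES_2D:
        V = eval_2d(family, X[:, :, None], X[:, None, :]).reshape(len(y), p * p)
        V = np.where(np.isfinite(V), V, np.nan)
        names = [f"{family}({a},{b})" for a in labels for b in labels]
        r, m = _pearson_columns(V, y)
        yield names, r, m
    elif family in FAMILIES_3D:
        for i in range(p):
            ti = X[:, i][:, None, None]
            V = eval_3d(family, ti, X[:, :, None], X[:, None, :])
            V = np.where(np.isfinite(V), V, np.nan).reshape(len(y), p * p)
            names = [f"{family}({labels[i]},{a},{b})"
                     for a in labels for b in labels]
            r, m = _pearson_columns(V, y)
            yield names, r, m
    else:
        raise ValueError(f"unknown family {family!r}")


def exhaustive_search(features: pd.DataFrame, smc, family: str,
                      alpha: float = 0.05, near_frac: float = 0.95,
                      cap: int = 20, positions: list[str] | None = None,
                      depth_layer: str = "", return_grid: bool = False,
                      ) -> ScreenResult:
    """Maximum-|r| combination of one family, with significant candidates.

    ``positions`` restricts the search space (default: all 48 position
    labels present in ``features``).  Ties in |r| break lexicographically by
    combination name.  For index families the returned ``candidates`` are
    the best combination plus any combination within ``near_frac`` of the
    best |r| (descending |r|, capped at ``cap``); for the raw family every
    significant position is a candidate.
    """
    if positions is None:
        positions = [p.label for p in all_positions()
                     if p.label in features.columns]
    missing = [lab for lab in positions if lab not in features.columns]
    if missing:
        raise KeyError(f"positions missing from feature table: {missing}")
    X = features[positions].to_numpy(float)
    y = np.asarray(smc, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("feature table and SMC column differ in length")

    all_names: list[str] = []
    all_r: list[np.ndarray] = []
    all_m: list[np.ndarray] = []
    for names, r, m in _family_grid_r(X, positions, y, family):
        all_names.extend(names)
        all_r.append(r)
        all_m.append(m)
    r = np.concatenate(all_r)
    m = np.concatenate(all_m)
    absr = np.abs(r)
    if not np.isfinite(absr).any():
        raise ValueError(
            f"family {family!r}: every combination is undefined")
    best_abs = np.nanmax(absr)
    tied = np.flatnonzero(absr == best_abs)
    names_arr = np.asarray(all_names, dtype=object)
    best_idx = min(tied, key=lambda i: all_names[i])
    best_name = all_names[best_idx]
    best_r = float(r[best_idx])
    best_p = float(_p_from_r(best_r, m[best_idx]))

    p_vals = _p_from_r(r, m)
    sig = np.isfinite(absr) & (p_vals < alpha)
    if family == "raw":
        cand_idx = np.flatnonzero(sig)
        order = np.lexsort((names_arr[cand_idx], -absr[cand_idx]))
        candidates = list(names_arr[cand_idx][order])
    else:
        near = sig & (absr >= near_frac * best_abs)
        cand_idx = np.flatnonzero(near)
        order = np.lexsort((names_arr[cand_idx], -absr[cand_idx]))
        candidates = list(names_arr[cand_idx][order][:cap])
        if best_name not in candidates and best_p < alpha:
            candidates.insert(0, best_name)

    grid = None
    if return_grid:
        grid = pd.DataFrame({"name": all_names, "r": r, "p": p_vals})
    return ScreenResult(depth_layer=depth_layer, family=family,
                        best_name=best_name, r=best_r, p=best_p,
                        candidates=candidates, grid=grid)


# ---------------------------------------------------------------------------
# redundancy and collinearity filters
# ---------------------------------------------------------------------------

def redundancy_filter(columns: pd.DataFrame, smc, labels: list[str],
                      r_cut: float = 0.90) -> list[str]:
    """Greedy removal of near-duplicate features.

    Features are walked in descending |r|-with-SMC order (ties
    lexicographic); a feature is kept only if its |r| with every already
    kept feature is below ``r_cut``.
    """
    y = np.asarray(smc, dtype=float)
    scored = []
    for lab in labels:
        r, _ = pearson_with_p(columns[lab], y)
        scored.append((-abs(r) if np.isfinite(r) else 0.0, lab))
    scored.sort()
    kept: list[str] = []
    for _, lab in scored:
        x = columns[lab].to_numpy(float)
        ok = True
        for kl in kept:
            rr, _ = pearson_with_p(x, columns[kl])
            if np.isfinite(rr) and abs(rr) >= r_cut:
                ok = False
                break
        if ok:
            kept.append(lab)
    return kept


def _vif_values(Z: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1−R_j²) from regressing column j on the other columns."""
    n, p = Z.shape
    Zc = Z - Z.mean(axis=0)
    sd = Zc.std(axis=0)
    sd[sd == 0] = 1.0
    Zc = Zc / sd
    vifs = np.empty(p)
    for j in range(p):
        others = np.delete(Zc, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, Zc[:, j], rcond=None)
        resid = Zc[:, j] - A @ coef
        sst = float((Zc[:, j] ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 1.0
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_filter(columns: pd.DataFrame, labels: list[str],
               vif_max: float = 10.0) -> list[str]:
    """Iteratively drop the largest-VIF feature until all VIF ≤ ``vif_max``.

    Perfectly collinear features (VIF = ∞) are dropped first, with a
    warning.  Rows with any undefined value are excluded from the VIF
    regressions.
    """
    labels = list(labels)
    while len(labels) >= 2:
        Z = columns[labels].to_numpy(float)
        Z = Z[np.all(np.isfinite(Z), axis=1)]
        if Z.shape[0] <= len(labels) + 1:
            warnings.warn("too few rows for a VIF check; subset left as is",
                          stacklevel=2)
            break
        vifs = _vif_values(Z)
        worst = int(np.argmax(vifs))
        if not np.isfinite(vifs[worst]):
            warnings.warn(f"feature {labels[worst]!r} is perfectly collinear; "
                          "dropped", stacklevel=2)
            labels.pop(worst)
            continue
        if vifs[worst] <= vif_max:
            break
        labels.pop(worst)
    return labels


# ---------------------------------------------------------------------------
# family pipeline
# ---------------------------------------------------------------------------

def materialize_features(features: pd.DataFrame,
                         labels: list[str]) -> pd.DataFrame:
    """Columns for a mixed list of position labels and index names."""
    defs, raw = [], []
    for lab in labels:
        if "(" in lab:
            defs.append(parse_index_name(lab))
        else:
            Position.from_label(lab)  # validates
            raw.append(lab)
    parts = []
    if raw:
        parts.append(features[raw])
    if defs:
        parts.append(batch_indices(features, defs))
    out = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=features.index)
    return out[labels]


def screen_family(features: pd.DataFrame, smc, family: str,
                  alpha: float = 0.05, r_cut: float = 0.90,
                  vif_max: float = 10.0, near_frac: float = 0.95,
                  cap: int = 20, positions: list[str] | None = None,
                  depth_layer: str = "") -> ScreenResult:
    """Full screening of one family: exhaustive search, significance,
    redundancy removal, VIF pruning."""
    res = exhaustive_search(features, smc, family, alpha=alpha,
                            near_frac=near_frac, cap=cap,
                            positions=positions, depth_layer=depth_layer)
    if not res.candidates:
        res.survivors = []
        return res
    cols = materialize_features(features, res.candidates)
    kept = redundancy_filter(cols, smc, res.candidates, r_cut=r_cut)
    if len(kept) >= 2:
        kept = vif_filter(cols, kept, vif_max=vif_max)
    res.survivors = kept
    return res
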