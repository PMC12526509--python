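"""Input combinations and the depth × combination × model evaluation grid.

Seven model-input combinations are formed from the three feature families
(raw GLCM textures, 2-D texture indices, 3-D texture indices) — exactly
the non-empty subsets:

====  ==========================
id    members
====  ==========================
1     raw textures
2     2-D indices
3     3-D indices
4     raw + 2-D
5     raw + 3-D
6     2-D + 3-D
7     raw + 2-D + 3-D (fusion)
====  ==========================

``run_grid`` screens per depth (on training rows only in strict mode, or
on all rows in the screen-first mode that screens before splitting),
fits every combination with every model family, and returns the 3 × 7 × 3
grid of validation records.  Failures in single cells are flagged, never
fatal.  SMC enters the models in percent, so RMSE is reported in
percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modeling import (MODEL_FAMILIES, EvalRecord, ModelSpec, evaluate,
                       fit_model, make_split)
from .screening import ScreenResult, materialize_features, screen_family
from .synthetic import DEPTH_LAYERS

__all__ = [
    "COMBINATIONS",
    "FEATURE_GROUPS",
    "assemble_combination",
    "screen_groups",
    "run_grid",
    "records_frame",
    "scatter_report",
    "improvement_report",
]

FEATURE_GROUPS = ("raw", "idx2d", "idx3d")

COMBINATIONS: dict[int, tuple[str, ...]] = {
    1: ("raw",),
    2: ("idx2d",),
    3: ("idx3d",),
    4: ("raw", "idx2d"),
    5: ("raw", "idx3d"),
    6: ("idx2d", "idx3d"),
    7: ("raw", "idx2d", "idx3d"),
}


def assemble_combination(survivors: dict[str, list[str]],
                         combination_id: int) -> list[str]:
    """Deduplicated union of the member families' surviving feature labels."""
    if combination_id not in COMBINATIONS:
        raise ValueError(f"combination id must be 1..7, got {combination_id}")
    labels: list[str] = []
    for group in COMBINATIONS[combination_id]:
        for lab in survivors.get(group, []):
            if lab not in labels:
                labels.append(lab)
    if not labels:
        raise ValueError(
            f"combination {combination_id} is empty: no surviving features "
            f"in groups {COMBINATIONS[combination_id]}")
    return labels


def screen_groups(features: pd.DataFrame, smc, depth_layer: str = "",
                  alpha: float = 0.05, cap: int = 20,
                  ) -> tuple[dict[str, list[str]], list[ScreenResult]]:
    """Screen the raw positions and all ten index families at one depth.

    Returns the survivor labels per feature group and the per-family
    screening results (best combination, r, p).
    """
    from .indices import FAMILIES_2D, FAMILIES_3D

    results: list[ScreenResult] = []
    survivors: dict[str, list[str]] = {g: [] for g in FEATURE_GROUPS}
    for group, fams in (("raw", ("raw",)), ("idx2d", FAMILIES_2D),
                        ("idx3d", FAMILIES_3D)):
        for fam in fams:
            res = screen_family(features, smc, fam, alpha=alpha, cap=cap,
                                depth_layer=depth_layer)
            results.append(res)
            for lab in res.survivors:
                if lab not in survivors[group]:
                    survivors[group].append(lab)
    return survivors, results


def run_grid(features: pd.DataFrame, smc_table: pd.DataFrame, seed: int = 0,
             strict: bool = True, depth_layers=DEPTH_LAYERS,
             families=MODEL_FAMILIES, combinations=tuple(range(1, 8)),
             alpha: float = 0.05, cap: int = 20,
             model_overrides: dict | None = None,
             ) -> tuple[list[EvalRecord], list[ScreenResult]]:
    """The full evaluation grid.

    Parameters
    ----------
    features : plots × 48-position table (index = plot_id).
    smc_table : long table (plot_id, depth_layer, smc) in volumetric
        fraction; converted to percent for modeling.
    strict : screen on training rows only (no leakage).  When False, the
        screening uses all plots before splitting (the order reported
        field studies typically apply).
    model_overrides : extra keyword arguments forwarded to every
        :class:`ModelSpec` (e.g. a smaller BPNN ``hidden_grid``).
    """
    records: list[EvalRecord] = []
    screens: list[ScreenResult] = []
    overrides = model_overrides or {}
    for depth in depth_layers:
        y_all = (smc_table[smc_table.depth_layer == depth]
                 .set_index("plot_id")["smc"] * 100.0)
        y_all = y_all.reindex(features.index).dropna()
        split = make_split(y_all, depth_layer=depth, seed=seed)
        screen_rows = split.train_ids if strict else list(y_all.index)
        survivors, res = screen_groups(features.loc[screen_rows],
                                       y_all.loc[screen_rows],
                                       depth_layer=depth, alpha=alpha, cap=cap)
        screens.extend(res)
        needed = sorted({lab for labs in survivors.values() for lab in labs})
        table = materialize_features(features, needed) if needed else None
        for cid in combinations:
            try:
                labels = assemble_combination(survivors, cid)
            except ValueError as exc:
                for fam in families:
                    records.append(EvalRecord(depth, cid, fam, np.nan, np.nan,
                                              np.nan, flags=[str(exc)]))
                continue
            # drop rows with undefined feature values from fitting
            cols = table[labels]
            usable = cols.index[np.all(np.isfinite(cols.to_numpy(float)), axis=1)]
            tr = [p for p in split.train_ids if p in set(usable)]
            va = [p for p in split.validation_ids if p in set(usable)]
            for fam in families:
                spec = ModelSpec(family=fam, seed=_fan_seed(seed, depth, cid, fam),
                                 **overrides)
                try:
                    fitted = fit_model(cols.loc[tr], y_all.loc[tr], labels,
                                       spec, folds=split.folds)
                    rec = evaluate(fitted, cols.loc[va], y_all.loc[va],
                                   depth_layer=depth, combination_id=cid)
                except Exception as exc:  # a failed cell must not abort the grid
                    rec = EvalRecord(depth, cid, fam, np.nan, np.nan, np.nan,
                                     flags=[f"failed: {exc}"])
                records.append(rec)
    return records, screens


def _fan_seed(seed: int, depth: str, cid: int, fam: str) -> int:
    """Deterministic per-cell seed below 2^31 (stable across processes)."""
    import zlib

    h = zlib.crc32(f"{depth}|{cid}|{fam}".encode())
    return int((seed * 1_000_003 + h) % (2 ** 31 - 1))


def records_frame(records: list[EvalRecord]) -> pd.DataFrame:
    """Long-format results table (depth, combination, model, R2, RMSE, MRE)."""
    return pd.DataFrame([
        {"depth_layer": r.depth_layer, "combination": r.combination_id,
         "model": r.family, "R2": r.r2, "RMSE": r.rmse, "MRE": r.mre,
         "flags": ";".join(r.flags)}
        for r in records
    ])


def scatter_report(records: list[EvalRecord], smc_table: pd.DataFrame,
                   combinations=(1, 7)) -> pd.DataFrame:
    """Plot-ready observed-vs-predicted table with least-squares fit.

    One row per validation plot for each depth × model × combination cell,
    plus the fitted slope/intercept (columns ``slope``/``intercept``
    repeated per cell) for drawing the regression and 1:1 lines.
    """
    rows = []
    for rec in records:
        if rec.combination_id not in combinations or rec.predictions is None:
            continue
        obs = (smc_table[smc_table.depth_layer == rec.depth_layer]
               .set_index("plot_id")["smc"] * 100.0)
        obs = obs.loc[rec.predictions.index]
        x = obs.to_numpy(float)
        yhat = rec.predictions.to_numpy(float)
        slope, intercept = np.polyfit(x, yhat, 1) if len(x) >= 2 else (np.nan, np.nan)
        for pid in rec.predictions.index:
            rows.append({
                "depth_layer": rec.depth_layer, "model": rec.family,
                "combination": rec.combination_id, "plot_id": pid,
                "observed": float(obs[pid]),
                "predicted": float(rec.predictions[pid]),
                "slope": float(slope), "intercept": float(intercept),
            })
    return pd.DataFrame(rows)


def improvement_report(records: list[EvalRecord], family: str = "RF",
                       base: int = 1, fused: int = 7) -> pd.DataFrame:
    """Relative validation-R² gain of the fused combination over the base,
    per depth: 100·(R²_fused − R²_base)/R²_base."""
    df = records_frame(records)
    rows = []
    for depth in df.depth_layer.unique():
        sel = df[(df.depth_layer == depth) & (df.model == family)]
        r2b = sel[sel.combination == base].R2
        r2f = sel[sel.combination == fused].R2
        if len(r2b) and len(r2f):
            b, f = float(r2b.iloc[0]), float(r2f.iloc[0])
            gain = 100.0 * (f - b) / b if b and np.isfinite(b) else np.nan
            rows.append({"depth_layer": depth, "model": family,
                         "R2_base": b, "R2_fused": f,
                         "improvement_pct": gain})
    return pd.DataFrame(rows)
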