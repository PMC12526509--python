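"""Two- and three-position texture indices.

A texture index is an arithmetic combination of two or three "positions"
(texture metric × band values, e.g. HOM6).  Six two-position families and
four three-position families are defined:

========  ===========================================
family    formula
========  ===========================================
ATI       Ti + Tj
DTI       Ti − Tj
NDTI      (Ti − Tj) / (Ti + Tj)
RTI       Ti / Tj
RDTI      1/Ti − 1/Tj
RATI      1/Ti + 1/Tj
BDSI      (Ti − Tj) / (Tk − Tj)
DTTI      Ti − Tj − Tk
MSI       Ti · Tj · Tk
NDTTI     (Ti − Tj − Tk) / (Ti + Tj + Tk)
========  ===========================================

Degenerate denominators (and reciprocals of zero) yield NaN — the undefined
marker — rather than an epsilon-stabilised value, so the downstream
correlation ranking is never silently distorted.  Tuples are ordered and
repetition is allowed, giving 48² two-position and 48³ three-position
combinations per family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glcm import Position

__all__ = [
    "FAMILIES_2D",
    "FAMILIES_3D",
    "IndexDefinition",
    "eval_2d",
    "eval_3d",
    "batch_indices",
    "parse_index_name",
]

FAMILIES_2D = ("ATI", "DTI", "NDTI", "RTI", "RDTI", "RATI")
FAMILIES_3D = ("BDSI", "DTTI", "MSI", "NDTTI")


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    return out


def _recip(x):
    return _safe_div(1.0, x)


_EVAL_2D = {
    "ATI": lambda ti, tj: np.asarray(ti, float) + tj,
    "DTI": lambda ti, tj: np.asarray(ti, float) - tj,
    "NDTI": lambda ti, tj: _safe_div(np.asarray(ti, float) - tj,
                                     np.asarray(ti, float) + tj),
    "RTI": lambda ti, tj: _safe_div(ti, tj),
    "RDTI": lambda ti, tj: _recip(ti) - _recip(tj),
    "RATI": lambda ti, tj: _recip(ti) + _recip(tj),
}

_EVAL_3D = {
    "BDSI": lambda ti, tj, tk: _safe_div(np.asarray(ti, float) - tj,
                                         np.asarray(tk, float) - tj),
    "DTTI": lambda ti, tj, tk: np.asarray(ti, float) - tj - tk,
    "MSI": lambda ti, tj, tk: np.asarray(ti, float) * tj * tk,
    "NDTTI": lambda ti, tj, tk: _safe_div(
        np.asarray(ti, float) - tj - tk,
        np.asarray(ti, float) + tj + np.asarray(tk, float)),
}


def eval_2d(family: str, ti, tj):
    """Evaluate a two-position index; NaN marks undefined results."""
    if family not in _EVAL_2D:
        raise ValueError(f"unknown 2-D index family {family!r}")
    return _EVAL_2D[family](ti, tj)


def eval_3d(family: str, ti, tj, tk):
    """Evaluate a three-position index; NaN marks undefined results."""
    if family not in _EVAL_3D:
        raise ValueError(f"unknown 3-D index family {family!r}")
    return _EVAL_3D[family](ti, tj, tk)


@dataclass(frozen=True)
class IndexDefinition:
    """One index family applied to an ordered position tuple."""

    family: str
    positions: tuple[Position, ...]

    def __post_init__(self) -> None:
        if self.family in FAMILIES_2D:
            arity = 2
        elif self.family in FAMILIES_3D:
            arity = 3
        else:
            raise ValueError(f"unknown index family {self.family!r}")
        if len(self.positions) != arity:
            raise ValueError(
                f"{self.family} takes {arity} positions, got {len(self.positions)}")

    @property
    def arity(self) -> int:
        return len(self.positions)

    @property
    def name(self) -> str:
        inner = ",".join(p.label for p in self.positions)
        return f"{self.family}({inner})"

    def evaluate(self, features: pd.DataFrame) -> np.ndarray:
        cols = [features[p.label].to_numpy(float) for p in self.positions]
        if self.arity == 2:
            return eval_2d(self.family, *cols)
        return eval_3d(self.family, *cols)


_NAME_RE = re.compile(r"^([A-Z]+)\(([A-Z0-9,]+)\)$")


def parse_index_name(name: str) -> IndexDefinition:
    """Parse ``"DTTI(HOM5,HOM2,SEC6)"`` back into an :class:`IndexDefinition`."""
    m = _NAME_RE.match(name.replace(" ", ""))
    if not m:
        raise ValueError(f"malformed index name {name!r}")
    family, inner = m.groups()
    positions = tuple(Position.from_label(lab) for lab in inner.split(","))
    return IndexDefinition(family, positions)


def batch_indices(features: pd.DataFrame,
                  definitions: list[IndexDefinition]) -> pd.DataFrame:
    """Evaluate a list of index definitions against a plots×positions table.

    Returns a DataFrame with one column per definition (named by the index
    grammar ``FAMILY(POS,...)``); undefined entries are NaN.
    """
    out = {}
    for d in definitions:
        for p in d.positions:
            if p.label not in features.columns:
                raise KeyError(f"position {p.label!r} missing from feature table")
        vals = d.evaluate(features)
        vals = np.where(np.isfinite(vals), vals, np.nan)
        out[d.name] = vals
    return pd.DataFrame(out, index=features.index)
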