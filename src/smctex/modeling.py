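"""Regression models for depth-resolved SMC estimation.

Three families are compared under identical preprocessing:

* **RF** — 200-tree bagged regression forest, squared-error split
  criterion, all features considered per split, out-of-bag error recorded.
* **PLSR** — partial least squares; the latent-variable count grows while
  each added component raises the 10-fold CV-predicted cumulative explained
  variance of Y by at least 5 points.
* **BPNN** — single hidden layer with tanh activation trained by a
  quasi-Newton batch optimizer (lbfgs); hidden size selected over
  {10, 15, …, 100} by fold-averaged CV RMSE, then refit with multiple
  restarts keeping the best.

Plots are split 2:1 into training and validation by SMC-stratified
sampling; all predictors are z-standardized with statistics computed on
training rows only (population sd), and the same parameters are applied to
held-out rows.  Validation metrics: R² = 1 − SSE/SST, RMSE (SMC units) and
MRE = mean(|ŷ−y|/y)·100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "SplitPlan",
    "EvalRecord",
    "make_split",
    "fold_standardize",
    "FittedModel",
    "fit_model",
    "evaluate",
]

MODEL_FAMILIES = ("RF", "PLSR", "BPNN")

DEFAULT_HIDDEN_GRID = tuple(range(10, 101, 5))


@dataclass(frozen=True)
class ModelSpec:
    """One model family with its hyperparameter settings."""

    family: str
    seed: int = 0
    n_trees: int = 200                      # RF
    max_lv: int = 10                        # PLSR search ceiling
    lv_gain: float = 0.05                   # PLSR incremental-gain rule
    hidden_grid: tuple[int, ...] = DEFAULT_HIDDEN_GRID  # BPNN
    n_restarts: int = 5                     # BPNN
    max_iter: int = 500                     # BPNN
    weight_decay: float | None = None       # BPNN L2; None = CV-selected
    decay_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class SplitPlan:
    """Train/validation plot ids plus the CV fold assignment over training."""

    depth_layer: str
    train_ids: list
    validation_ids: list
    folds: list[tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"train/validation overlap: {sorted(overlap)[:5]}")


@dataclass
class EvalRecord:
    """Validation-set performance of one depth × combination × model cell."""

    depth_layer: str
    combination_id: int
    family: str
    r2: float
    rmse: float
    mre: float
    predictions: pd.Series | None = None
    flags: list[str] = field(default_factory=list)


def make_split(smc: pd.Series, depth_layer: str = "", ratio: float = 1 / 3,
               seed: int = 0, n_folds: int = 10) -> SplitPlan:
    """SMC-stratified 2:1 train/validation split.

    Plots are sorted by SMC and partitioned into consecutive strata of
    three; one plot per stratum (chosen at random) goes to validation, so
    both sets span the full moisture range.
    """
    if len(smc) < 9:
        raise ValueError("need at least 9 plots for a stratified split")
    rng = np.random.default_rng(seed)
    order = smc.sort_values(kind="mergesort").index.to_list()
    train, val = [], []
    per_stratum = max(2, int(round(1 / ratio)))
    for s in range(0, len(order), per_stratum):
        stratum = order[s:s + per_stratum]
        n_val = len(stratum) // per_stratum
        pick = set(rng.choice(len(stratum), size=n_val, replace=False)) if n_val else set()
        for i, pid in enumerate(stratum):
            (val if i in pick else train).append(pid)
    k = min(n_folds, len(train))
    kf = KFold(n_splits=k, shuffle=True,
               random_state=int(rng.integers(2 ** 31 - 1)))
    folds = [(tr, te) for tr, te in kf.split(np.arange(len(train)))]
    return SplitPlan(depth_layer=depth_layer, train_ids=train,
                     validation_ids=val, folds=folds)


def fold_standardize(train: pd.DataFrame, apply_to: pd.DataFrame | None = None):
    """Z-standardize with training statistics (population sd).

    Zero-variance training columns are dropped with a warning.  Returns
    ``(train_z, apply_z, means, sds)``; ``apply_z`` is None when no
    held-out table is given.
    """
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.all():
        dropped = list(train.columns[~keep])
        warnings.warn(f"zero-variance features dropped: {dropped}", stacklevel=2)
    cols = train.columns[keep]
    means, sds = means[cols], sds[cols]
    train_z = (train[cols] - means) / sds
    apply_z = None if apply_to is None else (apply_to[cols] - means) / sds
    return train_z, apply_z, means, sds


@dataclass
class FittedModel:
    """A trained model plus the standardization fitted on its training set."""

    family: str
    model: object
    means: pd.Series
    sds: pd.Series
    labels: list[str]
    chosen: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        Z = (features[self.labels] - self.means) / self.sds
        yhat = self.model.predict(Z.to_numpy(float))
        return np.asarray(yhat, dtype=float).ravel()


def _cv_pairs(n: int, folds, spec: ModelSpec):
    """Reindex a stored fold plan to n rows, or build a fresh seeded one."""
    if folds and all(np.max(tr.tolist() + te.tolist()) < n for tr, te in folds):
        return folds
    k = min(spec.cv_folds, n)
    kf = KFold(n_splits=k, shuffle=True, random_state=spec.seed)
    return list(kf.split(np.arange(n)))


def _select_plsr_lv(X: pd.DataFrame, y: np.ndarray, spec: ModelSpec,
                    folds) -> int:
    """Smallest LV count reached by adding components while each addition
    gains ≥ ``lv_gain`` CV-predicted explained Y variance."""
    n, p = X.shape
    kmax = max(1, min(spec.max_lv, p, n - 2))
    pairs = _cv_pairs(n, folds, spec)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = []
    for k in range(1, kmax + 1):
        sse = 0.0
        for tr, te in pairs:
            Xtr, Xte, *_ = fold_standardize(X.iloc[tr], X.iloc[te])
            ytr = y[tr]
            k_eff = min(k, Xtr.shape[1], len(tr) - 1)
            pls = PLSRegression(n_components=k_eff, scale=False)
            pls.fit(Xtr.to_numpy(float), ytr - ytr.mean())
            pred = pls.predict(Xte.to_numpy(float)).ravel() + ytr.mean()
            sse += float(((y[te] - pred) ** 2).sum())
        r2.append(1.0 - sse / sst if sst > 0 else 0.0)
    chosen = 1
    while chosen < kmax and r2[chosen] - r2[chosen - 1] >= spec.lv_gain:
        chosen += 1
    return chosen


def _make_bpnn(hidden: int, alpha: float, spec: ModelSpec,
               seed: int) -> MLPRegressor:
    return MLPRegressor(hidden_layer_sizes=(hidden,), activation="tanh",
                        solver="lbfgs", max_iter=spec.max_iter, alpha=alpha,
                        random_state=seed)


def _bpnn_cv_rmse(X: pd.DataFrame, y: np.ndarray, hidden: int, alpha: float,
                  spec: ModelSpec, pairs, seed: int) -> float:
    sse, cnt = 0.0, 0
    for tr, te in pairs:
        Xtr, Xte, *_ = fold_standardize(X.iloc[tr], X.iloc[te])
        net = _make_bpnn(hidden, alpha, spec, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            net.fit(Xtr.to_numpy(float), y[tr])
        pred = net.predict(Xte.to_numpy(float))
        sse += float(((y[te] - pred) ** 2).sum())
        cnt += len(te)
    return np.sqrt(sse / cnt)


def fit_model(features: pd.DataFrame, smc: pd.Series, labels: Sequence[str],
              spec: ModelSpec, folds=None) -> FittedModel:
    """Train one model family on the given training rows.

    ``features``/``smc`` are training rows only; ``folds`` is an optional
    pre-made CV plan (row indices into the training set) reused across
    model families so every family sees the same folds.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no features to fit")
    X = features[labels]
    y = smc.to_numpy(float)
    Xz, _, means, sds = fold_standardize(X)
    kept = list(Xz.columns)
    flags: list[str] = []
    chosen: dict = {}

    if spec.family == "RF":
        model = RandomForestRegressor(
            n_estimators=spec.n_trees, criterion="squared_error",
            max_features=1.0, bootstrap=True, oob_score=True,
            random_state=spec.seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model.fit(Xz.to_numpy(float), y)
        oob = getattr(model, "oob_score_", None)
        chosen = {"n_trees": spec.n_trees, "oob_r2": oob}
    elif spec.family == "PLSR":
        n_lv = _select_plsr_lv(X[kept], y, spec, folds)
        model = _CenteredPLS(n_lv)
        model.fit(Xz.to_numpy(float), y)
        chosen = {"n_lv": n_lv}
    else:  # BPNN
        pairs = _cv_pairs(len(y), folds, spec)
        # hidden size at a fixed moderate decay, then weight decay (the
        # validation-controlled capacity surrogate for LM early stopping),
        # then restarts — all scored by the same fold-averaged CV RMSE
        search_alpha = spec.weight_decay if spec.weight_decay is not None else 0.1
        grid = [h for h in spec.hidden_grid]
        scores = [_bpnn_cv_rmse(X[kept], y, h, search_alpha, spec, pairs,
                                spec.seed) for h in grid]
        hidden = grid[int(np.argmin(scores))]
        if spec.weight_decay is None:
            a_scores = [_bpnn_cv_rmse(X[kept], y, hidden, a, spec, pairs,
                                      spec.seed) for a in spec.decay_grid]
            alpha = spec.decay_grid[int(np.argmin(a_scores))]
        else:
            alpha = spec.weight_decay
        seeds = [spec.seed + 1000 * rs for rs in range(spec.n_restarts)]
        restart_scores = [
            _bpnn_cv_rmse(X[kept], y, hidden, alpha, spec, pairs, s)
            for s in seeds
        ]
        best_seed = seeds[int(np.argmin(restart_scores))]
        model = _make_bpnn(hidden, alpha, spec, best_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xz.to_numpy(float), y)
        if model.n_iter_ >= spec.max_iter:
            flags = ["bpnn_not_converged"]
        chosen = {"hidden": hidden, "weight_decay": float(alpha),
                  "cv_rmse": float(np.min(restart_scores)),
                  "optimizer": "lbfgs", "restart_seed": best_seed}
    return FittedModel(family=spec.family, model=model, means=means, sds=sds,
                       labels=kept, chosen=chosen, flags=flags)


class _CenteredPLS:
    """PLS regression on pre-standardized X with internally centered y."""

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, X, y):
        self._ymean = float(np.mean(y))
        self._pls = PLSRegression(
            n_components=min(self.n_components, X.shape[1],
                             max(1, X.shape[0] - 1)),
            scale=False)
        self._pls.fit(X, np.asarray(y, float) - self._ymean)
        return self

    def predict(self, X):
        return self._pls.predict(X).ravel() + self._ymean


def evaluate(model: FittedModel, features: pd.DataFrame, smc: pd.Series,
             depth_layer: str = "", combination_id: int = 0) -> EvalRecord:
    """Validation metrics of a fitted model.

    R² is NaN (undefined marker) when the validation SMC has zero variance;
    MRE requires strictly positive observed SMC.
    """
    if len(smc) == 0:
        raise ValueError("validation set is empty")
    y = smc.to_numpy(float)
    if (y <= 0).any():
        raise ValueError("MRE requires strictly positive observed SMC")
    yhat = model.predict(features.loc[smc.index])
    sse = float(((y - yhat) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    rmse = float(np.sqrt(sse / len(y)))
    mre = float(np.mean(np.abs(yhat - y) / y) * 100.0)
    return EvalRecord(depth_layer=depth_layer, combination_id=combination_id,
                      family=model.family, r2=r2, rmse=rmse, mre=mre,
                      predictions=pd.Series(yhat, index=smc.index),
                      flags=list(model.flags))
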