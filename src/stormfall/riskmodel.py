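"""Risk-factor attribution with a regression-tree ensemble.

ΔNPV pixels are sampled with their co-located risk factors and modelled
with a random forest.  The forest fit itself delegates to scikit-learn, but
the four attribution statistics are computed here, from tree structures and
predictions, so their conventions are explicit:

* **VIMP** — permutation importance: increase in held-out MSE when one
  factor's values are shuffled, reported ×1000.
* **Minimal depth (MD)** — mean depth of the first split on a factor across
  trees (root = 0); trees that never split on it contribute a penalty depth
  of one plus their maximum depth.
* **Partial dependence** — model response along one factor with the others
  pinned at their mean values (the classical data-averaged variant is
  available via ``conditioning='data'``).
* **Friedman's H** — share of the two-way partial-dependence variance not
  explained by the two one-way functions, on a subsample; 0 = additive,
  1 = purely interactive.

The categorical geology factor is one-hot encoded internally and reported
as a single factor (columns permuted jointly; minimal depth over any of its
levels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .synthetic import GEOLOGY_CLASSES, RISK_FACTORS


@dataclass
class RiskSample:
    """Sampled pixels: risk-factor table, response vector and coordinates."""

    table: pd.DataFrame  # predictors + "dnpv" + "row"/"col"

    @property
    def predictors(self) -> list:
        return [c for c in self.table.columns if c not in ("dnpv", "row", "col")]

    @property
    def n(self) -> int:
        return len(self.table)


@dataclass
class EnsembleHandle:
    """A fitted forest plus the encoded design matrix and split bookkeeping."""

    model: RandomForestRegressor
    feature_names: list
    factor_columns: dict  # factor -> list of column indices
    X: np.ndarray
    y: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_r2: float
    test_r2: float

    @property
    def factors(self) -> list:
        return list(self.factor_columns)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def sample_pixels(
    risk_rasters: dict,
    response,
    n: int = 20000,
    seed: int = 0,
) -> RiskSample:
    """Sample valid-response pixels uniformly without replacement.

    Rows missing any predictor value are dropped after sampling (as with
    field locations lacking a risk-factor layer), so the returned table can
    be smaller than ``n``.  If fewer than ``n`` valid pixels exist, all are
    taken with a warning.
    """
    resp = np.asarray(getattr(response, "delta", response), dtype=float)
    shapes = {r.shape for r in risk_rasters.values()} | {resp.shape}
    if len(shapes) > 1:
        raise ValueError("risk rasters and response are not aligned")
    valid = np.flatnonzero(np.isfinite(resp))
    rng = np.random.default_rng(seed)
    if valid.size < n:
        warnings.warn(
            f"only {valid.size} valid response pixels available; sampling all",
            stacklevel=2,
        )
        chosen = valid
    else:
        chosen = rng.choice(valid, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, resp.shape)
    data = {name: np.asarray(r, dtype=float)[rows, cols] for name, r in risk_rasters.items()}
    table = pd.DataFrame(data)
    table["dnpv"] = resp[rows, cols]
    table["row"], table["col"] = rows, cols
    keep = ~table[list(risk_rasters)].isna().any(axis=1)
    return RiskSample(table.loc[keep].reset_index(drop=True))


def _encode(sample: RiskSample) -> tuple:
    """Design matrix with geology one-hot encoded; returns (X, names, cols)."""
    names: list = []
    columns: list = []
    factor_columns: dict = {}
    for factor in sample.predictors:
        vals = sample.table[factor].to_numpy(dtype=float)
        if factor == "geology":
            idx = []
            for k, cls in enumerate(GEOLOGY_CLASSES):
                idx.append(len(names))
                names.append(f"geology={cls}")
                columns.append((vals == k).astype(float))
            factor_columns[factor] = idx
        else:
            factor_columns[factor] = [len(names)]
            names.append(factor)
            columns.append(vals)
    return np.column_stack(columns), names, factor_columns


def fit_ensemble(
    sample: RiskSample,
    n_trees: int = 1000,
    seed: int = 0,
    holdout_fraction: float = 0.25,
    max_features: float = 1 / 3,
) -> EnsembleHandle:
    """Fit the regression forest on a seed-fixed 75/25 train/holdout split.

    The holdout rows feed the permutation-importance evaluation; mtry
    defaults to one third of the predictors, the regression-forest
    convention.
    """
    if sample.n < 50:
        raise ValueError("need at least 50 rows to fit the ensemble")
    y = sample.table["dnpv"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant; nothing to model")
    X, names, factor_columns = _encode(sample)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sample.n)
    n_test = max(int(round(holdout_fraction * sample.n)), 1)
    test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    model.fit(X[train_idx], y[train_idx])
    return EnsembleHandle(
        model=model,
        feature_names=names,
        factor_columns=factor_columns,
        X=X,
        y=y,
        train_idx=train_idx,
        test_idx=test_idx,
        train_r2=float(model.score(X[train_idx], y[train_idx])),
        test_r2=float(model.score(X[test_idx], y[test_idx])),
    )


def vimp(
    ensemble: EnsembleHandle,
    seed: int = 0,
    n_repeats: int = 1,
    permuter=None,
) -> pd.Series:
    """Permutation importance per factor: Δ holdout MSE × 1000.

    One-hot columns of a categorical factor are permuted jointly with one
    shared permutation.  ``permuter(n, rng) -> indices`` can replace the
    random shuffle (e.g. with the identity, which must yield exactly 0).
    """
    rng = np.random.default_rng(seed)
    Xt = ensemble.X[ensemble.test_idx]
    yt = ensemble.y[ensemble.test_idx]
    base_mse = float(np.mean((ensemble.predict(Xt) - yt) ** 2))
    draw = permuter or (lambda n, r: r.permutation(n))
    out = {}
    for factor, cols in ensemble.factor_columns.items():
        deltas = []
        for _ in range(n_repeats):
            idx = np.asarray(draw(len(yt), rng))
            Xp = Xt.copy()
            Xp[:, cols] = Xt[np.ix_(idx, cols)]
            mse = float(np.mean((ensemble.predict(Xp) - yt) ** 2))
            deltas.append(mse - base_mse)
        out[factor] = 1000.0 * float(np.mean(deltas))
    return pd.Series(out, name="vimp")


def minimal_depth(ensemble: EnsembleHandle) -> pd.Series:
    """Mean depth of the first split on each factor across all trees.

    Root depth is 0.  A tree that never splits on the factor contributes a
    penalty depth of (its maximum depth + 1).
    """
    col_to_factor = {
        c: f for f, cols in ensemble.factor_columns.items() for c in cols
    }
    sums = {f: 0.0 for f in ensemble.factor_columns}
    for est in ensemble.model.estimators_:
        tree = est.tree_
        depth = np.zeros(tree.node_count, dtype=int)
        first: dict = {}
        max_depth = 0
        for node in range(tree.node_count):  # parents precede children
            d = depth[node]
            max_depth = max(max_depth, d)
            left, right = tree.children_left[node], tree.children_right[node]
            if left == -1:
                continue
            depth[left] = depth[right] = d + 1
            factor = col_to_factor[tree.feature[node]]
            if factor not in first or d < first[factor]:
                first[factor] = d
        penalty = max_depth + 1
        for f in sums:
            sums[f] += first.get(f, penalty)
    n_trees = len(ensemble.model.estimators_)
    return pd.Series({f: s / n_trees for f, s in sums.items()}, name="minimal_depth")


def importance_table(ensemble: EnsembleHandle, seed: int = 0) -> pd.DataFrame:
    """VIMP and minimal depth with ranks (1 = most important under each)."""
    v = vimp(ensemble, seed=seed)
    md = minimal_depth(ensemble)
    out = pd.DataFrame({"vimp": v, "minimal_depth": md})
    out["rank_vimp"] = out["vimp"].rank(ascending=False).astype(int)
    out["rank_md"] = out["minimal_depth"].rank(ascending=True, method="first").astype(int)
    return out


def _grid_for(ensemble: EnsembleHandle, factor: str, grid_size: int) -> np.ndarray:
    cols = ensemble.factor_columns[factor]
    if factor == "geology":
        return np.arange(len(cols), dtype=float)
    vals = ensemble.X[:, cols[0]]
    return np.linspace(vals.min(), vals.max(), grid_size)


def _set_factor(X: np.ndarray, ensemble: EnsembleHandle, factor: str, value) -> None:
    """Overwrite a factor's column(s) in X with one value (in place)."""
    cols = ensemble.factor_columns[factor]
    if factor == "geology":
        for k, c in enumerate(cols):
            X[:, c] = 1.0 if k == int(value) else 0.0
    else:
        X[:, cols[0]] = value


def partial_dependence(
    ensemble: EnsembleHandle,
    factor: str,
    grid_size: int = 25,
    conditioning: str = "mean",
) -> pd.DataFrame:
    """Model response along one factor, others pinned at their means.

    ``conditioning='mean'`` evaluates the model on a single mean row per
    grid value; ``'data'`` averages predictions over all sample rows
    (the classical partial-dependence definition).  Geology is evaluated
    per class.  Returns columns (grid, pd).
    """
    if factor not in ensemble.factor_columns:
        raise ValueError(f"unknown predictor {factor!r}")
    grid = _grid_for(ensemble, factor, grid_size)
    if conditioning == "mean":
        base = ensemble.X.mean(axis=0, keepdims=True)
        rows = np.repeat(base, len(grid), axis=0)
        for i, g in enumerate(grid):
            _set_factor(rows[i : i + 1], ensemble, factor, g)
        values = ensemble.predict(rows)
    elif conditioning == "data":
        values = np.empty(len(grid))
        for i, g in enumerate(grid):
            Xg = ensemble.X.copy()
            _set_factor(Xg, ensemble, factor, g)
            values[i] = float(ensemble.predict(Xg).mean())
    else:
        raise ValueError(f"unknown conditioning {conditioning!r}")
    return pd.DataFrame({"grid": grid, "pd": values})


def _pd_at_points(
    ensemble: EnsembleHandle, Xs: np.ndarray, factors: tuple, chunk: int = 200_000
) -> np.ndarray:
    """Classical PD of one or two factors evaluated at the subsample's own
    factor values, averaging over the subsample's complement rows."""
    cols = [c for f in factors for c in ensemble.factor_columns[f]]
    n = Xs.shape[0]
    out = np.empty(n)
    rows_per = n
    step = max(chunk // rows_per, 1)
    for start in range(0, n, step):
        stop = min(start + step, n)
        # average over all subsample rows, pinning the factor columns of
        # each evaluation point in turn
        block = np.tile(Xs, (stop - start, 1))  # (b*n, p)
        block[:, cols] = np.repeat(Xs[start:stop][:, cols], n, axis=0)
        preds = ensemble.predict(block).reshape(stop - start, n)
        out[start:stop] = preds.mean(axis=1)
    return out


def friedman_h(
    ensemble: EnsembleHandle,
    factor_j: str,
    factor_k: str,
    n_points: int = 3000,
    seed: int = 0,
) -> float:
    """Friedman's H statistic for one factor pair, on a random subsample.

    H² = Σ[PDjk − PDj − PDk]² / Σ PDjk² over centered partial-dependence
    functions evaluated at the subsample points; returns H = √H² ∈ [0, 1].
    """
    if factor_j == factor_k:
        raise ValueError("Friedman's H needs two distinct factors")
    for f in (factor_j, factor_k):
        if f not in ensemble.factor_columns:
            raise ValueError(f"unknown predictor {f!r}")
    rng = np.random.default_rng(seed)
    n = min(n_points, ensemble.X.shape[0])
    rows = rng.choice(ensemble.X.shape[0], size=n, replace=False)
    Xs = ensemble.X[rows]

    pd_j = _pd_at_points(ensemble, Xs, (factor_j,))
    pd_k = _pd_at_points(ensemble, Xs, (factor_k,))
    pd_jk = _pd_at_points(ensemble, Xs, (factor_j, factor_k))
    pd_j = pd_j - pd_j.mean()
    pd_k = pd_k - pd_k.mean()
    pd_jk = pd_jk - pd_jk.mean()
    denom = float(np.sum(pd_jk**2))
    if denom == 0:
        return 0.0
    h2 = float(np.sum((pd_jk - pd_j - pd_k) ** 2)) / denom
    return float(np.sqrt(np.clip(h2, 0.0, 1.0)))


def h_matrix(
    ensemble: EnsembleHandle,
    n_points: int = 3000,
    seed: int = 0,
    factors: list | None = None,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise H statistics (diagonal NaN)."""
    factors = factors or ensemble.factors
    H = pd.DataFrame(np.nan, index=factors, columns=factors)
    for a in range(len(factors)):
        for b in range(a + 1, len(factors)):
            h = friedman_h(ensemble, factors[a], factors[b], n_points=n_points, seed=seed)
            H.iloc[a, b] = H.iloc[b, a] = h
    return H
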