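"""The pairwise key-predictor regression model.

A single *key* predictor z (the previous pH) modulates the effect of every
other predictor through a bank of sigmoid basis functions:

    y_hat = intercept + sum_j sum_i w[i, j] * f_j(z) * x_i

where f_j(z) = logistic(slope * (z - c_j)) for M centers c_j, and the x_i are
the K standardized non-key predictors with x_0 = 1 a constant term (so the key
predictor's own effect enters through sum_j w[0, j] * f_j(z)). The weights are
ridge-fitted in closed form; hyperparameters (basis size/sharpness, penalty)
are selected on the inner folds of a nested CV plan by the 95th-percentile
absolute error. The bilinear form makes the prediction exactly decomposable
into per-predictor contributions, which drives the per-sample importance
ranking displayed alongside each estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import KEY_PREDICTOR, PREDICTOR_NAMES

CONST_TERM = "const"

#: Default non-key predictor list: constant term + the Table-style predictors.
DEFAULT_NONKEY = (CONST_TERM, *PREDICTOR_NAMES)

#: Key-predictor (previous pH) span over which basis centers are placed.
CENTER_SPAN = (7.0, 7.6)


@dataclass(frozen=True)
class SigmoidBasis:
    """M logistic bumps over the key predictor, sharing one slope (per pH unit)."""

    centers: tuple
    slope: float

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 1 or len(c) < 1:
            raise ValueError("centers must be a non-empty 1-D sequence")
        if len(c) > 1 and np.any(np.diff(c) <= 0):
            raise ValueError("centers must be strictly increasing")
        if not (self.slope > 0) or not np.isfinite(self.slope):
            raise ValueError("slope must be a positive finite number")
        object.__setattr__(self, "centers", tuple(float(v) for v in c))

    @property
    def m(self) -> int:
        return len(self.centers)

    def evaluate(self, z) -> np.ndarray:
        """(n, M) matrix of f_j(z) = logistic(slope * (z - c_j))."""
        z = np.atleast_1d(np.asarray(z, dtype=float))
        return expit(self.slope * (z[:, None] - np.asarray(self.centers)[None, :]))


def make_centers(key_values, m: int, span: tuple = CENTER_SPAN) -> tuple:
    """Centers at equally spaced quantiles of the key predictor, clipped to span.

    Falls back to an even grid over the span when the data are degenerate.
    """
    lo, hi = span
    if m < 1:
        raise ValueError("m must be >= 1")
    values = np.clip(np.asarray(key_values, dtype=float), lo, hi)
    if m == 1:
        return (float(np.median(values)) if values.size else (lo + hi) / 2.0,)
    if values.size == 0:
        return tuple(np.linspace(lo, hi, m))
    qs = np.linspace(1.0 / (m + 1), m / (m + 1), m)
    c = np.quantile(values, qs)
    # enforce strict monotonicity; degenerate data fall back to an even grid
    for i in range(1, m):
        if c[i] <= c[i - 1]:
            c[i] = c[i - 1] + 1e-6
    if c[-1] > hi + 1e-3:
        return tuple(np.linspace(lo, hi, m))
    return tuple(float(v) for v in c)


@dataclass
class PairwiseModel:
    """A fitted pairwise regression for one target (pH or PaCO2).

    ``weights`` is (K, M) with row 0 the constant term; ``standardization``
    maps each non-constant predictor to its training (center, scale). The
    stored population means anchor the importance ranking's reference point.
    """

    target_name: str
    key_name: str
    nonkey_names: tuple
    basis: SigmoidBasis
    weights: np.ndarray
    intercept: float
    standardization: dict          # name -> (center, scale); excludes the constant
    key_mean: float
    nonkey_means: dict             # name -> raw population mean

    FORMAT_VERSION = 1

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        k, m = len(self.nonkey_names), self.basis.m
        if self.weights.shape != (k, m):
            raise ValueError(f"weights must have shape ({k}, {m}); got {self.weights.shape}")
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ValueError("weights and intercept must be finite")
        for name, (_, scale) in self.standardization.items():
            if not scale > 0:
                raise ValueError(f"standardization scale for {name!r} must be > 0")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": self.FORMAT_VERSION,
            "target_name": self.target_name,
            "key_name": self.key_name,
            "nonkey_names": list(self.nonkey_names),
            "basis": {"centers": list(self.basis.centers), "slope": self.basis.slope},
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "key_mean": self.key_mean,
            "nonkey_means": dict(self.nonkey_means),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PairwiseModel":
        if d.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model format version: {d.get('format_version')}")
        return cls(
            target_name=d["target_name"],
            key_name=d["key_name"],
            nonkey_names=tuple(d["nonkey_names"]),
            basis=SigmoidBasis(tuple(d["basis"]["centers"]), d["basis"]["slope"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            standardization={k: (float(v[0]), float(v[1]))
                             for k, v in d["standardization"].items()},
            key_mean=float(d["key_mean"]),
            nonkey_means={k: float(v) for k, v in d["nonkey_means"].items()},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PairwiseModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ImportanceItem:
    name: str
    importance: float       # target units
    value: float            # observed raw predictor value
    population_mean: float


@dataclass(frozen=True)
class ImportanceRanking:
    """Per-sample predictor importances, sorted by |importance| descending."""

    items: tuple

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def top(self, k: int) -> tuple:
        return self.items[:k]


# ---------------------------------------------------------------------------
# Design construction and ridge fitting
# ---------------------------------------------------------------------------

def _standardized_nonkey(rows: pd.DataFrame, nonkey_names, standardization) -> np.ndarray:
    """(n, K) matrix of standardized non-key predictors; constant column = 1."""
    cols = []
    for name in nonkey_names:
        if name == CONST_TERM:
            cols.append(np.ones(len(rows)))
            continue
        if name not in rows.columns:
            raise ValueError(f"missing predictor column: {name!r}")
        x = rows[name].to_numpy(dtype=float)
        center, scale = standardization[name]
        cols.append((x - center) / scale)
    return np.column_stack(cols)


def expand_design(rows: pd.DataFrame, basis: SigmoidBasis, nonkey_names=DEFAULT_NONKEY,
                  standardization: dict | None = None,
                  key_name: str = KEY_PREDICTOR) -> np.ndarray:
    """(n, K*M) design of f_j(z) * x_i columns, i-major (i outer, j inner).

    ``standardization`` maps non-constant predictor names to (center, scale);
    pass None for raw (unstandardized) predictors.
    """
    if standardization is None:
        standardization = {n: (0.0, 1.0) for n in nonkey_names if n != CONST_TERM}
    if key_name not in rows.columns:
        raise ValueError(f"missing key predictor column: {key_name!r}")
    z = rows[key_name].to_numpy(dtype=float)
    xs = _standardized_nonkey(rows, nonkey_names, standardization)
    if not np.all(np.isfinite(z)) or not np.all(np.isfinite(xs)):
        raise ValueError("non-finite predictor values in design")
    f = basis.evaluate(z)                        # (n, M)
    design = xs[:, :, None] * f[:, None, :]      # (n, K, M)
    return design.reshape(len(rows), -1)


def fit_ridge(design: np.ndarray, targets: np.ndarray, penalty: float,
              penalize: np.ndarray | None = None) -> np.ndarray:
    """Closed-form ridge: argmin ||y - Xw||^2 + penalty * ||w[penalize]||^2.

    ``penalize`` is a boolean mask of penalized columns (default: all).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("design and targets have incompatible shapes")
    if len(X) < 1:
        raise ValueError("need at least one row")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    mask = np.ones(X.shape[1]) if penalize is None else np.asarray(penalize, dtype=float)
    gram = X.T @ X + penalty * np.diag(mask)
    rhs = X.T @ y
    try:
        return np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular normal equations; use a penalty > 0 (ridge) to regularize"
        ) from exc


def train_pairwise_model(rows: pd.DataFrame, target_name: str, basis: SigmoidBasis,
                         penalty: float, nonkey_names=DEFAULT_NONKEY,
                         key_name: str = KEY_PREDICTOR) -> PairwiseModel:
    """Fit a PairwiseModel: standardize on these rows, expand, ridge-solve.

    The global intercept column is unpenalized; all K*M interaction columns
    share the ridge penalty.
    """
    if target_name not in rows.columns:
        raise ValueError(f"missing target column: {target_name!r}")
    standardization = {}
    nonkey_means = {}
    for name in nonkey_names:
        if name == CONST_TERM:
            continue
        x = rows[name].to_numpy(dtype=float)
        center = float(np.mean(x))
        scale = float(np.std(x))
        standardization[name] = (center, scale if scale > 1e-12 else 1.0)
        nonkey_means[name] = center
    X = expand_design(rows, basis, nonkey_names, standardization, key_name)
    D = np.column_stack([np.ones(len(rows)), X])
    penalize = np.ones(D.shape[1], dtype=bool)
    penalize[0] = False
    w = fit_ridge(D, rows[target_name].to_numpy(dtype=float), penalty, penalize)
    return PairwiseModel(
        target_name=target_name,
        key_name=key_name,
        nonkey_names=tuple(nonkey_names),
        basis=basis,
        weights=w[1:].reshape(len(nonkey_names), basis.m),
        intercept=float(w[0]),
        standardization=standardization,
        key_mean=float(np.mean(rows[key_name].to_numpy(dtype=float))),
        nonkey_means=nonkey_means,
    )


# ---------------------------------------------------------------------------
# Prediction, decomposition, importance
# ---------------------------------------------------------------------------

def predict(model: PairwiseModel, rows: pd.DataFrame) -> np.ndarray:
    """Point estimates y_hat per row."""
    X = expand_design(rows, model.basis, model.nonkey_names,
                      model.standardization, model.key_name)
    return model.intercept + X @ model.weights.reshape(-1)


def decompose(model: PairwiseModel, rows: pd.DataFrame) -> pd.DataFrame:
    """Per-predictor contributions g(x_i); columns sum exactly to predict().

    The constant term's column absorbs the intercept plus the key predictor's
    own effect sum_j w[0, j] * f_j(z).
    """
    z = rows[model.key_name].to_numpy(dtype=float)
    xs = _standardized_nonkey(rows, model.nonkey_names, model.standardization)
    f = model.basis.evaluate(z)                       # (n, M)
    slopes = f @ model.weights.T                      # (n, K): sum_j w_ij f_j(z)
    contrib = slopes * xs
    out = pd.DataFrame(contrib, columns=list(model.nonkey_names), index=rows.index)
    out[CONST_TERM] = out[CONST_TERM] + model.intercept
    return out


def rank_importance(model: PairwiseModel, row: pd.Series | pd.DataFrame) -> ImportanceRanking:
    """Importance of each non-key predictor for one sample.

    I_i = g(x_i) - g(x_bar_i): the predictor's contribution at its observed
    value minus at its population mean, holding the key predictor at the
    row's observed value. Sorted by |I_i| descending; ties keep predictor
    order. The constant term is excluded (its value never deviates).
    """
    if isinstance(row, pd.Series):
        row = row.to_frame().T
    if len(row) != 1:
        raise ValueError("rank_importance expects exactly one row")
    z = float(row[model.key_name].iloc[0])
    f = model.basis.evaluate(np.array([z]))[0]        # (M,)
    items = []
    for i, name in enumerate(model.nonkey_names):
        if name == CONST_TERM:
            continue
        if name not in row.columns:
            raise ValueError(f"missing predictor column: {name!r}")
        x = float(row[name].iloc[0])
        xbar = model.nonkey_means[name]
        center, scale = model.standardization[name]
        slope_i = float(f @ model.weights[i])
        imp = slope_i * ((x - center) / scale - (xbar - center) / scale)
        items.append(ImportanceItem(name, imp, x, xbar))
    order = sorted(range(len(items)), key=lambda k: (-abs(items[k].importance), k))
    return ImportanceRanking(tuple(items[k] for k in order))


def visualize_pairwise(model: PairwiseModel, nonkey_name: str,
                       key_grid, nonkey_grid) -> np.ndarray:
    """Contribution surface over (key, non-key) grids.

    Returns a (len(key_grid), len(nonkey_grid)) matrix whose (a, b) entry is
    the contribution of ``nonkey_name`` for a row with key value key_grid[a]
    and raw predictor value nonkey_grid[b].
    """
    if nonkey_name == CONST_TERM or nonkey_name not in model.nonkey_names:
        raise ValueError(f"unknown non-key predictor: {nonkey_name!r}")
    i = model.nonkey_names.index(nonkey_name)
    key_grid = np.asarray(key_grid, dtype=float)
    nonkey_grid = np.asarray(nonkey_grid, dtype=float)
    f = model.basis.evaluate(key_grid)                # (A, M)
    slopes = f @ model.weights[i]                     # (A,)
    center, scale = model.standardization[nonkey_name]
    return np.outer(slopes, (nonkey_grid - center) / scale)


def plot_pairwise(model: PairwiseModel, nonkey_name: str, key_grid, nonkey_grid,
                  ax=None):
    """Colormap rendering of the pairwise contribution surface."""
    import matplotlib.pyplot as plt

    surface = visualize_pairwise(model, nonkey_name, key_grid, nonkey_grid)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(np.asarray(key_grid), np.asarray(nonkey_grid), surface.T,
                         shading="auto", cmap="gray")
    ax.set_xlabel(f"key predictor ({model.key_name})")
    ax.set_ylabel(nonkey_name)
    ax.figure.colorbar(mesh, ax=ax, label=f"contribution to {model.target_name}")
    return ax


# ---------------------------------------------------------------------------
# Hyperparameter selection on the inner CV folds
# ---------------------------------------------------------------------------

DEFAULT_LAMBDA_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
DEFAULT_BASIS_GRID = tuple({"m": m, "slope": s} for m in (3, 5, 7) for s in (5.0, 10.0, 20.0))


@dataclass
class SelectionResult:
    penalty: float
    basis: SigmoidBasis
    scores: pd.DataFrame  # one row per grid point: m, slope, penalty, score


def _inner_cv_folds(rows: pd.DataFrame, split_plan) -> list:
    """(train_idx, val_idx) pairs over every (outer, inner) fold combination."""
    outer_ids, inner_ids = split_plan.row_folds(rows)
    folds = []
    for o in range(split_plan.outer_folds):
        for i in range(split_plan.inner_folds):
            train = (outer_ids != o) & (inner_ids != i)
            val = (outer_ids != o) & (inner_ids == i)
            if train.sum() >= 1 and val.sum() >= 1:
                folds.append((np.flatnonzero(train), np.flatnonzero(val)))
    if not folds:
        raise ValueError("split plan yields no usable inner folds")
    return folds


def _cv_p95(rows, folds, target_name, basis, penalty, nonkey_names, key_name) -> float:
    """Mean inner-CV 95th-percentile absolute error for one configuration."""
    y = rows[target_name].to_numpy(dtype=float)
    errs = []
    for train_idx, val_idx in folds:
        model = train_pairwise_model(rows.iloc[train_idx], target_name, basis,
                                     penalty, nonkey_names, key_name)
        e = np.abs(predict(model, rows.iloc[val_idx]) - y[val_idx])
        errs.append(np.percentile(e, 95))
    return float(np.mean(errs))


def select_hyperparameters(rows: pd.DataFrame, split_plan, lambda_grid=DEFAULT_LAMBDA_GRID,
                           basis_grid=DEFAULT_BASIS_GRID, target_name: str = "ph_t",
                           nonkey_names=DEFAULT_NONKEY, key_name: str = KEY_PREDICTOR
                           ) -> SelectionResult:
    """Pick (penalty, basis) minimizing mean inner-CV p95 absolute error.

    For every (outer o, inner i) pair, trains on rows outside outer fold o and
    inner fold i, scores on the rows of inner fold i (still outside o). Ties
    keep the earliest grid point (basis-major, then penalty order).

    Basis grid entries are dicts {"m": ..., "slope": ...}; an entry may pin
    explicit {"centers": ...} instead of data-quantile placement.
    """
    lambda_grid = tuple(lambda_grid)
    basis_grid = tuple(basis_grid)
    if not lambda_grid or not basis_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    folds = _inner_cv_folds(rows, split_plan)

    records = []
    best = None
    for spec in basis_grid:
        centers = (tuple(spec["centers"]) if "centers" in spec
                   else make_centers(rows[key_name].to_numpy(), int(spec["m"])))
        basis = SigmoidBasis(centers, float(spec["slope"]))
        for lam in lambda_grid:
            score = _cv_p95(rows, folds, target_name, basis, lam,
                            nonkey_names, key_name)
            records.append({"m": basis.m, "slope": basis.slope, "penalty": lam,
                            "score": score})
            if best is None or score < best[0]:
                best = (score, lam, basis)
    return SelectionResult(penalty=best[1], basis=best[2],
                           scores=pd.DataFrame.from_records(records))


def select_predictors(rows: pd.DataFrame, split_plan, basis: SigmoidBasis,
                      penalty: float, candidates=DEFAULT_NONKEY,
                      target_name: str = "ph_t", key_name: str = KEY_PREDICTOR,
                      min_keep: int = 3, rel_tol: float = 0.01) -> tuple:
    """Backward elimination of non-key predictors on the inner CV folds.

    Starting from ``candidates`` (the constant term is always retained),
    repeatedly drops the predictor whose removal yields the best mean inner-CV
    95th-percentile absolute error, as long as the score does not worsen by
    more than ``rel_tol`` relative to the incumbent (a parsimony rule: an
    uninformative predictor only moves the score within fold noise), until no
    drop qualifies or ``min_keep`` non-constant predictors remain. Returns
    (selected names, their CV score). The shipped default predictor list
    makes this optional; it exists for exploring wider candidate pools.
    """
    folds = _inner_cv_folds(rows, split_plan)
    current = list(candidates)
    if CONST_TERM not in current:
        current.insert(0, CONST_TERM)
    best = _cv_p95(rows, folds, target_name, basis, penalty, tuple(current), key_name)
    while len(current) - 1 > min_keep:
        trial_scores = []
        for name in current:
            if name == CONST_TERM:
                continue
            trial = tuple(n for n in current if n != name)
            trial_scores.append(
                (_cv_p95(rows, folds, target_name, basis, penalty, trial, key_name),
                 name))
        score, name = min(trial_scores)
        if score > best * (1.0 + rel_tol):
            break
        best = min(best, score)
        current.remove(name)
    return tuple(current), best
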