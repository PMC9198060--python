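"""Fold-ensemble prediction uncertainty and abstention.

The point estimate comes from a final model trained on all derivation rows;
uncertainty is the (population) variance of predictions across models trained
on the training split of each outer CV fold. Samples whose variance exceeds a
calibrated threshold are abstained on. Two calibration criteria:

* ``rate``: abstain a fixed fraction (default 25%) — the threshold is the
  corresponding upper percentile of calibration-set uncertainties;
* ``error_bound``: the smallest abstention rate whose retained 95th-percentile
  absolute pH error falls at or under a bound (default 0.1 pH), subject to a
  maximum abstention rate (default half of samples).

Threshold comparison is strict (uncertainty > threshold abstains), so a
degenerate ensemble with identical uncertainties abstains nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    DEFAULT_NONKEY, ImportanceRanking, PairwiseModel, SigmoidBasis,
    predict, rank_importance, train_pairwise_model,
)


class CalibrationError(RuntimeError):
    """The requested abstention criterion cannot be satisfied."""


@dataclass
class EnsemblePredictor:
    """Final model + per-fold models + calibrated abstention threshold."""

    final_model: PairwiseModel
    fold_models: list
    threshold: float | None = None  # variance, target units^2
    target_name: str = "ph_t"

    def __post_init__(self):
        if len(self.fold_models) < 2:
            raise ValueError("an ensemble needs at least 2 fold models")

    @property
    def calibrated(self) -> bool:
        return self.threshold is not None

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "target_name": self.target_name,
            "threshold": self.threshold,
            "final_model": self.final_model.to_dict(),
            "fold_models": [m.to_dict() for m in self.fold_models],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsemblePredictor":
        return cls(
            final_model=PairwiseModel.from_dict(d["final_model"]),
            fold_models=[PairwiseModel.from_dict(m) for m in d["fold_models"]],
            threshold=d["threshold"],
            target_name=d["target_name"],
        )


@dataclass(frozen=True)
class Prediction:
    """One estimate-or-abstain decision for a sample."""

    point: float
    uncertainty: float              # fold-prediction variance, target units^2
    interval: tuple                 # point +/- 1.96 * sqrt(uncertainty)
    abstained: bool
    importance: ImportanceRanking | None  # None when abstained


def train_ensemble(rows: pd.DataFrame, split_plan, basis: SigmoidBasis, penalty: float,
                   target_name: str = "ph_t", nonkey_names=DEFAULT_NONKEY) -> EnsemblePredictor:
    """Train the final model on all rows and one model per outer-fold training split."""
    outer_ids, _ = split_plan.row_folds(rows)
    fold_models = []
    for o in range(split_plan.outer_folds):
        train = outer_ids != o
        if train.sum() == 0:
            continue
        fold_models.append(
            train_pairwise_model(rows[train], target_name, basis, penalty, nonkey_names)
        )
    final = train_pairwise_model(rows, target_name, basis, penalty, nonkey_names)
    return EnsemblePredictor(final_model=final, fold_models=fold_models,
                             target_name=target_name)


def train_bootstrap_ensemble(rows: pd.DataFrame, basis: SigmoidBasis, penalty: float,
                             n_boot: int = 20, seed: int = 0, target_name: str = "ph_t",
                             nonkey_names=DEFAULT_NONKEY) -> EnsemblePredictor:
    """Alternative: resample patients with replacement for each ensemble member."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    patients = rows["patient_id"].unique()
    fold_models = []
    for _ in range(n_boot):
        chosen = rng.choice(patients, size=len(patients), replace=True)
        boot = pd.concat([rows[rows["patient_id"] == p] for p in chosen],
                         ignore_index=True)
        fold_models.append(
            train_pairwise_model(boot, target_name, basis, penalty, nonkey_names)
        )
    final = train_pairwise_model(rows, target_name, basis, penalty, nonkey_names)
    return EnsemblePredictor(final_model=final, fold_models=fold_models,
                             target_name=target_name)


def ensemble_uncertainty(ensemble: EnsemblePredictor, rows: pd.DataFrame) -> np.ndarray:
    """Per-row population variance of the fold models' predictions."""
    if len(ensemble.fold_models) < 2:
        raise ValueError("uncertainty needs at least 2 fold models")
    preds = np.stack([predict(m, rows) for m in ensemble.fold_models])
    return preds.var(axis=0, ddof=0)


def calibrate_threshold(ensemble: EnsemblePredictor, calibration_rows: pd.DataFrame,
                        criterion: str = "rate", abstention_rate: float = 0.25,
                        error_bound: float = 0.1, max_abstention: float = 0.5) -> float:
    """Set (and return) the abstention threshold from labeled calibration rows."""
    u = ensemble_uncertainty(ensemble, calibration_rows)
    if criterion == "rate":
        if not (0.0 <= abstention_rate < 1.0):
            raise ValueError("abstention_rate must lie in [0, 1)")
        threshold = float(np.percentile(u, 100.0 * (1.0 - abstention_rate)))
    elif criterion == "error_bound":
        y = calibration_rows[ensemble.target_name].to_numpy(dtype=float)
        err = np.abs(predict(ensemble.final_model, calibration_rows) - y)
        threshold = None
        best = None  # (p95, rate) among feasible rates, for the error message
        for thr in np.sort(np.unique(u))[::-1]:  # increasing abstention
            keep = u <= thr
            rate = 1.0 - keep.mean()
            if rate > max_abstention + 1e-12:
                break
            p95 = float(np.percentile(err[keep], 95))
            if best is None or p95 < best[0]:
                best = (p95, rate)
            if p95 <= error_bound:
                threshold = float(thr)
                break
        if threshold is None:
            raise CalibrationError(
                f"cannot reach retained p95 |error| <= {error_bound} abstaining on "
                f"<= {max_abstention:.0%} of samples; best achievable p95 "
                f"{best[0]:.4f} at abstention rate {best[1]:.1%}"
            )
    else:
        raise ValueError(f"unknown criterion {criterion!r}; use 'rate' or 'error_bound'")
    ensemble.threshold = threshold
    return threshold


def predict_or_abstain(ensemble: EnsemblePredictor, rows: pd.DataFrame,
                       with_importance: bool = True) -> list:
    """Per row: point estimate, uncertainty, abstain flag, ranked importances."""
    if not ensemble.calibrated:
        raise RuntimeError("ensemble threshold is not calibrated; call calibrate_threshold")
    points = predict(ensemble.final_model, rows)
    u = ensemble_uncertainty(ensemble, rows)
    half = 1.96 * np.sqrt(u)
    out = []
    for k in range(len(rows)):
        abstained = bool(u[k] > ensemble.threshold)
        imp = None
        if with_importance and not abstained:
            imp = rank_importance(ensemble.final_model, rows.iloc[k])
        out.append(Prediction(
            point=float(points[k]),
            uncertainty=float(u[k]),
            interval=(float(points[k] - half[k]), float(points[k] + half[k])),
            abstained=abstained,
            importance=imp,
        ))
    return out


def predictions_frame(predictions: list, top_k: int = 3) -> pd.DataFrame:
    """Flatten Prediction objects for CSV export (top-k predictors appended)."""
    records = []
    for p in predictions:
        rec = {
            "point": p.point,
            "uncertainty": p.uncertainty,
            "interval_lo": p.interval[0],
            "interval_hi": p.interval[1],
            "abstained": p.abstained,
        }
        items = p.importance.top(top_k) if p.importance is not None else ()
        for r in range(top_k):
            if r < len(items):
                rec[f"top{r + 1}_predictor"] = items[r].name
                rec[f"top{r + 1}_value"] = items[r].value
                rec[f"top{r + 1}_importance"] = items[r].importance
            else:
                rec[f"top{r + 1}_predictor"] = ""
                rec[f"top{r + 1}_value"] = np.nan
                rec[f"top{r + 1}_importance"] = np.nan
        records.append(rec)
    return pd.DataFrame.from_records(records)


def risk_coverage_curve(ensemble: EnsemblePredictor, rows: pd.DataFrame,
                        abstention_rates=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
                        n_random: int = 20, seed: int = 0) -> pd.DataFrame:
    """Retained p95 |error| vs abstention rate: uncertainty-ordered vs random.

    The random reference abstains the same number of samples uniformly at
    random, averaged over ``n_random`` orderings. Rates that retain no samples
    are omitted from the output.
    """
    abstention_rates = tuple(abstention_rates)
    if not abstention_rates:
        raise ValueError("abstention_rates grid must be non-empty")
    y = rows[ensemble.target_name].to_numpy(dtype=float)
    err = np.abs(predict(ensemble.final_model, rows) - y)
    u = ensemble_uncertainty(ensemble, rows)
    order = np.argsort(u, kind="stable")  # ascending: retained first
    n = len(rows)
    rng = np.random.default_rng(seed)
    random_orders = [rng.permutation(n) for _ in range(n_random)]
    records = []
    for rate in abstention_rates:
        k = int(np.floor(rate * n))
        if k >= n:
            continue
        retained = order[: n - k]
        p95_u = float(np.percentile(err[retained], 95))
        p95_r = float(np.mean([
            np.percentile(err[perm[: n - k]], 95) for perm in random_orders
        ]))
        records.append({"rate": rate, "p95_uncertainty": p95_u,
                        "p95_random": p95_r, "n_retained": n - k})
    return pd.DataFrame.from_records(records)
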