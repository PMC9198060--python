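"""Feature engineering: observation timelines -> predictor/target rows.

Each feature row pairs a blood-gas observation at time t (the target) with the
most recent prior observation within a lag window (the predictors): previous
pH / PaCO2 / HCO3-, end-tidal CO2 at both times, and deltas of the ventilator
settings and SpO2 (current minus previous). Also here: the plausibility filter
on raw measurements, pH-balancing resampling of derivation rows, and
patient-grouped pH-stratified nested cross-validation splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Target columns of a feature-row table.
TARGET_NAMES = ["ph_t", "paco2_t"]

#: The key predictor modulating all others through the sigmoid basis.
KEY_PREDICTOR = "ph_prev"

#: Non-key model predictors (a constant term is appended by the model itself).
PREDICTOR_NAMES = [
    "paco2_prev", "hco3_prev", "etco2_t", "etco2_prev",
    "d_fio2", "d_peep", "d_pip", "d_mnawp", "d_spo2", "d_tvin", "d_tvexp",
]

#: Auxiliary columns carried for baselines/evaluation (not model predictors).
AUX_COLUMNS = ["fio2_t", "mnawp_t", "spo2_t", "bg_type_prev", "bg_type_t"]

FEATURE_COLUMNS = (
    ["patient_id", "t_current", "t_previous", "lag_hours"]
    + TARGET_NAMES + [KEY_PREDICTOR] + PREDICTOR_NAMES + AUX_COLUMNS
)

#: Default plausibility ranges (inclusive bounds) per measured variable.
DEFAULT_PLAUSIBILITY: dict[str, tuple[float, float]] = {
    "ph": (6.5, 7.8),
    "paco2": (10.0, 150.0),
    "petco2": (0.0, 150.0),
    "hco3": (5.0, 60.0),
    "spo2": (0.0, 100.0),
    "fio2": (21.0, 100.0),
    "peep": (0.0, 25.0),
    "pip": (0.0, 60.0),
    "mnawp": (0.0, 45.0),
    "tv_in": (0.0, 25.0),
    "tv_exp": (0.0, 25.0),
}

# Cohort columns consumed when building feature rows.
_NEEDED = ["patient_id", "time", "ph", "paco2", "hco3", "petco2",
           "spo2", "fio2", "peep", "pip", "mnawp", "tv_in", "tv_exp", "bg_type"]


def _check_sorted(cohort: pd.DataFrame) -> None:
    d = cohort.groupby("patient_id", sort=False)["time"].diff()
    if (d.dropna() <= 0).any():
        bad = cohort.loc[d.index[d <= 0], "patient_id"].unique()[:5]
        raise ValueError(
            f"timestamps must strictly increase within each patient; offending patients: {list(bad)}"
        )


def build_feature_rows(cohort: pd.DataFrame, max_lag_hours: float | None = 24.0,
                       linkage: str = "previous") -> pd.DataFrame:
    """Build one feature row per observation that has a usable prior blood gas.

    linkage="previous" pairs each observation with the most recent prior one;
    linkage="first" pairs every later observation with the patient's first
    (used by the first-vs-previous-BG analysis). Rows whose lag exceeds
    ``max_lag_hours`` (when not None), whose PetCO2 is missing at either time,
    or that are a patient's first observation produce no row.
    """
    missing = [c for c in _NEEDED if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing required columns: {missing}")
    if linkage not in ("previous", "first"):
        raise ValueError(f"unknown linkage {linkage!r}; use 'previous' or 'first'")
    if len(cohort) == 0:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    _check_sorted(cohort)

    cur = cohort.reset_index(drop=True)
    g = cur.groupby("patient_id", sort=False)
    if linkage == "previous":
        prev = g[_NEEDED].shift(1)
    else:
        prev = g[_NEEDED].transform("first")
    lag = cur["time"] - prev["time"]

    mask = prev["time"].notna() & (lag > 0)
    if max_lag_hours is not None:
        mask &= lag <= max_lag_hours
    mask &= cur["petco2"].notna() & prev["petco2"].notna()
    numeric = [c for c in _NEEDED if c not in ("patient_id", "bg_type")]
    mask &= cur[numeric].notna().all(axis=1) & prev[numeric].notna().all(axis=1)

    cur, prev, lag = cur[mask], prev[mask], lag[mask]
    out = pd.DataFrame({
        "patient_id": cur["patient_id"].to_numpy(),
        "t_current": cur["time"].to_numpy(),
        "t_previous": prev["time"].to_numpy(),
        "lag_hours": lag.to_numpy(),
        "ph_t": cur["ph"].to_numpy(),
        "paco2_t": cur["paco2"].to_numpy(),
        "ph_prev": prev["ph"].to_numpy(),
        "paco2_prev": prev["paco2"].to_numpy(),
        "hco3_prev": prev["hco3"].to_numpy(),
        "etco2_t": cur["petco2"].to_numpy(),
        "etco2_prev": prev["petco2"].to_numpy(),
        "d_fio2": (cur["fio2"] - prev["fio2"]).to_numpy(),
        "d_peep": (cur["peep"] - prev["peep"]).to_numpy(),
        "d_pip": (cur["pip"] - prev["pip"]).to_numpy(),
        "d_mnawp": (cur["mnawp"] - prev["mnawp"]).to_numpy(),
        "d_spo2": (cur["spo2"] - prev["spo2"]).to_numpy(),
        "d_tvin": (cur["tv_in"] - prev["tv_in"]).to_numpy(),
        "d_tvexp": (cur["tv_exp"] - prev["tv_exp"]).to_numpy(),
        "fio2_t": cur["fio2"].to_numpy(),
        "mnawp_t": cur["mnawp"].to_numpy(),
        "spo2_t": cur["spo2"].to_numpy(),
        "bg_type_prev": prev["bg_type"].to_numpy(),
        "bg_type_t": cur["bg_type"].to_numpy(),
    })
    return out.reset_index(drop=True)


def plausibility_filter(cohort: pd.DataFrame, ranges: dict | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop observations with any out-of-range value; log every violation.

    Returns (filtered cohort, rejection log). The log has one row per
    violation: row_index, patient_id, variable, value, lower, upper.
    """
    if ranges is None:
        ranges = DEFAULT_PLAUSIBILITY
    unknown = [v for v in ranges if v not in cohort.columns]
    if unknown:
        raise ValueError(f"plausibility ranges name unknown variables: {unknown}")

    log_records = []
    bad = np.zeros(len(cohort), dtype=bool)
    for var, (lo, hi) in ranges.items():
        values = cohort[var].to_numpy(dtype=float)
        viol = (values < lo) | (values > hi) | ~np.isfinite(values)
        for idx in np.flatnonzero(viol):
            log_records.append((
                int(cohort.index[idx]), cohort["patient_id"].iloc[idx],
                var, float(values[idx]), float(lo), float(hi),
            ))
        bad |= viol
    log = pd.DataFrame(
        log_records,
        columns=["row_index", "patient_id", "variable", "value", "lower", "upper"],
    )
    return cohort.loc[~bad].copy(), log


def _largest_remainder(weights: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to n, proportional to weights (largest remainder)."""
    raw = weights * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def resample_by_ph(rows: pd.DataFrame, bin_edges=(7.30, 7.45),
                   target_weights=(0.17, 0.54, 0.29), seed: int = 0,
                   ph_column: str = "ph_t") -> pd.DataFrame:
    """Rebalance the pH distribution of derivation rows toward target bin weights.

    Over-represented bins are subsampled without replacement; under-represented
    bins keep every row and duplicate rows sampled with replacement (so every
    original row of such a bin survives). The output carries a ``source_index``
    column (positional index into ``rows``) for multiplicity bookkeeping. The
    output size equals the input size. Never apply this to validation data.
    """
    n = len(rows)
    if n == 0:
        out = rows.copy()
        out["source_index"] = np.array([], dtype=int)
        return out
    weights = np.asarray(target_weights, dtype=float)
    if len(weights) != len(bin_edges) + 1:
        raise ValueError("need len(bin_edges) + 1 target weights")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("target weights must be non-negative and sum > 0")
    weights = weights / weights.sum()

    ph = rows[ph_column].to_numpy(dtype=float)
    bins = np.digitize(ph, bin_edges)  # 0 .. len(bin_edges)
    counts = np.bincount(bins, minlength=len(weights))
    empty = (counts == 0) & (weights > 0)
    if empty.any():
        warnings.warn(
            f"empty pH bins with positive target weight: {np.flatnonzero(empty).tolist()}; "
            "weight redistributed to populated bins",
            stacklevel=2,
        )
        weights = np.where(empty, 0.0, weights)
        weights = weights / weights.sum()
    target_counts = _largest_remainder(weights, n)

    rng = np.random.default_rng(seed)
    taken: list[np.ndarray] = []
    for b in range(len(weights)):
        idx = np.flatnonzero(bins == b)
        tc = target_counts[b]
        if tc == 0 or len(idx) == 0:
            continue
        if tc == len(idx):
            taken.append(idx)
        elif tc < len(idx):
            taken.append(rng.choice(idx, size=tc, replace=False))
        else:
            extra = rng.choice(idx, size=tc - len(idx), replace=True)
            taken.append(np.concatenate([idx, extra]))
    source = np.concatenate(taken) if taken else np.array([], dtype=int)
    out = rows.iloc[source].copy()
    out["source_index"] = source
    return out.reset_index(drop=True)


@dataclass
class SplitPlan:
    """Patient-grouped, pH-stratified nested CV assignment.

    ``assignment`` has one row per patient: patient_id, outer_fold,
    inner_fold. Inner folds partition each outer fold's patients; the inner CV
    for outer fold o uses patients with outer_fold != o grouped by inner_fold.
    """

    outer_folds: int
    inner_folds: int
    assignment: pd.DataFrame
    stratify_variable: str = "ph_t"

    def row_folds(self, rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(outer, inner) fold ids per feature row, via the patient mapping."""
        m = rows[["patient_id"]].merge(self.assignment, on="patient_id", how="left")
        if m["outer_fold"].isna().any():
            missing = rows.loc[m["outer_fold"].isna().to_numpy(), "patient_id"].unique()
            raise ValueError(f"rows contain patients absent from the split plan: {list(missing)[:5]}")
        return m["outer_fold"].to_numpy(dtype=int), m["inner_fold"].to_numpy(dtype=int)

    def save(self, path) -> None:
        self.assignment.to_csv(path, index=False)


def _deal_stratified(patient_ph: pd.DataFrame, n_folds: int, rng: np.random.Generator
                     ) -> dict:
    """Assign patients (sorted by mean pH) to folds by permuted chunks of size n_folds."""
    ordered = patient_ph.sort_values(["mean_ph", "patient_id"], kind="mergesort")
    ids = ordered["patient_id"].to_numpy()
    fold_of: dict = {}
    for start in range(0, len(ids), n_folds):
        chunk = ids[start:start + n_folds]
        folds = rng.permutation(n_folds)[: len(chunk)]
        for pid, f in zip(chunk, folds):
            fold_of[pid] = int(f)
    return fold_of


def make_split_plan(rows: pd.DataFrame, outer: int = 5, inner: int = 5,
                    seed: int = 0) -> SplitPlan:
    """Build a nested CV plan: no patient leakage, pH-stratified fold composition."""
    if outer < 2 or inner < 2:
        raise ValueError("outer and inner fold counts must be >= 2")
    patient_ph = (
        rows.groupby("patient_id")["ph_t"].mean().rename("mean_ph").reset_index()
    )
    if len(patient_ph) < outer:
        raise ValueError(
            f"need at least {outer} patients for {outer} outer folds; got {len(patient_ph)}"
        )
    rng = np.random.default_rng(seed)
    outer_of = _deal_stratified(patient_ph, outer, rng)
    patient_ph["outer_fold"] = patient_ph["patient_id"].map(outer_of)
    inner_col = {}
    for o in range(outer):
        sub = patient_ph[patient_ph["outer_fold"] == o]
        inner_of = _deal_stratified(sub, inner, rng)
        inner_col.update(inner_of)
    patient_ph["inner_fold"] = patient_ph["patient_id"].map(inner_col)
    assignment = patient_ph[["patient_id", "outer_fold", "inner_fold"]].reset_index(drop=True)
    return SplitPlan(outer_folds=outer, inner_folds=inner, assignment=assignment)


def ph_range_fractions(ph: np.ndarray, edges=(7.30, 7.45)) -> np.ndarray:
    """Fractions of values below, between, and at/above the pH range edges."""
    ph = np.asarray(ph, dtype=float)
    lo, hi = edges
    return np.array([
        np.mean(ph < lo),
        np.mean((ph >= lo) & (ph < hi)),
        np.mean(ph >= hi),
    ])
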