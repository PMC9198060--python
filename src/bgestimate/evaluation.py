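"""Agreement statistics and performance evaluation.

Error percentiles (95th-percentile absolute error — "the worst 5% of
samples"), CLIA blood-gas-analyzer agreement fractions (|error| <= 0.04 pH or
5 mmHg), per-range breakdowns, time-lag degradation, pH safe-range coverage of
uncertainty intervals, Bland-Altman limits of agreement, and Mann-Whitney
model comparison.

Range conventions: pH bins (-inf, 7.30), [7.30, 7.45), [7.45, inf); PaCO2 bins
labeled 20-35 / 35-60 / 60-120 mmHg with unbounded outer edges so that the
per-range counts partition the estimated set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PH_RANGE_EDGES = (7.30, 7.45)
PH_RANGE_LABELS = ("<7.3", "7.3-7.45", ">=7.45")
PCO2_RANGE_EDGES = (35.0, 60.0)
PCO2_RANGE_LABELS = ("20-35", "35-60", "60-120")
CLIA_PH = 0.04      # pH units
CLIA_PCO2 = 5.0     # mmHg
DEFAULT_LAG_EDGES = (0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0)
LOW_N = 20          # per-bin sample count below which a p95 is flagged


def p95_abs_error(errors) -> float:
    """95th percentile of |error| (linear-interpolation quantile)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("p95_abs_error requires at least one error")
    return float(np.percentile(np.abs(errors), 95))


def clia_agreement(errors, bound: float) -> float:
    """Fraction of samples with |error| <= bound."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("clia_agreement requires at least one error")
    if not bound > 0:
        raise ValueError("bound must be > 0")
    return float(np.mean(np.abs(errors) <= bound))


def _range_bins(values: np.ndarray, edges) -> np.ndarray:
    return np.digitize(np.asarray(values, dtype=float), edges)


def per_range_p95(errors, truths, edges, labels) -> dict:
    """p95 |error| per true-value range; empty ranges are omitted."""
    errors = np.asarray(errors, dtype=float)
    bins = _range_bins(truths, edges)
    out = {}
    for b, label in enumerate(labels):
        sel = bins == b
        if sel.any():
            out[label] = p95_abs_error(errors[sel])
    return out


def range_coverage(points, half_widths, truths, edges=PH_RANGE_EDGES) -> dict:
    """Fraction of predictions whose interval intersects the truth's pH range.

    The interval is [point - hw, point + hw] (closed); a range bin [lo, hi) is
    covered when interval_hi >= lo and interval_lo < hi (outer bins unbounded).
    Zero half-width reduces to point-in-bin classification.
    """
    points = np.asarray(points, dtype=float)
    hw = np.asarray(half_widths, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if points.size == 0:
        raise ValueError("range_coverage requires at least one prediction")
    bounds = [(-np.inf, edges[0]), (edges[0], edges[1]), (edges[1], np.inf)]
    bins = _range_bins(truths, edges)
    lo = np.array([bounds[b][0] for b in bins])
    hi = np.array([bounds[b][1] for b in bins])
    covered = (points + hw >= lo) & (points - hw < hi)
    out = {"overall": float(covered.mean())}
    for b, label in enumerate(PH_RANGE_LABELS):
        sel = bins == b
        if sel.any():
            out[label] = float(covered[sel].mean())
    return out


def lag_analysis(lag_hours, errors, bin_edges=DEFAULT_LAG_EDGES) -> pd.DataFrame:
    """Per lag-bin p95 |error|. Empty bins are absent; small bins flagged low_n."""
    lag_hours = np.asarray(lag_hours, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if lag_hours.shape != errors.shape:
        raise ValueError("lag_hours and errors must align")
    records = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sel = (lag_hours >= lo) & (lag_hours < hi)
        if not sel.any():
            continue
        records.append({
            "bin": f"{lo:g}-{hi:g}", "lo": lo, "hi": hi,
            "n": int(sel.sum()),
            "p95": p95_abs_error(errors[sel]),
            "low_n": bool(sel.sum() < LOW_N),
        })
    return pd.DataFrame.from_records(
        records, columns=["bin", "lo", "hi", "n", "p95", "low_n"]
    )


def bland_altman(estimates, truths) -> tuple:
    """(mean difference, lower limit, upper limit) with limits at +/- 1.96 SD."""
    estimates = np.asarray(estimates, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if estimates.size < 2:
        raise ValueError("bland_altman requires at least 2 pairs")
    d = estimates - truths
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def compare_models(errors_a, errors_b) -> float:
    """Two-sided Mann-Whitney U p-value on absolute errors.

    Exact null distribution for small tie-free samples (both n <= 50),
    normal approximation with tie correction otherwise.
    """
    a = np.abs(np.asarray(errors_a, dtype=float))
    b = np.abs(np.asarray(errors_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("compare_models requires two non-empty error sets")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 50 and b.size <= 50 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def first_vs_previous_bg_analysis(model, cohort: pd.DataFrame,
                                  max_lag_hours: float | None = 24.0) -> dict:
    """p95 |error| with most-recent-prior-BG linkage vs first-BG linkage.

    Re-links the cohort both ways, applies the same fitted model, and reports
    both p95 values. The first-BG linkage carries no lag cap (every later
    sample reuses the admission BG).
    """
    from .features import build_feature_rows
    from .model_core import predict

    multi = cohort.groupby("patient_id").size() >= 2
    if not multi.any():
        raise ValueError("cohort has no patients with 2+ blood gases")
    prev_rows = build_feature_rows(cohort, max_lag_hours=max_lag_hours, linkage="previous")
    first_rows = build_feature_rows(cohort, max_lag_hours=None, linkage="first")
    out = {}
    for name, rows in (("previous", prev_rows), ("first", first_rows)):
        err = np.abs(predict(model, rows) - rows[model.target_name].to_numpy())
        out[f"p95_{name}"] = p95_abs_error(err)
        out[f"n_{name}"] = int(len(rows))
    return out


@dataclass
class EvaluationReport:
    """All headline statistics for one model's predictions on one dataset."""

    n_total: int
    n_estimated: int
    abstention_rate: float
    p95_ph: float
    p95_ph_by_range: dict
    p95_pco2: float
    p95_pco2_by_range: dict
    clia_fraction_ph: float
    clia_fraction_pco2: float
    range_coverage_fraction: dict
    bland_altman_ph: tuple
    bland_altman_pco2: tuple
    lag_p95: list  # lag_analysis records

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["bland_altman_ph"] = list(self.bland_altman_ph)
        d["bland_altman_pco2"] = list(self.bland_altman_pco2)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            d = json.load(fh)
        d["bland_altman_ph"] = tuple(d["bland_altman_ph"])
        d["bland_altman_pco2"] = tuple(d["bland_altman_pco2"])
        return cls(**d)

    def to_text(self) -> str:
        lines = [
            f"samples: {self.n_estimated}/{self.n_total} estimated "
            f"(abstention {self.abstention_rate:.1%})",
            f"pH   p95 |err|: {self.p95_ph:.4f}  by range: "
            + ", ".join(f"{k}: {v:.4f}" for k, v in self.p95_ph_by_range.items()),
            f"PCO2 p95 |err|: {self.p95_pco2:.2f}  by range: "
            + ", ".join(f"{k}: {v:.2f}" for k, v in self.p95_pco2_by_range.items()),
            f"CLIA agreement: pH {self.clia_fraction_ph:.1%} (±{CLIA_PH}), "
            f"PCO2 {self.clia_fraction_pco2:.1%} (±{CLIA_PCO2:g} mmHg)",
            "pH range coverage: "
            + ", ".join(f"{k}: {v:.1%}" for k, v in self.range_coverage_fraction.items()),
            f"Bland-Altman pH: mean {self.bland_altman_ph[0]:+.4f}, "
            f"limits [{self.bland_altman_ph[1]:+.4f}, {self.bland_altman_ph[2]:+.4f}]",
            f"Bland-Altman PCO2: mean {self.bland_altman_pco2[0]:+.2f}, "
            f"limits [{self.bland_altman_pco2[1]:+.2f}, {self.bland_altman_pco2[2]:+.2f}]",
        ]
        for rec in self.lag_p95:
            flag = " (low n)" if rec["low_n"] else ""
            lines.append(f"lag {rec['bin']} h: p95 {rec['p95']:.4f} (n={rec['n']}){flag}")
        return "\n".join(lines)


def build_report(ph_true, ph_pred, pco2_true, pco2_pred, abstained, lag_hours,
                 ph_half_width) -> EvaluationReport:
    """Assemble the full report; error statistics use non-abstained samples only."""
    ph_true = np.asarray(ph_true, dtype=float)
    ph_pred = np.asarray(ph_pred, dtype=float)
    pco2_true = np.asarray(pco2_true, dtype=float)
    pco2_pred = np.asarray(pco2_pred, dtype=float)
    abstained = np.asarray(abstained, dtype=bool)
    lag_hours = np.asarray(lag_hours, dtype=float)
    ph_half_width = np.asarray(ph_half_width, dtype=float)
    keep = ~abstained
    if not keep.any():
        raise ValueError("all samples abstained; nothing to evaluate")
    ph_err = ph_pred[keep] - ph_true[keep]
    pco2_err = pco2_pred[keep] - pco2_true[keep]
    return EvaluationReport(
        n_total=int(len(ph_true)),
        n_estimated=int(keep.sum()),
        abstention_rate=float(abstained.mean()),
        p95_ph=p95_abs_error(ph_err),
        p95_ph_by_range=per_range_p95(ph_err, ph_true[keep], PH_RANGE_EDGES, PH_RANGE_LABELS),
        p95_pco2=p95_abs_error(pco2_err),
        p95_pco2_by_range=per_range_p95(pco2_err, pco2_true[keep],
                                        PCO2_RANGE_EDGES, PCO2_RANGE_LABELS),
        clia_fraction_ph=clia_agreement(ph_err, CLIA_PH),
        clia_fraction_pco2=clia_agreement(pco2_err, CLIA_PCO2),
        range_coverage_fraction=range_coverage(ph_pred[keep], ph_half_width[keep],
                                               ph_true[keep]),
        bland_altman_ph=bland_altman(ph_pred[keep], ph_true[keep]),
        bland_altman_pco2=bland_altman(pco2_pred[keep], pco2_true[keep]),
        lag_p95=lag_analysis(lag_hours[keep], ph_err).to_dict("records"),
    )
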