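"""End-to-end pipeline: configuration, orchestration, tabular I/O, figures.

``run_pipeline`` executes the full study loop on synthetic cohorts: simulate
derivation and validation data, plausibility-filter, build feature rows,
pH-resample the derivation rows only, split patients into nested CV folds,
select hyperparameters on the inner folds, train fold + final models for both
targets, calibrate the abstention threshold on pH, predict-or-abstain on the
validation set (the pH abstention decision is shared with the paired PaCO2
prediction), and evaluate. One master seed fans out to per-stage child seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines, evaluation, features, model_core, synthetic_cohort, uncertainty
from .features import DEFAULT_PLAUSIBILITY, SplitPlan
from .model_core import DEFAULT_BASIS_GRID, DEFAULT_LAMBDA_GRID, SigmoidBasis, make_centers
from .synthetic_cohort import COHORT_COLUMNS, GeneratorConfig

log = logging.getLogger("bgestimate")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class FeaturesConfig:
    max_lag_hours: float = 24.0
    plausibility: dict | None = None          # None -> DEFAULT_PLAUSIBILITY
    resample: bool = True
    resample_bin_edges: tuple = (7.30, 7.45)
    resample_target_weights: tuple = (0.17, 0.54, 0.29)
    outer_folds: int = 5
    inner_folds: int = 5


@dataclass
class ModelConfig:
    select: bool = True
    basis_grid: tuple = DEFAULT_BASIS_GRID
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    default_m: int = 5
    default_slope: float = 10.0
    default_lambda: float = 1.0


@dataclass
class UncertaintyConfig:
    criterion: str = "rate"                   # 'rate' or 'error_bound'
    abstention_rate: float = 0.25
    error_bound: float = 0.1
    max_abstention: float = 0.5
    n_random_orderings: int = 20
    risk_rates: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class EvaluationConfig:
    lag_bin_edges: tuple = evaluation.DEFAULT_LAG_EDGES
    clia_ph: float = evaluation.CLIA_PH
    clia_pco2: float = evaluation.CLIA_PCO2


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_validation_patients: int = 200
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    uncertainty: UncertaintyConfig = field(default_factory=UncertaintyConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0
    output_dir: str = "bg_run"
    make_figures: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {
            "generator": GeneratorConfig,
            "features": FeaturesConfig,
            "model": ModelConfig,
            "uncertainty": UncertaintyConfig,
            "evaluation": EvaluationConfig,
        }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in d.items():
            if key in sections:
                section_cls = sections[key]
                section_known = {f.name for f in dataclasses.fields(section_cls)}
                bad = set(value) - section_known
                if bad:
                    raise ValueError(f"unknown keys in config section {key!r}: {sorted(bad)}")
                value = {k: (tuple(v) if isinstance(v, list) and k != "basis_grid"
                             else v) for k, v in value.items()}
                if key == "model" and "basis_grid" in value:
                    value["basis_grid"] = tuple(dict(b) for b in value["basis_grid"])
                kwargs[key] = section_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           default_flow_style=False, sort_keys=True)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def load_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the documented schema exhaustively."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {missing}")
    extra = [c for c in df.columns
             if c not in COHORT_COLUMNS + synthetic_cohort.LATENT_COLUMNS]
    if extra:
        warnings.warn(f"cohort file {path} has unknown columns (preserved): {extra}",
                      stacklevel=2)
    return df


def save_cohort(cohort: pd.DataFrame, path, config: GeneratorConfig | None = None) -> None:
    """Write a cohort CSV; when a config is given, a sidecar JSON records it (incl. seed)."""
    cohort.to_csv(path, index=False)
    if config is not None:
        meta = Path(str(path) + ".meta.json")
        with open(meta, "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=1, sort_keys=True)


def save_predictions(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def load_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["point", "uncertainty", "interval_lo", "interval_hi", "abstained"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"predictions file {path} missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s ...", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _child_seeds(seed: int, n: int) -> list:
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(config: PipelineConfig, output_dir=None) -> dict:
    """Execute the full pipeline; returns artifact paths plus the report."""
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 6)
    artifacts: dict = {"output_dir": str(outdir)}

    config.to_yaml(outdir / "config_resolved.yaml")
    artifacts["config"] = str(outdir / "config_resolved.yaml")

    # --- simulate -----------------------------------------------------------
    @_stage("simulate")
    def simulate():
        gen = replace(config.generator, seed=seeds[0])
        der = synthetic_cohort.simulate_cohort(gen)
        val_gen = replace(config.generator, seed=seeds[1],
                          n_patients=config.n_validation_patients)
        val = synthetic_cohort.simulate_cohort(val_gen)
        save_cohort(der, outdir / "derivation_cohort.csv", gen)
        save_cohort(val, outdir / "validation_cohort.csv", val_gen)
        return der, val

    derivation, validation = simulate()
    artifacts["derivation_cohort"] = str(outdir / "derivation_cohort.csv")
    artifacts["validation_cohort"] = str(outdir / "validation_cohort.csv")

    # --- filter + features --------------------------------------------------
    @_stage("features")
    def build():
        ranges = config.features.plausibility or DEFAULT_PLAUSIBILITY
        der, der_log = features.plausibility_filter(derivation, ranges)
        val, val_log = features.plausibility_filter(validation, ranges)
        der_rows = features.build_feature_rows(der, config.features.max_lag_hours)
        val_rows = features.build_feature_rows(val, config.features.max_lag_hours)
        logs = [frame.assign(cohort=name)
                for name, frame in (("derivation", der_log), ("validation", val_log))
                if len(frame)]
        combined = (pd.concat(logs, ignore_index=True) if logs
                    else der_log.assign(cohort=pd.Series(dtype=str)))
        combined.to_csv(outdir / "plausibility_rejections.csv", index=False)
        return der_rows, val_rows

    der_rows, val_rows = build()
    if len(der_rows) == 0 or len(val_rows) == 0:
        raise PipelineError("stage 'features' failed: no usable feature rows")

    # --- resample (derivation only; validation keeps its natural distribution)
    @_stage("resample")
    def resample():
        if not config.features.resample:
            return der_rows.copy()
        return features.resample_by_ph(
            der_rows, config.features.resample_bin_edges,
            config.features.resample_target_weights, seed=seeds[2])

    train_rows = resample()
    train_rows.to_csv(outdir / "derivation_rows.csv", index=False)
    val_rows.to_csv(outdir / "validation_rows.csv", index=False)
    artifacts["derivation_rows"] = str(outdir / "derivation_rows.csv")
    artifacts["validation_rows"] = str(outdir / "validation_rows.csv")

    # --- split --------------------------------------------------------------
    @_stage("split")
    def split():
        plan = features.make_split_plan(train_rows, config.features.outer_folds,
                                        config.features.inner_folds, seed=seeds[3])
        plan.save(outdir / "split_plan.csv")
        return plan

    plan = split()
    artifacts["split_plan"] = str(outdir / "split_plan.csv")

    # --- hyperparameters ----------------------------------------------------
    @_stage("select_hyperparameters")
    def select():
        if config.model.select:
            sel = model_core.select_hyperparameters(
                train_rows, plan, config.model.lambda_grid, config.model.basis_grid)
            sel.scores.to_csv(outdir / "hyperparameter_scores.csv", index=False)
            return sel.penalty, sel.basis
        basis = SigmoidBasis(
            make_centers(train_rows["ph_prev"].to_numpy(), config.model.default_m),
            config.model.default_slope)
        return config.model.default_lambda, basis

    penalty, basis = select()
    log.info("selected penalty=%g, basis m=%d slope=%g", penalty, basis.m, basis.slope)

    # --- train --------------------------------------------------------------
    @_stage("train")
    def train():
        ens_ph = uncertainty.train_ensemble(train_rows, plan, basis, penalty, "ph_t")
        ens_pco2 = uncertainty.train_ensemble(train_rows, plan, basis, penalty, "paco2_t")
        return ens_ph, ens_pco2

    ens_ph, ens_pco2 = train()

    # --- calibrate (on the unresampled derivation rows: natural distribution)
    @_stage("calibrate")
    def calibrate():
        threshold = uncertainty.calibrate_threshold(
            ens_ph, der_rows, criterion=config.uncertainty.criterion,
            abstention_rate=config.uncertainty.abstention_rate,
            error_bound=config.uncertainty.error_bound,
            max_abstention=config.uncertainty.max_abstention)
        log.info("calibrated pH uncertainty threshold: %.3e", threshold)
        return threshold

    threshold = calibrate()
    for name, ens in (("ph", ens_ph), ("pco2", ens_pco2)):
        with open(outdir / f"ensemble_{name}.json", "w") as fh:
            json.dump(ens.to_dict(), fh, indent=1, sort_keys=True)
        artifacts[f"ensemble_{name}"] = str(outdir / f"ensemble_{name}.json")

    # --- predict-or-abstain on validation ------------------------------------
    @_stage("predict")
    def predict_stage():
        preds_ph = uncertainty.predict_or_abstain(ens_ph, val_rows)
        frame = uncertainty.predictions_frame(preds_ph)
        # the paired PaCO2 estimate shares the pH abstention decision
        frame["pco2_point"] = model_core.predict(ens_pco2.final_model, val_rows)
        frame.insert(0, "patient_id", val_rows["patient_id"].to_numpy())
        frame.insert(1, "t_current", val_rows["t_current"].to_numpy())
        save_predictions(frame, outdir / "predictions.csv")
        return frame

    preds = predict_stage()
    artifacts["predictions"] = str(outdir / "predictions.csv")

    # --- evaluate -----------------------------------------------------------
    @_stage("evaluate")
    def evaluate_stage():
        abstained = preds["abstained"].to_numpy(dtype=bool)
        report = evaluation.build_report(
            ph_true=val_rows["ph_t"], ph_pred=preds["point"],
            pco2_true=val_rows["paco2_t"], pco2_pred=preds["pco2_point"],
            abstained=abstained, lag_hours=val_rows["lag_hours"],
            ph_half_width=preds["point"] - preds["interval_lo"])
        # baselines on the same (non-abstained) validation rows
        keep = ~abstained
        avdsf_est = baselines.avdsf_baseline_frame(val_rows[keep])
        ok = avdsf_est["estimated"].to_numpy()
        baudin_ph = baselines.predict_baudin(
            baselines.fit_baudin(train_rows, "ph_t"), val_rows[keep])
        ph_true = val_rows.loc[keep, "ph_t"].to_numpy()
        model_err = preds.loc[keep, "point"].to_numpy() - ph_true
        comparison = {
            "p95_model": evaluation.p95_abs_error(model_err),
            "p95_avdsf": evaluation.p95_abs_error(
                avdsf_est["ph_est"].to_numpy()[ok] - ph_true[ok]),
            "p95_baudin": evaluation.p95_abs_error(baudin_ph - ph_true),
            "p_vs_avdsf": evaluation.compare_models(
                model_err[ok], avdsf_est["ph_est"].to_numpy()[ok] - ph_true[ok]),
            "p_vs_baudin": evaluation.compare_models(model_err, baudin_ph - ph_true),
        }
        curve = uncertainty.risk_coverage_curve(
            ens_ph, val_rows, config.uncertainty.risk_rates,
            config.uncertainty.n_random_orderings, seed=seeds[4])
        fvp = evaluation.first_vs_previous_bg_analysis(
            ens_ph.final_model, validation, config.features.max_lag_hours)
        return report, comparison, curve, fvp

    report, comparison, curve, fvp = evaluate_stage()
    full = {
        "report": report.to_dict(),
        "baseline_comparison": comparison,
        "first_vs_previous": fvp,
        "threshold": threshold,
        "penalty": penalty,
        "basis": {"centers": list(basis.centers), "slope": basis.slope},
        "seed": config.seed,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(full, fh, indent=1, sort_keys=True)
    (outdir / "report.txt").write_text(report.to_text() + "\n")
    curve.to_csv(outdir / "risk_coverage.csv", index=False)
    artifacts["report"] = str(outdir / "report.json")
    artifacts["risk_coverage"] = str(outdir / "risk_coverage.csv")

    if config.make_figures:
        @_stage("figures")
        def figures():
            _make_figures(outdir, val_rows, preds, curve, report, ens_ph)
        figures()
        artifacts["figures"] = str(outdir)

    artifacts["report_obj"] = report
    artifacts["full_report"] = full
    return artifacts


def _make_figures(outdir: Path, val_rows, preds, curve, report, ens_ph) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keep = ~preds["abstained"].to_numpy(dtype=bool)
    truth = val_rows.loc[keep, "ph_t"].to_numpy()
    est = preds.loc[keep, "point"].to_numpy()

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].scatter(truth, est, s=6, alpha=0.4)
    lims = [min(truth.min(), est.min()), max(truth.max(), est.max())]
    axes[0].plot(lims, lims, "k--", lw=1)
    for edge in (7.30, 7.45):
        axes[0].axvline(edge, color="gray", ls=":", lw=0.8)
        axes[0].axhline(edge, color="gray", ls=":", lw=0.8)
    axes[0].set_xlabel("laboratory pH")
    axes[0].set_ylabel("estimated pH")
    diff = est - truth
    mean, lo, hi = report.bland_altman_ph
    axes[1].scatter((est + truth) / 2, diff, s=6, alpha=0.4)
    axes[1].axhline(mean, color="k")
    axes[1].axhline(lo, color="k", ls="--")
    axes[1].axhline(hi, color="k", ls="--")
    axes[1].set_xlabel("mean of estimate and laboratory pH")
    axes[1].set_ylabel("estimate - laboratory")
    fig.tight_layout()
    fig.savefig(outdir / "fig_scatter_bland_altman.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].plot(curve["rate"], curve["p95_uncertainty"], "o-",
                 label="uncertainty-ordered")
    axes[0].plot(curve["rate"], curve["p95_random"], "s--", label="random")
    axes[0].set_xlabel("abstention rate")
    axes[0].set_ylabel("retained p95 |pH error|")
    axes[0].legend()
    lag = pd.DataFrame(report.lag_p95)
    if len(lag):
        axes[1].plot((lag["lo"] + lag["hi"]) / 2, lag["p95"], "o-")
        axes[1].set_xlabel("time since previous BG (h)")
        axes[1].set_ylabel("p95 |pH error|")
    fig.tight_layout()
    fig.savefig(outdir / "fig_risk_coverage_lag.png", dpi=120)
    plt.close(fig)
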