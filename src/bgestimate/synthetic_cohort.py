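"""Synthetic ventilated-patient cohort simulator.

Generates per-patient timelines of blood-gas samples (pH, PaCO2, HCO3-) with
contemporaneous noninvasive measurements (PetCO2, SpO2, FiO2, ventilator
pressures, tidal volumes), carrying the statistical structure the estimation
model relies on:

* PaCO2 deviations follow a mean-reverting (Ornstein-Uhlenbeck-like) process
  around a patient baseline, so serial correlation decays with elapsed time;
* bicarbonate drifts as a slow random walk (the metabolic component);
* pH is computed from (PaCO2, HCO3-) via Henderson-Hasselbalch, so the triple
  is exactly consistent;
* PetCO2 = PaCO2 * (1 - AVDSf_patient) + noise, with a patient-specific
  alveolar dead-space fraction;
* ventilator pressure interventions causally shift subsequent PaCO2;
* inter-sample gaps are lognormal around a configurable median (~4-5 h), and
  the cohort pH distribution is concentrated in 7.30-7.45 with acidotic and
  alkalotic tails.

The continuous-time convention: ``paco2_ar_coeff`` is the autocorrelation of
the PaCO2 deviation over one *median* inter-sample interval, and
``metabolic_drift_sd`` / ``paco2_noise_sd`` are the innovation SDs over that
same nominal step; both scale with the actual elapsed gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import hco3_from_ph_paco2, henderson_hasselbalch_ph

#: Canonical column order of a cohort table (one row per blood-gas observation).
COHORT_COLUMNS = [
    "patient_id", "time", "ph", "paco2", "hco3", "bg_type",
    "petco2", "spo2", "fio2", "peep", "pip", "mnawp", "tv_in", "tv_exp",
]

#: Latent per-patient truth kept alongside the observables (not a predictor).
LATENT_COLUMNS = ["avdsf_true"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate a mixed pediatric ICU population: median inter-BG gap
    ~4.7 h, dead-space fraction 0.11 +/- 0.07, PaCO2 around 45 mmHg, and
    roughly 11% / 71% / 18% of samples in the pH ranges <7.30 / 7.30-7.45 /
    >=7.45.
    """

    n_patients: int = 500
    mean_obs_per_patient: float = 8.0
    inter_bg_hours_median: float = 4.7
    inter_bg_log_sd: float = 0.55          # SD of log inter-BG gap
    avdsf_mean: float = 0.11
    avdsf_sd: float = 0.07
    paco2_ar_coeff: float = 0.75           # PaCO2 autocorrelation at the median gap
    paco2_noise_sd: float = 3.0            # mmHg innovation SD at the median gap
    metabolic_drift_sd: float = 0.6        # mmol/L HCO3 random-walk SD at the median gap
    petco2_noise_sd: float = 2.0           # mmHg measurement noise on PetCO2
    intervention_prob: float = 0.25        # per-step probability of a ventilator change
    intervention_effect_mmhg_per_cmh2o: float = -1.5  # signed: + pressure -> - PaCO2
    ph_tail_fraction: float = 0.12         # patients seeded acidotic or alkalotic
    acidotic_share: float = 0.35           # fraction of tail patients that are acidotic
    capillary_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        fractions = {
            "avdsf_mean": self.avdsf_mean,
            "intervention_prob": self.intervention_prob,
            "ph_tail_fraction": self.ph_tail_fraction,
            "acidotic_share": self.acidotic_share,
            "capillary_fraction": self.capillary_fraction,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {value}")
        sds = {
            "avdsf_sd": self.avdsf_sd,
            "paco2_noise_sd": self.paco2_noise_sd,
            "metabolic_drift_sd": self.metabolic_drift_sd,
            "petco2_noise_sd": self.petco2_noise_sd,
            "inter_bg_log_sd": self.inter_bg_log_sd,
        }
        for name, value in sds.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0; got {value}")
        if not (0.0 <= self.paco2_ar_coeff < 1.0):
            raise ValueError(f"paco2_ar_coeff must lie in [0, 1); got {self.paco2_ar_coeff}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.mean_obs_per_patient < 1:
            raise ValueError("mean_obs_per_patient must be >= 1")
        if self.inter_bg_hours_median <= 0:
            raise ValueError("inter_bg_hours_median must be > 0")
        numeric = [
            self.mean_obs_per_patient, self.inter_bg_hours_median, self.inter_bg_log_sd,
            self.avdsf_mean, self.avdsf_sd, self.paco2_ar_coeff, self.paco2_noise_sd,
            self.metabolic_drift_sd, self.petco2_noise_sd, self.intervention_prob,
            self.intervention_effect_mmhg_per_cmh2o, self.ph_tail_fraction,
            self.acidotic_share, self.capillary_fraction,
        ]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("all GeneratorConfig parameters must be finite")


# Patient-group pH / PaCO2 baselines (mean, sd, clip-lo, clip-hi). The normal
# band is narrower than the observed sample spread because within-patient
# PaCO2/HCO3 dynamics add ~0.05 pH of observation-level variability on top.
_GROUP_PH = {
    "acidotic": (7.25, 0.04, 7.05, 7.31),
    "alkalotic": (7.50, 0.03, 7.455, 7.62),
    "normal": (7.38, 0.025, 7.315, 7.44),
}
_GROUP_PACO2 = {
    "acidotic": (55.0, 8.0, 25.0, 90.0),
    "alkalotic": (38.0, 4.0, 22.0, 60.0),
    "normal": (45.0, 5.0, 25.0, 75.0),
}


def simulate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a cohort table (COHORT_COLUMNS + avdsf_true), seed-deterministic."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    median = config.inter_bg_hours_median
    ar = config.paco2_ar_coeff
    # Stationary SD of the PaCO2 deviation process implied by the per-median-gap
    # innovation SD: innov_sd^2 = stat_sd^2 * (1 - ar^2).
    stat_sd = config.paco2_noise_sd / math.sqrt(1.0 - ar**2) if ar > 0 else config.paco2_noise_sd

    records: list[tuple] = []
    for pid in range(config.n_patients):
        u = rng.uniform()
        if u < config.ph_tail_fraction * config.acidotic_share:
            group = "acidotic"
        elif u < config.ph_tail_fraction:
            group = "alkalotic"
        else:
            group = "normal"
        m, s, lo, hi = _GROUP_PH[group]
        ph_base = float(np.clip(rng.normal(m, s), lo, hi))
        m, s, lo, hi = _GROUP_PACO2[group]
        paco2_base = float(np.clip(rng.normal(m, s), lo, hi))
        hco3 = hco3_from_ph_paco2(ph_base, paco2_base)
        avdsf_p = float(np.clip(rng.normal(config.avdsf_mean, config.avdsf_sd), 0.0, 0.6))
        severity = rng.uniform(1.0, 20.0)  # drives the SpO2/FiO2 coupling

        n_obs = 1 + rng.poisson(config.mean_obs_per_patient - 1.0)
        t = rng.uniform(0.0, 12.0)
        paco2_dev = rng.normal(0.0, stat_sd)
        peep = float(np.clip(rng.normal(7.0, 2.0), 3.0, 15.0))
        pip = peep + float(np.clip(rng.normal(16.0, 3.0), 8.0, 35.0))
        fio2 = float(np.clip(rng.normal(45.0, 12.0), 21.0, 100.0))
        tv_exp = float(np.clip(rng.normal(7.3, 1.5), 3.0, 12.0))

        for k in range(n_obs):
            if k > 0:
                gap = median * math.exp(config.inter_bg_log_sd * rng.standard_normal())
                gap = float(np.clip(gap, 0.25, 36.0))
                t += gap
                rel = gap / median
                rho = ar**rel if ar > 0 else 0.0
                innov_sd = stat_sd * math.sqrt(max(1.0 - rho**2, 0.0))
                d_pip = 0.0
                if rng.uniform() < config.intervention_prob:
                    pip_new = float(np.clip(pip + rng.choice([-5, -4, -3, -2, 2, 3, 4, 5]), 10.0, 55.0))
                    d_pip = pip_new - pip
                    pip = pip_new
                    if rng.uniform() < 0.5:
                        peep = float(np.clip(peep + rng.choice([-2, -1, 1, 2]), 3.0, 18.0))
                if rng.uniform() < 0.3:
                    fio2 = float(np.clip(fio2 + rng.choice([-20, -15, -10, -5, 5, 10, 15, 20]), 21.0, 100.0))
                paco2_dev = (
                    rho * paco2_dev
                    + rng.normal(0.0, innov_sd)
                    + config.intervention_effect_mmhg_per_cmh2o * d_pip
                )
                hco3 = hco3 + rng.normal(0.0, config.metabolic_drift_sd * math.sqrt(rel))
                tv_exp = float(np.clip(tv_exp + rng.normal(0.0, 0.3), 3.0, 12.0))

            hco3 = float(np.clip(hco3, 8.0, 50.0))
            paco2 = float(np.clip(paco2_base + paco2_dev, 15.0, 130.0))
            ph = henderson_hasselbalch_ph(paco2, hco3)
            petco2 = paco2 * (1.0 - avdsf_p) + rng.normal(0.0, config.petco2_noise_sd)
            petco2 = max(petco2, 1.0)
            mnawp = float(np.clip((pip + 2.0 * peep) / 3.0 + rng.normal(0.0, 0.5), 4.0, 45.0))
            spo2 = float(np.clip(100.0 - severity * math.exp(-(fio2 - 21.0) / 30.0)
                                 + rng.normal(0.0, 1.0), 60.0, 100.0))
            tv_in = tv_exp + abs(rng.normal(0.4, 0.15))
            bg_type = "capillary" if rng.uniform() < config.capillary_fraction else "arterial"
            records.append((pid, t, ph, paco2, hco3, bg_type, petco2, spo2,
                            fio2, peep, pip, mnawp, tv_in, tv_exp, avdsf_p))

    return pd.DataFrame(records, columns=COHORT_COLUMNS + LATENT_COLUMNS)


def cohort_realism_report(cohort: pd.DataFrame) -> dict:
    """Median/IQR summaries and pH-range fractions of a generated cohort.

    Returns a flat dict (JSON-friendly): for each of pH, PaCO2, PetCO2,
    recomputed AVDSf and inter-BG hours the median and quartiles, plus the
    fractions of samples with pH <7.30, in [7.30, 7.45), and >=7.45.
    """
    if len(cohort) == 0:
        raise ValueError("cohort_realism_report requires a non-empty cohort")
    out: dict[str, float] = {
        "n_patients": int(cohort["patient_id"].nunique()),
        "n_obs": int(len(cohort)),
    }

    def _quartiles(name: str, values: np.ndarray) -> None:
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        out[f"{name}_median"] = float(med)
        out[f"{name}_q1"] = float(q1)
        out[f"{name}_q3"] = float(q3)

    _quartiles("ph", cohort["ph"].to_numpy())
    _quartiles("paco2", cohort["paco2"].to_numpy())
    _quartiles("petco2", cohort["petco2"].to_numpy())
    _quartiles("avdsf", ((cohort["paco2"] - cohort["petco2"]) / cohort["paco2"]).to_numpy())
    gaps = cohort.sort_values(["patient_id", "time"]).groupby("patient_id")["time"].diff().dropna()
    if len(gaps):
        _quartiles("inter_bg_hours", gaps.to_numpy())
    ph = cohort["ph"].to_numpy()
    out["frac_ph_acidotic"] = float(np.mean(ph < 7.30))
    out["frac_ph_normal"] = float(np.mean((ph >= 7.30) & (ph < 7.45)))
    out["frac_ph_alkalotic"] = float(np.mean(ph >= 7.45))
    out["frac_capillary"] = float(np.mean(cohort["bg_type"].to_numpy() == "capillary"))
    return out


# ---------------------------------------------------------------------------
# Benchmark cohorts used by the test-bench properties
# ---------------------------------------------------------------------------

def heteroscedastic_cohort(n_patients: int, seed: int, noisy_share: float = 0.5,
                           noise_factor: float = 3.0) -> pd.DataFrame:
    """A mixture cohort with per-patient heteroscedastic noise.

    A ``noisy_share`` fraction of patients have their PaCO2 innovation,
    metabolic drift and PetCO2 noise SDs inflated by ``noise_factor``. Used to
    exercise the risk-coverage property: prediction errors (and, through more
    extreme feature values, ensemble disagreement) are larger for noisy
    patients, so uncertainty-ordered abstention should beat random abstention.
    """
    n_noisy = int(round(n_patients * noisy_share))
    quiet = replace(GeneratorConfig(), n_patients=n_patients - n_noisy, seed=seed)
    base = GeneratorConfig()
    noisy = replace(
        base,
        n_patients=n_noisy,
        seed=seed + 10_000,
        paco2_noise_sd=base.paco2_noise_sd * noise_factor,
        metabolic_drift_sd=base.metabolic_drift_sd * noise_factor,
        petco2_noise_sd=base.petco2_noise_sd * noise_factor,
    )
    a = simulate_cohort(quiet)
    b = simulate_cohort(noisy)
    b = b.assign(patient_id=b["patient_id"] + quiet.n_patients)
    return pd.concat([a, b], ignore_index=True)


def drifting_cohort(n_patients: int, seed: int) -> pd.DataFrame:
    """A cohort with strong time-dependent drift and wide inter-BG gaps.

    Faster PaCO2 decorrelation, a stronger metabolic random walk and a wider
    lognormal gap distribution populate every lag bin up to 24 h; used by the
    lag-degradation and first-vs-previous-BG properties.
    """
    cfg = replace(
        GeneratorConfig(),
        n_patients=n_patients,
        seed=seed,
        paco2_ar_coeff=0.5,
        paco2_noise_sd=4.0,
        metabolic_drift_sd=2.0,
        inter_bg_log_sd=1.0,
        inter_bg_hours_median=5.0,
    )
    return simulate_cohort(cfg)
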