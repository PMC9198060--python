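"""Physiologic baseline estimators for blood-gas prediction.

Two comparison models:

* the alveolar dead-space fraction (AVDSf) carry-forward model, which infers
  the current PaCO2 from the current end-tidal CO2 and the dead-space fraction
  of the previous blood gas, then converts to pH with the Henderson-Hasselbalch
  equation using the previous bicarbonate;
* a capnography-era linear regression (Baudin-style) predicting the targets
  from current PetCO2, FiO2 and mean airway pressure only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# Henderson-Hasselbalch constants: carbonic acid pKa and CO2 solubility in
# plasma (mmol/L per mmHg). Standard physiologic values.
PK_CARBONIC = 6.1
CO2_SOLUBILITY = 0.03


@dataclass(frozen=True)
class AcidBaseState:
    """A (pH, PaCO2, HCO3-) triple; consistent iff it satisfies Henderson-Hasselbalch."""

    ph: float
    paco2: float  # mmHg
    hco3: float   # mmol/L

    def is_consistent(self, tol: float = 1e-6) -> bool:
        return abs(self.ph - henderson_hasselbalch_ph(self.paco2, self.hco3)) <= tol


def henderson_hasselbalch_ph(paco2, hco3):
    """pH from PaCO2 (mmHg) and bicarbonate (mmol/L).

    pH = pK + log10( HCO3- / (s * PaCO2) ) with pK = 6.1, s = 0.03.
    Accepts scalars or arrays; inputs must be strictly positive.
    """
    paco2 = np.asarray(paco2, dtype=float)
    hco3 = np.asarray(hco3, dtype=float)
    if np.any(paco2 <= 0) or np.any(hco3 <= 0):
        raise ValueError("henderson_hasselbalch_ph requires paco2 > 0 and hco3 > 0")
    out = PK_CARBONIC + np.log10(hco3 / (CO2_SOLUBILITY * paco2))
    return out if out.ndim else float(out)


def hco3_from_ph_paco2(ph, paco2):
    """Invert Henderson-Hasselbalch: bicarbonate (mmol/L) from pH and PaCO2."""
    paco2 = np.asarray(paco2, dtype=float)
    if np.any(paco2 <= 0):
        raise ValueError("paco2 must be positive")
    out = CO2_SOLUBILITY * paco2 * np.power(10.0, np.asarray(ph, dtype=float) - PK_CARBONIC)
    return out if out.ndim else float(out)


def avdsf(paco2, petco2):
    """Alveolar dead-space fraction (PaCO2 - PetCO2) / PaCO2.

    May be negative when measurement noise puts PetCO2 above PaCO2; negative
    values are returned unclipped (a warning is emitted) because clipping
    would bias the downstream carry-forward inversion.
    """
    paco2 = np.asarray(paco2, dtype=float)
    petco2 = np.asarray(petco2, dtype=float)
    if np.any(paco2 <= 0):
        raise ValueError("avdsf requires paco2 > 0")
    out = (paco2 - petco2) / paco2
    if np.any(np.asarray(out) < 0):
        warnings.warn("negative AVDSf (PetCO2 > PaCO2); kept unclipped", stacklevel=2)
    return out if out.ndim else float(out)


def avdsf_baseline_predict(prev: AcidBaseState, prev_petco2: float, current_petco2: float):
    """Carry-forward estimate of (PaCO2, pH) at the current time.

    The dead-space fraction of the *previous* blood gas is assumed unchanged:
    paco2_est = PetCO2[t] / (1 - AVDSf_prev), and pH follows from the previous
    bicarbonate via Henderson-Hasselbalch.

    Returns (paco2_est, ph_est); both NaN when AVDSf_prev >= 1 (inversion
    undefined — the row is flagged not estimated).
    """
    frac = avdsf(prev.paco2, prev_petco2)
    if frac >= 1.0:
        return float("nan"), float("nan")
    paco2_est = current_petco2 / (1.0 - frac)
    if paco2_est <= 0:
        return float("nan"), float("nan")
    ph_est = henderson_hasselbalch_ph(paco2_est, prev.hco3)
    return float(paco2_est), float(ph_est)


def avdsf_baseline_frame(rows: pd.DataFrame) -> pd.DataFrame:
    """Vectorized AVDSf carry-forward baseline over a feature-row table.

    Expects columns paco2_prev, etco2_prev, hco3_prev, etco2_t. Returns a frame
    with paco2_est, ph_est and an ``estimated`` flag (False where the previous
    dead-space fraction makes the inversion undefined).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frac = avdsf(rows["paco2_prev"].to_numpy(), rows["etco2_prev"].to_numpy())
    frac = np.atleast_1d(frac)
    ok = frac < 1.0
    paco2_est = np.full(len(rows), np.nan)
    paco2_est[ok] = rows["etco2_t"].to_numpy()[ok] / (1.0 - frac[ok])
    ok &= paco2_est > 0
    ph_est = np.full(len(rows), np.nan)
    ph_est[ok] = henderson_hasselbalch_ph(paco2_est[ok], rows["hco3_prev"].to_numpy()[ok])
    return pd.DataFrame(
        {"paco2_est": paco2_est, "ph_est": ph_est, "estimated": ok},
        index=rows.index,
    )


@dataclass
class BaudinModel:
    """Linear regression on current PetCO2, FiO2 and mean airway pressure."""

    target_name: str
    intercept: float
    coefficients: dict  # predictor name -> coefficient

    PREDICTORS = ("etco2_t", "fio2_t", "mnawp_t")


def fit_baudin(rows: pd.DataFrame, target_name: str = "ph_t") -> BaudinModel:
    """Ordinary least squares of the target on (PetCO2[t], FiO2[t], MnAwP[t])."""
    missing = [c for c in BaudinModel.PREDICTORS if c not in rows.columns]
    if missing:
        raise ValueError(f"rows missing Baudin predictors: {missing}")
    X = np.column_stack(
        [np.ones(len(rows))] + [rows[c].to_numpy(dtype=float) for c in BaudinModel.PREDICTORS]
    )
    y = rows[target_name].to_numpy(dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design for Baudin regression")
    return BaudinModel(
        target_name=target_name,
        intercept=float(coef[0]),
        coefficients=dict(zip(BaudinModel.PREDICTORS, map(float, coef[1:]))),
    )


def predict_baudin(model: BaudinModel, rows: pd.DataFrame) -> np.ndarray:
    out = np.full(len(rows), model.intercept)
    for name, c in model.coefficients.items():
        out = out + c * rows[name].to_numpy(dtype=float)
    return out
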