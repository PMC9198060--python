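import numpy as np
import pandas as pd
import pytest

import bgestimate as bg

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "suite", deadline=None, derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("suite")
except ImportError:  # hypothesis is an optional test dependency
    pass


@pytest.fixture(scope="session")
def derivation_cohort():
    return bg.simulate_cohort(bg.GeneratorConfig(n_patients=150, seed=11))


@pytest.fixture(scope="session")
def derivation_rows(derivation_cohort):
    return bg.build_feature_rows(derivation_cohort)


@pytest.fixture(scope="session")
def validation_rows():
    cohort = bg.simulate_cohort(bg.GeneratorConfig(n_patients=100, seed=12))
    return bg.build_feature_rows(cohort)


@pytest.fixture(scope="session")
def split_plan(derivation_rows):
    return bg.make_split_plan(derivation_rows, seed=3)


@pytest.fixture(scope="session")
def default_basis(derivation_rows):
    return bg.SigmoidBasis(bg.make_centers(derivation_rows["ph_prev"].to_numpy(), 5), 10.0)


@pytest.fixture(scope="session")
def ph_model(derivation_rows, default_basis):
    return bg.train_pairwise_model(derivation_rows, "ph_t", default_basis, 1.0)


@pytest.fixture(scope="session")
def ph_ensemble(derivation_rows, split_plan, default_basis):
    return bg.train_ensemble(derivation_rows, split_plan, default_basis, 1.0, "ph_t")


def constant_model(value: float, target_name: str = "ph_t") -> bg.PairwiseModel:
    """A degenerate fitted model predicting a constant (zero weights)."""
    return bg.PairwiseModel(
        target_name=target_name,
        key_name="ph_prev",
        nonkey_names=("const",),
        basis=bg.SigmoidBasis((7.35,), 10.0),
        weights=np.zeros((1, 1)),
        intercept=value,
        standardization={},
        key_mean=7.35,
        nonkey_means={},
    )


@pytest.fixture
def tiny_cohort():
    """Two patients, hand-written observations for linkage/delta checks."""
    base = dict(ph=7.38, paco2=45.0, hco3=24.0, bg_type="arterial", petco2=40.0,
                fio2=40.0, peep=7.0, pip=22.0, mnawp=12.0, tv_in=7.5, tv_exp=7.0)
    rows = [
        dict(patient_id="a", time=0.0, spo2=90.0, **base),
        dict(patient_id="a", time=4.0, spo2=95.0, **base),
        dict(patient_id="b", time=1.0, spo2=97.0, **base),
    ]
    return pd.DataFrame(rows)
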