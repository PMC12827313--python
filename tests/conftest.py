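import numpy as np
import pandas as pd
import pytest

from aamsm import coxph, msdata, simulate

_YEAR = 365.25

#: Constant-hazard configuration used for oracle-consistency checks: every
#: arrow of the default structure is active, but intensities are low enough
#: that each occupation curve stays away from p = 0.5, keeping the
#: Monte-Carlo scale of the sup-norm comparison well below the tolerance.
ORACLE_RATES_PER_YEAR = {
    1: 0.016, 2: 0.006, 3: 0.010, 4: 0.004, 5: 0.002,
    6: 0.004, 7: 0.002, 8: 0.002, 9: 0.002, 10: 0.001, 11: 0.001,
    12: 0.008, 13: 0.003, 14: 0.003,
    15: 0.30, 16: 0.05, 17: 0.10, 18: 0.02,
}


def oracle_config(n_patients: int) -> simulate.SimulatorConfig:
    base = {q: ((0.0,), (r / _YEAR,)) for q, r in ORACLE_RATES_PER_YEAR.items()}
    return simulate.SimulatorConfig(
        n_patients=n_patients, n_eltrombopag=0,
        baselines=base, betas={},
        accrual_window_days=0.0, admin_cutoff_day=5 * _YEAR,
        gates={},
    )


@pytest.fixture(scope="session")
def structure():
    return msdata.default_structure()


@pytest.fixture(scope="session")
def two_state_structure():
    return msdata.TransitionStructure(
        states={1: "Alive", 2: "Dead"},
        transitions={1: (1, 2)},
        absorbing=frozenset({2}),
    )


def two_state_data(times, status) -> pd.DataFrame:
    times = np.asarray(times, float)
    status = np.asarray(status, int)
    return pd.DataFrame({
        "patient_id": np.arange(len(times)), "visit": 1,
        "from_state": 1, "to_state": 2, "trans": 1,
        "Tstart": 0.0, "Tstop": times, "status": status,
    })


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient synthetic registry with event logs (registry defaults)."""
    cfg = simulate.SimulatorConfig(n_patients=400, n_eltrombopag=0)
    return simulate.simulate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def small_long(small_cohort, structure):
    dummies = coxph.encode_covariates(small_cohort.covariates)
    return msdata.expand_long_format(small_cohort.paths, structure, dummies)
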