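import numpy as np
import pandas as pd
import pytest

from gaitenv.classify import run_experiment
from gaitenv.features import extract_feature_table
from gaitenv.selection import run_selection
from gaitenv.synth import CohortDesign, SynthConfig, generate_cohort


@pytest.fixture()
def noiseless_cfg():
    """Perfectly periodic, perfectly mounted configuration."""
    return SynthConfig(
        noise_sd=0.0, timing_jitter_sd=0.0, amp_jitter_sd=0.0,
        lr_asymmetry=0.0, tilt_deg=(0.0, 0.0), heading_deg=0.0,
    )


@pytest.fixture(scope="session")
def cohort_tables():
    """Feature tables of a full-size effect_scale=1 cohort (shared; read-only)."""
    ds = generate_cohort(CohortDesign(seed=101))
    roles = dict(zip(ds.manifest["participant"], ds.manifest["role"]))
    table = extract_feature_table(ds.runs, roles=roles)
    train = table[table["role"] == "training"].reset_index(drop=True)
    test = table[table["role"] == "testing"].reset_index(drop=True)
    return ds, train, test


@pytest.fixture(scope="session")
def cohort_selection(cohort_tables):
    """Iterated selection result on the shared cohort's training table."""
    _, train, _ = cohort_tables
    return run_selection(train, n_iterations=100, seed=202)


@pytest.fixture(scope="session")
def cohort_experiment(cohort_tables, cohort_selection):
    """A 20-iteration classification experiment on the shared cohort."""
    _, train, test = cohort_tables
    return run_experiment(train, test, cohort_selection.retained,
                          n_iterations=20, seed=303)


def make_noise_table(n_participants=40, n_features=25, informative=None,
                     shift=3.0, seed=0):
    """Feature table of one row per participant: standard-normal noise
    features, optionally one informative column shifted by ``shift`` pooled
    SDs between conditions."""
    rng = np.random.default_rng(seed)
    conds = np.array(["treadmill", "sidewalk"])[
        np.arange(n_participants) % 2]
    X = rng.normal(size=(n_participants, n_features))
    names = [f"f{i:02d}" for i in range(n_features)]
    table = pd.DataFrame(X, columns=names)
    if informative is not None:
        table[informative] += np.where(conds == "treadmill", shift, 0.0)
    table["participant"] = [f"p{i:02d}" for i in range(n_participants)]
    table["condition"] = conds
    return table, names
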