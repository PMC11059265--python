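import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from imusway import signal_prep as sp
from imusway import sway_features as sf
from imusway import synth_cohort as sc


@pytest.fixture(scope="session")
def default_params():
    return sc.default_params()


@pytest.fixture(scope="session")
def cn_trial(default_params):
    """One default CN eyes-open trial, 30 s at 64 Hz."""
    return sc.simulate_sway_trial(default_params, 30.0, 64.0, seed=42)


@pytest.fixture(scope="session")
def cn_signals(cn_trial):
    return sp.to_sway_signals(cn_trial)


@pytest.fixture(scope="session")
def cn_features(cn_signals):
    return sf.extract_features(cn_signals)


@pytest.fixture(scope="session")
def toy_signals():
    """64-sample random sway signals for brute-force oracle comparisons."""
    rng = np.random.default_rng(7)
    acc = rng.normal(0, 0.05, size=(3, 64))
    acc = acc - acc.mean(axis=1, keepdims=True)
    gyr = rng.normal(0, 0.5, size=(3, 64))
    ml, v, ap = acc
    return sp.SwaySignals(
        ml=ml, v=v, ap=ap, gml=gyr[0], gv=gyr[1], gap=gyr[2],
        svm=np.sqrt(ml**2 + v**2 + ap**2), fs=64.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """6+6 subjects, 2 trials, EO only, 12 s -- fast end-to-end material."""
    spec = sc.CohortSpec(
        n_cn=6, n_mci=6, trials_per_subject=2, sessions=("EO",),
        trial_duration_s=12.0, effect_scale=1.0, seed=11,
    )
    return sc.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    """Wide feature table + labels + subjects for the small cohort."""
    subjects, recordings = small_cohort
    fvs = [sf.extract_features(sp.to_sway_signals(r)) for r in recordings]
    wide = sf.features_to_frame(fvs)
    merged = wide.merge(subjects[["subject_id", "group"]], on="subject_id")
    X = merged[sf.feature_names()]
    return X, merged["group"].to_numpy(), merged["subject_id"].to_numpy(), subjects
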