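import warnings

import numpy as np
import pandas as pd
import pytest

from ergml.erg_io import ERGRecording
from ergml.fusion_selection import FeatureTable
from ergml.synthetic_data import (
    CohortConfig,
    GroupEffect,
    WaveformParams,
    simulate_cohort,
    simulate_erg_waveform,
)

# sklearn 1.9 deprecation chatter from SVC(probability=True); not actionable here
warnings.filterwarnings("ignore", message="The `probability` parameter")
warnings.filterwarnings("ignore", message="Stochastic Optimizer")


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 18-subject cohort with all four groups and both slots."""
    config = CohortConfig(
        n_per_group={"control": 6, "ASD": 5, "ADHD": 4, "ASD_ADHD": 3},
        seed=7,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def clean_recording():
    """Noiseless synthetic recording with known trough/peak geometry."""
    params = WaveformParams(
        a_amp=20.0, a_time=15.0, b_amp=40.0, b_time=30.0,
        op_amps=(0.0, 0.0), noise_sd=0.0, band_texture_rms=(0.0,) * 8,
    )
    samples = simulate_erg_waveform(params, GroupEffect.identity(), np.random.default_rng(0))
    return ERGRecording("sub-x", "R", 446.0, 2000.0, samples)


def gaussian_table(n_per_class=30, p=6, shift=2.0, informative=1, seed=0, classes=("control", "ASD")):
    """Two-class Gaussian feature table: first `informative` columns shifted."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for ci, cls in enumerate(classes):
        X = rng.standard_normal((n_per_class, p))
        if ci > 0:
            X[:, :informative] += shift
        blocks.append(X)
        labels += [cls] * n_per_class
    X = np.vstack(blocks)
    idx = [f"s{i:03d}" for i in range(len(labels))]
    features = pd.DataFrame(X, index=idx, columns=[f"f{j}" for j in range(p)])
    lab = pd.Series(labels, index=idx, name="group")
    meta = pd.DataFrame({"group": lab, "sex": "M", "site": 1, "medicated": False})
    return FeatureTable(features, lab, meta)


@pytest.fixture
def make_gaussian_table():
    return gaussian_table
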