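from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from ergml.erg_io import ERGRecording
from ergml.synthetic_data import (
    CohortConfig,
    GroupEffect,
    WaveformParams,
    simulate_cohort,
    simulate_erg_waveform,
)
from ergml.time_domain import extract_td_features

NOISELESS = WaveformParams(
    a_amp=20.0, a_time=15.0, b_amp=40.0, b_time=30.0,
    op_amps=(0.0, 0.0), noise_sd=0.0, band_texture_rms=(0.0,) * 8,
)


def test_waveform_determinism():
    p = WaveformParams()
    x1 = simulate_erg_waveform(p, rng=np.random.default_rng(9))
    x2 = simulate_erg_waveform(p, rng=np.random.default_rng(9))
    assert np.array_equal(x1, x2)


def test_waveform_shape_and_length():
    """Negative deflection first, then a larger positive peak."""
    x = simulate_erg_waveform(NOISELESS, rng=np.random.default_rng(0))
    assert x.size == NOISELESS.n_samples == 500
    i_min, i_max = int(np.argmin(x)), int(np.argmax(x))
    assert i_min < i_max
    assert x[i_min] < -1.0 and x[i_max] > 1.0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        simulate_erg_waveform(replace(NOISELESS, a_time=40.0))
    with pytest.raises(ValueError):
        simulate_erg_waveform(replace(NOISELESS, noise_sd=-1.0))
    with pytest.raises(ValueError):
        simulate_erg_waveform(NOISELESS, GroupEffect(b_amp_scale=-1.0))


def test_no_ops_no_energy_in_op_band():
    """Without injected oscillations the 80-120 Hz band is almost empty."""
    x = simulate_erg_waveform(NOISELESS, rng=np.random.default_rng(0))
    X = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(x.size, 1 / 2000.0)
    band = X[(f >= 80) & (f <= 120)].sum()
    assert band / X.sum() < 0.01


def test_td_detector_recovers_waveform_geometry():
    """Noiseless kernel calibration: detector finds the requested values."""
    x = simulate_erg_waveform(NOISELESS, rng=np.random.default_rng(0))
    td = extract_td_features(ERGRecording("s", "R", 446.0, 2000.0, x))
    assert abs(td.Ta - 15.0) <= 1.0
    assert abs(td.Tb - 30.0) <= 1.0
    assert td.Aa == pytest.approx(20.0, rel=0.05)
    assert td.Ab == pytest.approx(40.0, rel=0.05)


def test_tb_shift_monotonicity():
    """Larger tb_shift strictly increases extracted Tb (noiseless)."""
    tbs = []
    for shift in (0.0, 2.0, 4.0):
        x = simulate_erg_waveform(
            NOISELESS, GroupEffect(tb_shift=shift), np.random.default_rng(0)
        )
        td = extract_td_features(ERGRecording("s", "R", 446.0, 2000.0, x))
        tbs.append(td.Tb)
    assert tbs[0] < tbs[1] < tbs[2]


def _noiseless_config(**kwargs):
    return CohortConfig(
        base_params=NOISELESS,
        latency_sd=0.0, rec_latency_sd=0.0, a_latency_sd=0.0,
        amp_sigma=0.0, rec_amp_sigma=0.0, shape_sigma=0.0, op_sigma=0.0,
        **kwargs,
    )


def test_cohort_tb_shift_group_difference():
    """A +3 ms b-wave delay appears as a 3.0 +- 0.1 ms group mean Tb shift."""
    config = _noiseless_config(
        n_per_group={"control": 8, "ASD": 8, "ADHD": 0, "ASD_ADHD": 0},
        effects={"control": GroupEffect.identity(), "ASD": GroupEffect(tb_shift=3.0)},
        seed=3,
        eyes=("R",), flash_strengths=(446.0,),
    )
    manifest, recordings = simulate_cohort(config)
    group_of = {m.subject_id: m.group for m in manifest}
    tbs = {"control": [], "ASD": []}
    for rec in recordings:
        tbs[group_of[rec.subject_id]].append(extract_td_features(rec).Tb)
    diff = np.mean(tbs["ASD"]) - np.mean(tbs["control"])
    assert diff == pytest.approx(3.0, abs=0.1)


def test_cohort_determinism(small_cohort):
    config = CohortConfig(
        n_per_group={"control": 6, "ASD": 5, "ADHD": 4, "ASD_ADHD": 3}, seed=7
    )
    manifest2, recordings2 = simulate_cohort(config)
    manifest1, recordings1 = small_cohort
    assert [m.subject_id for m in manifest1] == [m.subject_id for m in manifest2]
    assert all(m1 == m2 for m1, m2 in zip(manifest1, manifest2))
    assert all(np.array_equal(r1.samples, r2.samples) for r1, r2 in zip(recordings1, recordings2))


def test_default_census_counts():
    manifest, _ = simulate_cohort(CohortConfig(seed=1, eyes=("R",), flash_strengths=(446.0,)))
    counts = Counter(m.group for m in manifest)
    assert counts == {"control": 137, "ASD": 77, "ADHD": 43, "ASD_ADHD": 21}
    control_sex = Counter(m.sex for m in manifest if m.group == "control")
    assert control_sex == {"M": 57, "F": 80}


def test_every_subject_has_four_recordings(small_cohort):
    manifest, recordings = small_cohort
    per_subject = Counter(r.subject_id for r in recordings)
    assert all(per_subject[m.subject_id] == 4 for m in manifest)
    slots = {(r.eye, r.flash_td_s) for r in recordings}
    assert slots == {("R", 113.0), ("R", 446.0), ("L", 113.0), ("L", 446.0)}


def test_missing_rate_drops_recordings():
    config = CohortConfig(
        n_per_group={"control": 20, "ASD": 0, "ADHD": 0, "ASD_ADHD": 0},
        missing_rate=0.3, seed=5, eyes=("R",), flash_strengths=(446.0,),
    )
    manifest, recordings = simulate_cohort(config)
    assert len(recordings) < len(manifest)


def test_empty_group_with_effect_rejected():
    config = CohortConfig(
        n_per_group={"control": 5, "ASD": 0, "ADHD": 0, "ASD_ADHD": 0},
        effects={"ASD": GroupEffect(tb_shift=2.0)},
    )
    with pytest.raises(ValueError, match="ASD"):
        simulate_cohort(config)


def test_flash_gain_scales_446():
    config = _noiseless_config(
        n_per_group={"control": 3, "ASD": 0, "ADHD": 0, "ASD_ADHD": 0},
        seed=2, eyes=("R",),
    )
    _, recordings = simulate_cohort(config)
    by_strength = {}
    for rec in recordings:
        by_strength.setdefault(rec.flash_td_s, []).append(extract_td_features(rec).Ab)
    ratio = np.mean(by_strength[446.0]) / np.mean(by_strength[113.0])
    assert ratio == pytest.approx(1.4, rel=0.05)
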