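"""Synthetic photopic ERG cohorts.

The clinical dataset behind this analysis is not public, so this module
generates cohorts with the statistical structure the pipeline assumes: four
diagnostic groups (control / ASD / ADHD / ASD+ADHD) with realistic group
sizes and sex ratios, two recording sites, two eyes and two flash strengths
(113 and 446 Td.s) per subject, and configurable group effects on b-wave
timing/amplitude and on the energy and kurtosis of the 40-Hz VFCDM
sub-bands.

The waveform kernel is the canonical photopic morphology: a cornea-negative
a-wave followed by a larger positive b-wave (both gamma-shaped bumps whose
amplitudes and peak times are calibrated numerically to the requested
values), oscillatory potentials as exponentially damped sinusoids near 80
and 160 Hz gated to the a-to-b rising limb, per-band narrow-band "texture"
noise carrying the injectable spectral effects, and band-limited white
measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from ergml.erg_io import ERGRecording, GROUPS, SubjectMeta

__all__ = [
    "WaveformParams",
    "GroupEffect",
    "CohortConfig",
    "simulate_erg_waveform",
    "simulate_cohort",
]

_N_BANDS = 8  # 40-Hz VFCDM bands tiling 0-320 Hz


@dataclass(frozen=True)
class WaveformParams:
    """Deterministic shape parameters of one averaged ERG waveform.

    Amplitudes are in uV (``a_amp`` baseline-to-trough, ``b_amp``
    trough-to-peak), times in ms after flash onset.  Defaults describe a
    skin-electrode photopic response to a 113 Td.s flash.
    """

    a_amp: float = 8.0
    a_time: float = 14.0
    b_amp: float = 25.0
    b_time: float = 30.0
    #: damped-sinusoid oscillatory-potential amplitudes (uV) at ~80 and ~160 Hz
    op_amps: tuple[float, ...] = (2.5, 1.2)
    op_decay: float = 0.08  # 1/ms
    noise_sd: float = 1.0
    duration: float = 250.0
    fs: float = 2000.0
    #: gamma-kernel shape (sharpness) of the a- and b-wave bumps; smaller is
    #: broader.  Jittered per subject to emulate morphology heterogeneity.
    shape_a: float = 22.0
    shape_b: float = 9.0
    #: RMS (uV) of the stationary narrow-band texture per 40-Hz band; this is
    #: the carrier of the injectable band-energy / band-kurtosis effects
    band_texture_rms: tuple[float, ...] = (0.0, 0.6, 0.9, 0.9, 0.6, 0.4, 0.3, 0.2)

    def validate(self) -> None:
        if self.a_time >= self.b_time:
            raise ValueError(f"a_time ({self.a_time}) must precede b_time ({self.b_time})")
        if self.a_amp < 0 or self.b_amp < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        n = self.duration * self.fs / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration*fs/1000 must be an integer sample count")
        if len(self.band_texture_rms) != _N_BANDS:
            raise ValueError(f"band_texture_rms must have {_N_BANDS} entries")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs / 1000.0))


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative / additive deviations of one group from the control.

    The control group is the identity effect: all scales 1, all shifts 0.
    """

    b_amp_scale: float = 1.0
    tb_shift: float = 0.0  # ms
    band_energy_scale: tuple[float, ...] = (1.0,) * _N_BANDS
    band_kurtosis_shift: tuple[float, ...] = (0.0,) * _N_BANDS

    def validate(self) -> None:
        if self.b_amp_scale <= 0:
            raise ValueError("b_amp_scale must be positive")
        if len(self.band_energy_scale) != _N_BANDS or len(self.band_kurtosis_shift) != _N_BANDS:
            raise ValueError(f"per-band effect vectors must have {_N_BANDS} entries")
        if any(s <= 0 for s in self.band_energy_scale):
            raise ValueError("band_energy_scale entries must be positive")

    @classmethod
    def identity(cls) -> "GroupEffect":
        return cls()

    @property
    def is_identity(self) -> bool:
        return (
            self.b_amp_scale == 1.0
            and self.tb_shift == 0.0
            and all(s == 1.0 for s in self.band_energy_scale)
            and all(s == 0.0 for s in self.band_kurtosis_shift)
        )


# census defaults: group sizes and male:female splits of the study population
_DEFAULT_N = {"control": 137, "ASD": 77, "ADHD": 43, "ASD_ADHD": 21}
_DEFAULT_MALE_FRACTION = {
    "control": 57 / 137,
    "ASD": 56 / 77,
    "ADHD": 25 / 43,
    "ASD_ADHD": 16 / 21,
}
# age distributions per group: mean, sd, (min, max) in years
_AGE = {
    "control": (12.2, 4.5, (5.0, 26.7)),
    "ASD": (12.8, 4.3, (5.9, 27.3)),
    "ADHD": (13.0, 3.4, (6.2, 21.8)),
    "ASD_ADHD": (12.9, 4.4, (6.9, 24.3)),
}
# fraction of each group on psychoactive medication, from the reported usage
_DEFAULT_MED_RATE = {"control": 0.015, "ASD": 0.26, "ADHD": 0.74, "ASD_ADHD": 0.62}


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort; the seed determines output."""

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_N))
    sex_ratio_per_group: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MALE_FRACTION)
    )
    site_assignment: tuple[float, float] = (0.5, 0.5)
    medication_rate_per_group: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MED_RATE)
    )
    effects: dict[str, GroupEffect] = field(
        default_factory=lambda: {g: GroupEffect.identity() for g in GROUPS}
    )
    seed: int = 0
    base_params: WaveformParams = WaveformParams()
    flash_strengths: tuple[float, ...] = (113.0, 446.0)
    #: a/b amplitude gain of the 446 Td.s flash relative to 113 Td.s
    flash_gain_446: float = 1.4
    eyes: tuple[str, ...] = ("R", "L")
    missing_rate: float = 0.0
    #: per-slot probability of an extra replicate recording (deduplicated at load)
    replicate_rate: float = 0.0
    #: subject-level log-normal amplitude sigma and Gaussian latency sd (ms)
    amp_sigma: float = 0.15
    latency_sd: float = 1.0
    #: subject-level morphology heterogeneity: log-normal jitter of the
    #: gamma-kernel shapes, independent a-wave latency sd (ms), and
    #: log-normal jitter of the oscillatory-potential amplitudes
    shape_sigma: float = 0.15
    a_latency_sd: float = 0.5
    op_sigma: float = 0.3
    #: within-subject (per-recording) residual variation
    rec_amp_sigma: float = 0.05
    rec_latency_sd: float = 0.25
    #: b-wave amplitude multiplier applied to medicated subjects
    medication_b_scale: float = 1.15

    def validate(self) -> None:
        self.base_params.validate()
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError(f"negative count for group {g}")
        for d in (self.sex_ratio_per_group, self.medication_rate_per_group):
            for g, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability out of [0,1] for group {g}: {p}")
        if not np.isclose(sum(self.site_assignment), 1.0):
            raise ValueError("site_assignment proportions must sum to 1")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0,1]")
        for g, eff in self.effects.items():
            eff.validate()
            if not eff.is_identity and self.n_per_group.get(g, 0) == 0:
                raise ValueError(
                    f"group {g!r} has a non-identity effect but zero subjects"
                )


def _gamma_bump(t: np.ndarray, t_peak: float, shape: float) -> np.ndarray:
    """Unit-height gamma-like bump peaking at t_peak (t in ms, t>=0)."""
    out = np.zeros_like(t)
    pos = t > 0
    r = t[pos] / t_peak
    out[pos] = r**shape * np.exp(shape * (1.0 - r))
    return out


def _ab_complex(
    t: np.ndarray,
    a_amp: float,
    a_time: float,
    b_amp: float,
    b_time: float,
    shape_a: float = 22.0,
    shape_b: float = 9.0,
) -> tuple[np.ndarray, float, float]:
    """Calibrated a-wave + b-wave compound.

    The two bumps overlap, so amplitudes and peak times are fixed-point
    calibrated: after convergence the sampled minimum is -a_amp at a_time and
    the trough-to-peak excursion is b_amp at b_time (to sample resolution).
    Returns the waveform and the calibrated trough/peak centre times.
    """
    ca, cb = a_amp, b_amp
    ta_c, tb_c = a_time, b_time
    for _ in range(10):
        s = -ca * _gamma_bump(t, ta_c, shape_a) + cb * _gamma_bump(t, tb_c, shape_b)
        i_min = int(np.argmin(s))
        after = s[i_min + 1 :]
        i_max = i_min + 1 + int(np.argmax(after)) if after.size else i_min
        m = -s[i_min]
        M = s[i_max] - s[i_min]
        if a_amp > 0 and m > 1e-9:
            ta_c = max(ta_c + (a_time - t[i_min]), 1.0)
            ca *= a_amp / m
        if b_amp > 0 and M > 1e-9:
            tb_c = max(tb_c + (b_time - t[i_max]), ta_c + 1.0)
            cb *= b_amp / M
    return (
        -ca * _gamma_bump(t, ta_c, shape_a) + cb * _gamma_bump(t, tb_c, shape_b),
        ta_c,
        tb_c,
    )


def _band_texture(
    t_s: np.ndarray,
    fs: float,
    band: int,
    rms: float,
    kurtosis_shift: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Narrow-band Gaussian texture for one 40-Hz band, optionally modulated.

    A kurtosis shift is injected by multiplying the band-limited Gaussian
    carrier with a slow log-normal envelope exp(sigma*u); sigma is chosen so
    the modulated texture alone has Pearson kurtosis 3 + shift.
    """
    n = t_s.size
    fc = (band + 0.5) * 40.0
    # slow complex envelope: white complex Gaussian smoothed to ~40 Hz bandwidth
    smooth = max(int(fs / 40.0), 2)
    kernel = np.ones(smooth) / smooth
    z = rng.standard_normal(n) + 1j * rng.standard_normal(n)
    z = np.convolve(z, kernel, mode="same")
    comp = np.real(z * np.exp(2j * np.pi * fc * t_s))
    if kurtosis_shift > 0:
        sigma = np.sqrt(np.log1p(kurtosis_shift / 3.0) / 4.0)
        # envelope fluctuations must be slower (~<10 Hz) than the analysis
        # band width, or band-limited demodulation smooths the bursts away
        slow = max(int(0.060 * fs), 2)
        u = np.convolve(rng.standard_normal(n), np.ones(slow) / slow, mode="same")
        u_sd = np.std(u)
        if u_sd > 0:
            comp = comp * np.exp(sigma * u / u_sd)
    c_rms = np.sqrt(np.mean(comp**2))
    return comp * (rms / c_rms) if c_rms > 0 else comp


def simulate_erg_waveform(
    params: WaveformParams,
    group_effect: GroupEffect | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Generate one averaged photopic ERG waveform (uV at ``params.fs``).

    Deterministic given the rng state; two calls with identically seeded
    generators return bit-identical arrays.
    """
    params.validate()
    eff = group_effect or GroupEffect.identity()
    eff.validate()
    rng = rng or np.random.default_rng()

    n = params.n_samples
    t = np.arange(n) * 1000.0 / params.fs  # ms
    t_s = t / 1000.0

    b_amp = params.b_amp * eff.b_amp_scale
    b_time = params.b_time + eff.tb_shift
    if params.a_time >= b_time:
        raise ValueError("tb_shift moved the b-wave before the a-wave")
    x, ta_c, tb_c = _ab_complex(
        t, params.a_amp, params.a_time, b_amp, b_time, params.shape_a, params.shape_b
    )

    # oscillatory potentials: damped sinusoids gated to the a->b rising limb
    limb = max(tb_c - ta_c, 1.0)
    gate = np.zeros(n)
    in_limb = (t >= ta_c) & (t <= tb_c + limb)
    gate[in_limb] = np.sin(np.pi * (t[in_limb] - ta_c) / (2.0 * limb)) ** 2
    for f_hz, amp in zip((80.0, 160.0), params.op_amps):
        if amp > 0:
            phase = 2 * np.pi * f_hz * (t - ta_c) / 1000.0
            x = x + amp * gate * np.exp(-params.op_decay * np.maximum(t - ta_c, 0.0)) * np.sin(phase)

    for k in range(_N_BANDS):
        rms = params.band_texture_rms[k] * np.sqrt(eff.band_energy_scale[k])
        if rms > 0:
            x = x + _band_texture(t_s, params.fs, k, rms, eff.band_kurtosis_shift[k], rng)

    if params.noise_sd > 0:
        noise = rng.standard_normal(n) * params.noise_sd
        # acquisition band limit (300 Hz low-pass)
        sos = sps.butter(4, 300.0, fs=params.fs, output="sos")
        x = x + sps.sosfiltfilt(sos, noise)

    return x


def simulate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[SubjectMeta], list[ERGRecording]]:
    """Generate a full cohort: manifest plus recordings.

    Each subject receives one recording per (eye, flash strength) slot
    (minus random dropouts at ``missing_rate``).  Subject-level random
    effects (log-normal amplitude factor, Gaussian latency shift) are shared
    across a subject's recordings so within-subject recordings correlate;
    small per-recording residuals are added on top.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    manifest: list[SubjectMeta] = []
    recordings: list[ERGRecording] = []
    sid_counter = 0

    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        if n == 0:
            continue
        male_frac = config.sex_ratio_per_group.get(group, 0.5)
        n_male = int(round(n * male_frac))
        sexes = ["M"] * n_male + ["F"] * (n - n_male)
        effect = config.effects.get(group, GroupEffect.identity())
        mu, sd, (lo, hi) = _AGE[group]
        med_rate = config.medication_rate_per_group.get(group, 0.0)

        for sex in sexes:
            sid_counter += 1
            sid = f"sub-{sid_counter:04d}"
            site = 1 if rng.random() < config.site_assignment[0] else 2
            age = float(np.clip(rng.normal(mu, sd), lo, hi))
            medicated = bool(rng.random() < med_rate)
            manifest.append(
                SubjectMeta(
                    subject_id=sid, group=group, sex=sex, age_years=age,
                    site=site, medicated=medicated,
                )
            )

            amp_factor = float(np.exp(rng.normal(0.0, config.amp_sigma)))
            lat_shift = float(rng.normal(0.0, config.latency_sd))
            a_lat_shift = lat_shift + float(rng.normal(0.0, config.a_latency_sd))
            shape_a = config.base_params.shape_a * float(
                np.exp(rng.normal(0.0, config.shape_sigma))
            )
            shape_b = config.base_params.shape_b * float(
                np.exp(rng.normal(0.0, config.shape_sigma))
            )
            op_factor = float(np.exp(rng.normal(0.0, config.op_sigma)))

            for eye in config.eyes:
                for strength in config.flash_strengths:
                    n_reps = 1 + (1 if rng.random() < config.replicate_rate else 0)
                    if rng.random() < config.missing_rate:
                        continue
                    for _ in range(n_reps):
                        gain = config.flash_gain_446 if strength >= 446 else 1.0
                        rec_amp = amp_factor * float(
                            np.exp(rng.normal(0.0, config.rec_amp_sigma))
                        )
                        rec_lat = lat_shift + float(rng.normal(0.0, config.rec_latency_sd))
                        med_scale = config.medication_b_scale if medicated else 1.0
                        rec_a_lat = a_lat_shift + (rec_lat - lat_shift)
                        p = replace(
                            config.base_params,
                            a_amp=config.base_params.a_amp * gain * rec_amp,
                            b_amp=config.base_params.b_amp * gain * rec_amp * med_scale,
                            a_time=max(config.base_params.a_time + rec_a_lat, 2.0),
                            b_time=config.base_params.b_time + rec_lat,
                            shape_a=shape_a,
                            shape_b=shape_b,
                            op_amps=tuple(a * op_factor for a in config.base_params.op_amps),
                        )
                        samples = simulate_erg_waveform(p, effect, rng)
                        recordings.append(
                            ERGRecording(
                                subject_id=sid, eye=eye, flash_td_s=strength,
                                fs=p.fs, samples=samples,
                            )
                        )
    return manifest, recordings
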