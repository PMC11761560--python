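"""Dataset containers and on-disk formats.

A dataset is a *manifest* (one row per subject: group, sex, age, site,
medication flag), an *index* (one row per recording: subject, eye, flash
strength, waveform path) and one small CSV per waveform (``time_ms``,
``amplitude_uv``).  This open dialect replaces the proprietary export format
of the recording device.  Times are in ms with 0 = flash onset; amplitudes in
microvolts; the default sampling rate is 2 kHz with recordings band-limited
to 0.1-300 Hz by the acquisition hardware.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ERGRecording",
    "SubjectMeta",
    "DatasetError",
    "GROUPS",
    "load_dataset",
    "write_dataset",
    "run_cli",
]

logger = logging.getLogger(__name__)

#: closed vocabulary of diagnostic groups
GROUPS = ("control", "ASD", "ADHD", "ASD_ADHD")
EYES = ("R", "L")
SEXES = ("M", "F")
SITES = (1, 2)


class DatasetError(ValueError):
    """Structured load error naming the offending row/file."""


@dataclass
class ERGRecording:
    """One averaged ERG waveform with its acquisition metadata."""

    subject_id: str
    eye: str
    flash_td_s: float
    fs: float
    samples: np.ndarray
    t0: float = 0.0  # ms offset of flash onset relative to the first sample

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise DatasetError(f"{self.subject_id}: fs must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise DatasetError(f"{self.subject_id}: empty sample array")
        if self.flash_td_s <= 0:
            raise DatasetError(
                f"{self.subject_id}: flash strength must be positive, got {self.flash_td_s}"
            )
        if self.eye not in EYES:
            raise DatasetError(f"{self.subject_id}: eye must be R or L, got {self.eye!r}")

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to flash onset."""
        return np.arange(self.samples.size) * 1000.0 / self.fs - self.t0

    @property
    def slot(self) -> str:
        """Recording slot label, e.g. ``R446``."""
        return f"{self.eye}{int(round(self.flash_td_s))}"


@dataclass
class SubjectMeta:
    """Per-subject labels: diagnostic group, sex, age, site, medication."""

    subject_id: str
    group: str
    sex: str
    age_years: float
    site: int
    medicated: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DatasetError(f"{self.subject_id}: unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise DatasetError(f"{self.subject_id}: sex must be M or F, got {self.sex!r}")
        if int(self.site) not in SITES:
            raise DatasetError(f"{self.subject_id}: site must be 1 or 2, got {self.site}")
        self.site = int(self.site)
        self.medicated = bool(self.medicated)


def write_dataset(
    manifest: list[SubjectMeta], recordings: list[ERGRecording], outdir: str | Path
) -> None:
    """Write manifest.csv, index.csv and one waveform CSV per recording."""
    outdir = Path(outdir)
    wavedir = outdir / "waveforms"
    wavedir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "sex": m.sex,
                "age_years": m.age_years,
                "site": m.site,
                "medicated": int(m.medicated),
            }
            for m in manifest
        ]
    ).to_csv(outdir / "manifest.csv", index=False)

    index_rows = []
    used_paths: set[str] = set()
    for rec in recordings:
        rel = f"waveforms/{rec.subject_id}_{rec.slot}.csv"
        rep = 1
        while rel in used_paths:  # replicate recordings get distinct files
            rel = f"waveforms/{rec.subject_id}_{rec.slot}_rep{rep}.csv"
            rep += 1
        used_paths.add(rel)
        pd.DataFrame(
            {"time_ms": rec.times_ms, "amplitude_uv": rec.samples}
        ).to_csv(outdir / rel, index=False, float_format="%.8g")
        index_rows.append(
            {
                "subject_id": rec.subject_id,
                "eye": rec.eye,
                "flash_td_s": rec.flash_td_s,
                "fs": rec.fs,
                "path": rel,
            }
        )
    pd.DataFrame(index_rows).to_csv(outdir / "index.csv", index=False)


def load_dataset(
    index_path: str | Path, manifest_path: str | Path
) -> tuple[list[SubjectMeta], list[ERGRecording]]:
    """Load and validate a dataset.

    Every recording's ``subject_id`` must resolve in the manifest.  Replicate
    recordings of the same (subject, eye, strength) are deduplicated: the
    first is retained, later ones dropped with a warning, matching the
    analysis rule that no signal is repeated across fused instances.
    """
    index_path, manifest_path = Path(index_path), Path(manifest_path)
    man_df = pd.read_csv(manifest_path, float_precision="round_trip")
    manifest: list[SubjectMeta] = []
    seen_ids: set[str] = set()
    for i, row in man_df.iterrows():
        sid = str(row["subject_id"])
        if sid in seen_ids:
            raise DatasetError(f"manifest row {i}: duplicate subject_id {sid!r}")
        seen_ids.add(sid)
        manifest.append(
            SubjectMeta(
                subject_id=sid,
                group=str(row["group"]),
                sex=str(row["sex"]),
                age_years=float(row["age_years"]),
                site=int(row["site"]),
                medicated=bool(int(row["medicated"])),
            )
        )

    idx_df = pd.read_csv(index_path, float_precision="round_trip")
    recordings: list[ERGRecording] = []
    seen_slots: set[tuple[str, str, float]] = set()
    for i, row in idx_df.iterrows():
        sid = str(row["subject_id"])
        if sid not in seen_ids:
            raise DatasetError(
                f"index row {i}: recording for subject {sid!r} absent from manifest"
            )
        key = (sid, str(row["eye"]), float(row["flash_td_s"]))
        if key in seen_slots:
            msg = f"index row {i}: replicate recording {key} dropped (first kept)"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        seen_slots.add(key)
        wav_path = index_path.parent / str(row["path"])
        wav = pd.read_csv(wav_path, float_precision="round_trip")
        samples = pd.to_numeric(wav["amplitude_uv"], errors="coerce").to_numpy()
        if np.isnan(samples).any():
            raise DatasetError(f"index row {i}: non-numeric samples in {wav_path}")
        fs = float(row["fs"]) if "fs" in row else 2000.0
        t0 = -float(wav["time_ms"].iloc[0])
        recordings.append(
            ERGRecording(
                subject_id=sid,
                eye=str(row["eye"]),
                flash_td_s=float(row["flash_td_s"]),
                fs=fs,
                samples=samples,
                t0=t0,
            )
        )
    return manifest, recordings


def run_cli(argv: list[str] | None = None) -> int:
    """Entry point for the ``ergml`` command; see :mod:`ergml.cli`."""
    from ergml.cli import run_cli as _run

    return _run(argv)
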