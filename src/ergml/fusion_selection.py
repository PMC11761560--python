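"""Feature fusion across families, eyes and flash strengths, plus selection.

Fusion concatenates per-recording feature blocks — TD (4), DWT (34), VFCDM
(64) — over the requested (eye, flash strength) slots of each subject, so a
two-slot TD+VFCDM table has 136 columns and a two-slot all-family table 204.
Columns are suffixed with the slot, e.g. ``vfcdm_kt_3_L113``.  Subjects
missing any required recording are dropped; replicate recordings of a slot
are never fused together (the first is used).

Selection implements the two threshold rules used throughout the analysis:
random-forest feature importance with a relative (0.25 x mean FI) or
absolute (>= 0.01) cut, and Shapley scores (mean over classes of the mean
absolute Shapley value across instances) with a >= 0.005 cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ergml.dwt_features import extract_dwt_features
from ergml.erg_io import ERGRecording, SubjectMeta
from ergml.shapley import model_shapley
from ergml.time_domain import extract_td_features
from ergml.vfcdm_features import extract_vfcdm_features

__all__ = [
    "FusionSpec",
    "FeatureTable",
    "SelectionResult",
    "extract_recording_features",
    "fuse_features",
    "filter_cohort",
    "fi_select",
    "shapley_select",
    "FAMILY_SIZES",
]

FAMILY_SIZES = {"TD": 4, "DWT": 34, "VFCDM": 64}
_FAMILY_ORDER = ("TD", "DWT", "VFCDM")


@dataclass(frozen=True)
class FusionSpec:
    """Which features, subjects and recording slots to fuse.

    ``preset="selected"`` applies the curated exclusion list on top of all
    three families: the a-wave time, the OP160 coefficients, and the
    statistics of VFCDM bands 7 and 8 are removed.
    """

    families: tuple[str, ...] = ("TD", "DWT", "VFCDM")
    recordings: tuple[tuple[str, float], ...] = (("R", 446.0), ("L", 446.0))
    sites: tuple[int, ...] = (1, 2)
    groups: tuple[str, ...] = ("control", "ASD", "ADHD", "ASD_ADHD")
    exclude_medicated: bool = False
    sex_filter: str = "both"  # both | M | F
    exclude_td: bool = False
    preset: str | None = None  # None | "selected"

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("at least one feature family is required")
        if not self.recordings:
            raise ValueError("at least one recording slot is required")
        for fam in self.families:
            if fam not in FAMILY_SIZES:
                raise ValueError(f"unknown family {fam!r}")
        if self.sex_filter not in ("both", "M", "F"):
            raise ValueError(f"sex_filter must be both/M/F, got {self.sex_filter!r}")


@dataclass
class FeatureTable:
    """Subject-instance feature matrix with labels and metadata.

    ``features`` is indexed by subject_id (one row per subject); ``labels``
    holds the group and ``meta`` the sex/site/medicated columns, all aligned
    on the same index.
    """

    features: pd.DataFrame
    labels: pd.Series
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.features.index.has_duplicates:
            raise ValueError("duplicated subject rows in feature table")
        if self.features.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def n_subjects(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset_rows(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.features.loc[mask], self.labels.loc[mask], self.meta.loc[mask])

    def subset_features(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(self.features[names], self.labels, self.meta)


@dataclass(frozen=True)
class SelectionResult:
    """Kept-feature set from a thresholded importance rule."""

    method: str  # FI_relative | FI_absolute | Shapley
    threshold: float
    kept_features: tuple[str, ...]
    scores: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "threshold": self.threshold,
            "kept_features": list(self.kept_features),
            "scores": self.scores,
        }


def extract_recording_features(rec: ERGRecording, families: tuple[str, ...]) -> dict[str, float]:
    """Un-suffixed features of one recording for the requested families."""
    feats: dict[str, float] = {}
    if "TD" in families:
        feats.update(extract_td_features(rec).as_dict())
    if "DWT" in families:
        feats.update(extract_dwt_features(rec))
    if "VFCDM" in families:
        feats.update(extract_vfcdm_features(rec))
    return feats


def _selected_preset_filter(name: str) -> bool:
    """True if the column survives the 'selected features' exclusion list."""
    base = name.rsplit("_", 1)[0] if "_" in name else name
    if base == "Ta":
        return False
    if base.startswith("dwt_OP160") or base == "dwt_sum_OP160":
        return False
    if base.startswith("vfcdm_") and base.endswith(("_7", "_8")):
        return False
    return True


def fuse_features(
    dataset: tuple[list[SubjectMeta], list[ERGRecording]],
    spec: FusionSpec,
    precomputed: dict[tuple[str, str, float], dict[str, float]] | None = None,
) -> FeatureTable:
    """Build the fused subject x feature table for a fusion spec.

    ``precomputed`` optionally maps (subject_id, eye, strength) to the
    un-suffixed per-recording feature dict, letting callers extract once and
    fuse many ways.  Subjects missing any required slot are dropped; cohort
    filters (site, group, medication, sex) are applied afterwards via
    :func:`filter_cohort`.
    """
    manifest, recordings = dataset
    families = tuple(f for f in _FAMILY_ORDER if f in spec.families)
    if spec.exclude_td:
        families = tuple(f for f in families if f != "TD")
        if not families:
            raise ValueError("exclude_td removed the only requested family")

    by_slot: dict[tuple[str, str, float], ERGRecording] = {}
    for rec in recordings:
        key = (rec.subject_id, rec.eye, float(rec.flash_td_s))
        by_slot.setdefault(key, rec)  # replicates: first kept

    rows: dict[str, dict[str, float]] = {}
    for meta in manifest:
        row: dict[str, float] = {}
        complete = True
        for eye, strength in spec.recordings:
            key = (meta.subject_id, eye, float(strength))
            if precomputed is not None and key in precomputed:
                feats = {
                    k: v
                    for k, v in precomputed[key].items()
                    if _family_of(k) in families
                }
            elif key in by_slot:
                feats = extract_recording_features(by_slot[key], families)
            else:
                complete = False
                break
            suffix = f"{eye}{int(round(strength))}"
            row.update({f"{name}_{suffix}": val for name, val in feats.items()})
        if complete:
            rows[meta.subject_id] = row

    if not rows:
        raise ValueError("no subject has all required recordings; table is empty")

    features = pd.DataFrame.from_dict(rows, orient="index")
    if spec.preset == "selected":
        keep = [c for c in features.columns if _selected_preset_filter(c)]
        features = features[keep]

    meta_df = pd.DataFrame(
        {
            "group": {m.subject_id: m.group for m in manifest},
            "sex": {m.subject_id: m.sex for m in manifest},
            "site": {m.subject_id: m.site for m in manifest},
            "medicated": {m.subject_id: m.medicated for m in manifest},
        }
    ).loc[features.index]
    table = FeatureTable(features=features, labels=meta_df["group"], meta=meta_df)
    return filter_cohort(table, spec)


def _family_of(name: str) -> str:
    if name.startswith("dwt_"):
        return "DWT"
    if name.startswith("vfcdm_"):
        return "VFCDM"
    return "TD"


def filter_cohort(table: FeatureTable, spec: FusionSpec) -> FeatureTable:
    """Apply site/medication/sex/group filters and 2-group relabelling.

    For a two-group contrast of control vs ASD (or ADHD), subjects with the
    co-occurring ASD+ADHD diagnosis are folded into the clinical class.
    """
    meta, labels = table.meta, table.labels.copy()

    groups = tuple(spec.groups)
    if set(groups) in ({"control", "ASD"}, {"control", "ADHD"}):
        clinical = next(g for g in groups if g != "control")
        labels = labels.mask(labels == "ASD_ADHD", clinical)

    mask = (
        meta["site"].isin(spec.sites)
        & labels.isin(groups)
        & (meta["sex"] == spec.sex_filter if spec.sex_filter != "both" else True)
    )
    if spec.exclude_medicated:
        mask &= ~meta["medicated"]

    out = FeatureTable(
        features=table.features.loc[mask],
        labels=labels.loc[mask],
        meta=meta.loc[mask],
    )
    present = set(out.labels.unique())
    missing = [g for g in groups if g not in present]
    if missing:
        raise ValueError(
            f"cohort filters removed every subject of group(s) {missing} "
            f"(sites={spec.sites}, sex={spec.sex_filter}, "
            f"exclude_medicated={spec.exclude_medicated})"
        )
    return out


def fi_threshold(fi: np.ndarray, mode: str) -> tuple[str, float, list[int]]:
    """Apply an FI threshold rule; returns (method, threshold, kept indices).

    ``relative_0.25_mean`` keeps FI >= 0.25 x mean(FI); ``absolute_0.01``
    keeps FI >= 0.01.  Features exactly at the threshold are kept.
    """
    fi = np.asarray(fi, dtype=float)
    if mode == "relative_0.25_mean":
        return "FI_relative", 0.25 * float(np.mean(fi)), \
            [i for i in range(fi.size) if fi[i] >= 0.25 * np.mean(fi)]
    if mode == "absolute_0.01":
        return "FI_absolute", 0.01, [i for i in range(fi.size) if fi[i] >= 0.01]
    raise ValueError(f"unknown FI mode {mode!r}")


def fi_select(
    table: FeatureTable,
    labels: pd.Series | None = None,
    mode: str = "relative_0.25_mean",
    seed: int = 0,
    n_estimators: int = 300,
) -> SelectionResult:
    """Random-forest feature-importance selection.

    ``relative_0.25_mean`` keeps features whose FI is at least 0.25 x the
    mean FI; ``absolute_0.01`` keeps FI >= 0.01.  The same forest-derived FI
    is used regardless of the downstream model family (kernel models have no
    native FI).  Features exactly at the threshold are kept; ordering is by
    descending FI with column order breaking ties.
    """
    y = table.labels if labels is None else labels
    X = table.features.to_numpy()
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if y.nunique() < 2:
        raise ValueError("need at least 2 classes")

    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    fi = rf.feature_importances_
    names = table.feature_names

    method, threshold, kept_idx = fi_threshold(fi, mode)
    if not kept_idx:
        warnings.warn("all feature importances below threshold; keeping all features")
        kept_idx = list(range(len(names)))
    kept_idx.sort(key=lambda i: (-fi[i], i))
    return SelectionResult(
        method=method,
        threshold=threshold,
        kept_features=tuple(names[i] for i in kept_idx),
        scores={names[i]: float(fi[i]) for i in range(len(names))},
    )


def shapley_scores(
    model,
    table: FeatureTable,
    seed: int = 0,
    max_background: int = 32,
    n_permutations: int = 8,
) -> dict[str, float]:
    """Per-feature score: mean over classes of mean |Shapley| across instances."""
    X = table.features.to_numpy()
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(len(X), size=min(max_background, len(X)), replace=False)
    background = X[bg_idx]

    n_classes = len(model.classes_)
    class_indices = [1] if n_classes == 2 else list(range(n_classes))
    scores = np.zeros(X.shape[1])
    for ci in class_indices:
        phi, _ = model_shapley(
            model, X, background, class_index=ci,
            method="permutation", n_permutations=n_permutations, seed=seed + ci,
        )
        scores += np.abs(phi).mean(axis=0)
    scores /= len(class_indices)
    return dict(zip(table.feature_names, scores.tolist()))


def shapley_select(
    model,
    table: FeatureTable,
    threshold: float = 0.005,
    seed: int = 0,
    **kwargs,
) -> SelectionResult:
    """Shapley-score selection: keep features with score >= threshold.

    The model must already be fitted on exactly the table's features.
    """
    scores = shapley_scores(model, table, seed=seed, **kwargs)
    names = table.feature_names
    kept_idx = [i for i, n in enumerate(names) if scores[n] >= threshold]
    if not kept_idx:
        warnings.warn("all Shapley scores below threshold; keeping top feature")
        kept_idx = [int(np.argmax([scores[n] for n in names]))]
    kept_idx.sort(key=lambda i: (-scores[names[i]], i))
    return SelectionResult(
        method="Shapley",
        threshold=threshold,
        kept_features=tuple(names[i] for i in kept_idx),
        scores={n: float(scores[n]) for n in names},
    )
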