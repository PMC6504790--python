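"""Identification accuracy, the window-size curve, and the static-FC baseline.

``evaluate`` scores a trained network on labeled clips (argmax of the
inference-mode softmax).  ``window_curve`` re-segments whole test
sessions at several window lengths and scores each; because the network
is recurrent it consumes any window length without retraining.
``fc_identify`` is the classical fingerprinting baseline: each subject
is summarized by the Pearson correlation matrix of their full training
(Day-1) series, and a test clip is assigned to the subject whose
vectorized connectivity profile correlates best with the clip's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas_io import RoiTimeSeries, TimeSeriesClip, segment_clips
from .convrnn import ConvRnnModel, predict_proba
from .errors import ValidationError


@dataclass
class AccuracyReport:
    n_clips: int
    n_correct: int
    accuracy: float
    per_subject: pd.DataFrame


@dataclass
class WindowCurve:
    """Accuracy as a function of evaluation window length."""

    rows: pd.DataFrame  # columns: window, n_clips, accuracy

    def __post_init__(self) -> None:
        w = self.rows["window"].to_numpy()
        if not np.all(np.diff(w) > 0):
            raise ValidationError("window values must be strictly increasing")


@dataclass
class FcDatabase:
    """Per-subject vectorized upper-triangular correlation profiles."""

    subjects: list[str]
    profiles: np.ndarray  # (n_subjects, K*(K-1)/2)


def _report(true_subjects: Sequence[str], predicted: Sequence[str]) -> AccuracyReport:
    df = pd.DataFrame({"subject_id": list(true_subjects), "predicted": list(predicted)})
    df["correct"] = df["subject_id"] == df["predicted"]
    per_subject = (
        df.groupby("subject_id")["correct"]
        .agg(n_clips="size", n_correct="sum")
        .reset_index()
    )
    per_subject["accuracy"] = per_subject["n_correct"] / per_subject["n_clips"]
    n_correct = int(df["correct"].sum())
    return AccuracyReport(
        n_clips=len(df),
        n_correct=n_correct,
        accuracy=n_correct / len(df),
        per_subject=per_subject,
    )


def evaluate(
    model: ConvRnnModel,
    clips: Sequence[TimeSeriesClip],
    batch_size: int = 128,
) -> AccuracyReport:
    """Score labeled clips with inference-mode argmax predictions."""
    if not clips:
        raise ValidationError("clip list is empty")
    if model.label_map is None:
        raise ValidationError("model carries no label map; train it first")
    windows = {c.window for c in clips}
    if len(windows) != 1:
        raise ValidationError(f"clips have mixed window lengths: {sorted(windows)}")
    inverse = {v: k for k, v in model.label_map.items()}
    x = np.stack([c.values for c in clips])
    pred_idx = predict_proba(model, x, batch_size=batch_size).argmax(axis=1)
    predicted = [inverse.get(int(i), f"<class {i}>") for i in pred_idx]
    return _report([c.subject_id for c in clips], predicted)


def window_curve(
    model: ConvRnnModel,
    test_sessions: Iterable[RoiTimeSeries],
    windows: Sequence[int] = (1, 5, 10, 25, 50, 100, 200, 400, 600, 1200),
    batch_size: int = 128,
) -> WindowCurve:
    """Accuracy at several evaluation window lengths.

    Each session is segmented non-overlapping from frame 0 with the
    remainder dropped, exactly as during training.  Windows longer than
    the shortest session are skipped with a warning.
    """
    sessions = list(test_sessions)
    if not sessions:
        raise ValidationError("no test sessions given")
    min_frames = min(ts.n_frames for ts in sessions)
    rows = []
    for w in sorted(set(int(w) for w in windows)):
        if w > min_frames:
            warnings.warn(
                f"window {w} exceeds the shortest session ({min_frames} frames); skipped"
            )
            continue
        clips = [clip for ts in sessions for clip in segment_clips(ts, w)]
        report = evaluate(model, clips, batch_size=batch_size)
        rows.append({"window": w, "n_clips": report.n_clips, "accuracy": report.accuracy})
    return WindowCurve(rows=pd.DataFrame(rows))


def _fc_profile(values: np.ndarray, context: str) -> np.ndarray:
    """Vectorized upper-triangular Pearson correlation of a frames x K matrix.

    Columns with zero variance produce undefined correlations; those
    entries are set to 0 with a warning so short windows stay usable.
    An all-undefined profile (e.g. a constant clip) is an error.
    """
    if values.shape[0] < 3:
        raise ValidationError(
            f"{context}: at least 3 frames are needed to form correlations"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    iu = np.triu_indices(values.shape[1], k=1)
    profile = corr[iu]
    bad = ~np.isfinite(profile)
    if bad.all():
        raise ValidationError(f"{context}: all correlations are undefined")
    if bad.any():
        warnings.warn(
            f"{context}: {int(bad.sum())} undefined correlation(s) from "
            "zero-variance ROIs set to 0"
        )
        profile = np.where(bad, 0.0, profile)
    return np.clip(profile, -1.0, 1.0)


def build_fc_database(
    train_sessions: Iterable[RoiTimeSeries] | Mapping[str, Sequence[RoiTimeSeries]],
) -> FcDatabase:
    """One connectivity profile per subject from their concatenated series."""
    if isinstance(train_sessions, Mapping):
        grouped = {k: list(v) for k, v in train_sessions.items()}
    else:
        grouped = {}
        for ts in train_sessions:
            grouped.setdefault(ts.subject_id, []).append(ts)
    if len(grouped) < 2:
        raise ValidationError("FC identification needs at least 2 subjects")
    subjects = sorted(grouped)
    profiles = np.stack(
        [
            _fc_profile(
                np.concatenate([ts.values for ts in grouped[s]], axis=0),
                context=f"subject {s} database series",
            )
            for s in subjects
        ]
    )
    return FcDatabase(subjects=subjects, profiles=profiles)


def fc_identify(
    train_sessions: Iterable[RoiTimeSeries] | Mapping[str, Sequence[RoiTimeSeries]],
    test_clips: Sequence[TimeSeriesClip],
) -> AccuracyReport:
    """Static functional-connectivity matching baseline.

    A clip is assigned to the database subject maximizing the Pearson
    correlation between vectorized FC profiles; exact ties go to the
    lowest subject index (database order is sorted subject id).
    """
    db = build_fc_database(train_sessions)
    if not test_clips:
        raise ValidationError("clip list is empty")
    db_centered = db.profiles - db.profiles.mean(axis=1, keepdims=True)
    db_norm = db_centered / np.linalg.norm(db_centered, axis=1, keepdims=True)
    predicted = []
    for clip in test_clips:
        profile = _fc_profile(
            clip.values, context=f"clip {clip.clip_index} of {clip.subject_id}"
        )
        centered = profile - profile.mean()
        denom = np.linalg.norm(centered)
        if denom == 0:
            raise ValidationError(
                f"clip {clip.clip_index} of {clip.subject_id}: constant FC profile"
            )
        scores = db_norm @ (centered / denom)
        predicted.append(db.subjects[int(np.argmax(scores))])
    return _report([c.subject_id for c in test_clips], predicted)
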