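"""Atlas handling, ROI time-series extraction, normalization, and clip segmentation.

The spatial unit of the whole package is the ROI: a sphere around an
atlas coordinate (MNI millimetres) whose voxel signals are averaged into
a single time series.  The atlas file fixes the ROI *order*, which
defines the 1-D axis the network convolves over, so every time-series
matrix in the package keeps its columns in atlas order.

On-disk formats are plain tab-separated text:

* atlas: header row with columns ``roi_id``, ``x_mm``, ``y_mm``, ``z_mm``,
  ``diameter_mm``, ``network_label``;
* time series: a frames x ROIs matrix with no header;
* manifest: header row with columns ``subject_id``, ``session_id``,
  ``path`` and optionally ``role`` (train / validation / test).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

ATLAS_COLUMNS = ("roi_id", "x_mm", "y_mm", "z_mm", "diameter_mm", "network_label")

#: standard deviation below which a column is treated as constant
ZERO_VARIANCE_TOL = 1e-12


class RoiRecord(NamedTuple):
    roi_id: int
    x_mm: float
    y_mm: float
    z_mm: float
    diameter_mm: float
    network_label: str
    order_index: int


@dataclass(frozen=True)
class RoiAtlas:
    """Ordered ROI table defining the 1-D spatial axis."""

    rois: tuple[RoiRecord, ...]

    def __post_init__(self) -> None:
        order = [r.order_index for r in self.rois]
        if order != list(range(len(self.rois))):
            raise ValidationError("order_index values must be exactly 0..K-1 in order")
        for r in self.rois:
            if not r.diameter_mm > 0:
                raise ValidationError(f"ROI {r.roi_id}: diameter_mm must be > 0")

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def roi_ids(self) -> np.ndarray:
        return np.array([r.roi_id for r in self.rois])

    @property
    def coordinates_mm(self) -> np.ndarray:
        """(K, 3) array of sphere centers in MNI millimetres."""
        return np.array([[r.x_mm, r.y_mm, r.z_mm] for r in self.rois], dtype=float)

    @property
    def network_labels(self) -> list[str]:
        return [r.network_label for r in self.rois]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rois)


@dataclass
class RoiTimeSeries:
    """A frames x K matrix of ROI signals from one scanning session.

    ``zero_variance`` is a boolean mask over columns that were constant
    when the series was normalized; those columns are stored as all
    zeros (the same convention occlusion uses for "no signal").
    """

    values: np.ndarray
    frame_interval_s: float = 0.72
    subject_id: str = ""
    session_id: str = ""
    normalized: bool = False
    zero_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("time series values must be a 2-D frames x ROIs array")
        if not self.frame_interval_s > 0:
            raise ValidationError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class TimeSeriesClip:
    """A fixed-length window cut from one session, with provenance."""

    values: np.ndarray
    subject_id: str
    session_id: str
    clip_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValidationError("clip values must be a W x K array with W >= 1")

    @property
    def window(self) -> int:
        return self.values.shape[0]


@dataclass
class CohortSplit:
    """Train / validation / test partition of clips, plus the class labels."""

    train: list[TimeSeriesClip]
    validation: list[TimeSeriesClip]
    test: list[TimeSeriesClip]
    label_map: dict[str, int] = field(default_factory=dict)


def load_atlas(path: str | os.PathLike) -> RoiAtlas:
    """Read a tab-separated atlas table, preserving file order."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"atlas file {path} is empty") from exc
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"atlas file {path} is missing columns: {missing}")
    if len(df) == 0:
        raise ValidationError(f"atlas file {path} contains no ROI rows")
    if df["roi_id"].duplicated().any():
        dupes = df.loc[df["roi_id"].duplicated(), "roi_id"].tolist()
        raise ValidationError(f"duplicate roi_id values in atlas: {dupes}")
    records = tuple(
        RoiRecord(
            roi_id=int(row.roi_id),
            x_mm=float(row.x_mm),
            y_mm=float(row.y_mm),
            z_mm=float(row.z_mm),
            diameter_mm=float(row.diameter_mm),
            network_label=str(row.network_label),
            order_index=i,
        )
        for i, row in enumerate(df.itertuples(index=False))
    )
    return RoiAtlas(rois=records)


def _sphere_voxel_indices(
    shape3: tuple[int, int, int],
    affine: np.ndarray,
    inv_affine: np.ndarray,
    center_mm: np.ndarray,
    radius_mm: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of voxels whose centers lie within ``radius_mm`` of ``center_mm``."""
    center_vox = inv_affine @ np.append(center_mm, 1.0)
    # conservative search box: radius divided by the smallest axis step
    steps = np.linalg.norm(affine[:3, :3], axis=0)
    span = np.ceil(radius_mm / steps).astype(int) + 1
    lo = np.maximum(np.floor(center_vox[:3]).astype(int) - span, 0)
    hi = np.minimum(np.ceil(center_vox[:3]).astype(int) + span + 1, shape3)
    if np.any(lo >= hi):
        return (np.array([], int),) * 3
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)], axis=0)
    mm = (affine @ vox)[:3].T
    inside = np.linalg.norm(mm - center_mm, axis=1) <= radius_mm
    return ii.ravel()[inside], jj.ravel()[inside], kk.ravel()[inside]


def extract_roi_timeseries(image, atlas: RoiAtlas) -> RoiTimeSeries:
    """Average voxels within each atlas sphere, for every frame.

    ``image`` is a nibabel spatial image (or a path to one) with a 4-D
    data array and a voxel-to-MNI affine.  A voxel belongs to an ROI when
    its center lies within ``diameter_mm / 2`` (Euclidean, millimetres)
    of the ROI center.
    """
    import nibabel as nib

    if isinstance(image, (str, os.PathLike)):
        image = nib.load(image)
    data = np.asarray(image.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValidationError(f"expected a 4-D image, got {data.ndim}-D")
    affine = np.asarray(image.affine, dtype=float)
    try:
        inv_affine = np.linalg.inv(affine)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("image affine is singular") from exc

    n_frames = data.shape[3]
    out = np.empty((n_frames, len(atlas)), dtype=float)
    for r in atlas.rois:
        center = np.array([r.x_mm, r.y_mm, r.z_mm])
        ii, jj, kk = _sphere_voxel_indices(
            data.shape[:3], affine, inv_affine, center, r.diameter_mm / 2.0
        )
        if ii.size == 0:
            raise ValidationError(
                f"ROI {r.roi_id} ({r.network_label}): sphere at "
                f"({r.x_mm}, {r.y_mm}, {r.z_mm}) mm contains no voxels"
            )
        out[:, r.order_index] = data[ii, jj, kk, :].mean(axis=0)
    return RoiTimeSeries(values=out, normalized=False)


def normalize_timeseries(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Demean and scale each column to unit (population) variance.

    Constant columns cannot be scaled; they become all zeros and are
    flagged in ``zero_variance`` instead of raising.
    """
    if ts.normalized:
        raise ValidationError("time series is already normalized")
    if ts.n_frames < 2:
        raise ValidationError("normalization requires at least 2 frames")
    mean = ts.values.mean(axis=0)
    std = ts.values.std(axis=0)  # population convention (divide by N)
    zero = std < ZERO_VARIANCE_TOL
    centered = ts.values - mean
    out = np.where(zero, 0.0, centered / np.where(zero, 1.0, std))
    return replace(ts, values=out, normalized=True, zero_variance=zero)


def segment_clips(ts: RoiTimeSeries, window: int) -> list[TimeSeriesClip]:
    """Cut a session into non-overlapping ``window``-frame clips.

    Clips start at frame 0; the remainder after ``floor(frames/window)``
    whole windows is discarded.
    """
    window = int(window)
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if window > ts.n_frames:
        raise ValidationError(
            f"window ({window}) exceeds session length ({ts.n_frames} frames)"
        )
    n_clips = ts.n_frames // window
    return [
        TimeSeriesClip(
            values=ts.values[i * window : (i + 1) * window].copy(),
            subject_id=ts.subject_id,
            session_id=ts.session_id,
            clip_index=i,
        )
        for i in range(n_clips)
    ]


def build_split(
    sessions: Mapping[str, Sequence[RoiTimeSeries]],
    window: int,
    roles: Mapping[tuple[str, str], str] | None = None,
    normalize: bool = True,
) -> CohortSplit:
    """Partition per-subject sessions into train/validation/test clips.

    Without an explicit ``roles`` mapping the assignment is positional,
    mirroring the two-day design: all but the last two sessions train
    the model (sessions 1-2 of 4), the second-to-last is validation and
    the last is test.  ``roles`` maps ``(subject_id, session_id)`` to
    ``"train" | "validation" | "test"`` and overrides the positional rule.
    """
    split = CohortSplit(train=[], validation=[], test=[], label_map={})
    for subject_id in sorted(sessions):
        sess = list(sessions[subject_id])
        if roles is None and len(sess) < 3:
            raise ValidationError(
                f"subject {subject_id} has {len(sess)} session(s); "
                "at least 3 are needed (train / validation / test)"
            )
        per_role: dict[str, list[RoiTimeSeries]] = {"train": [], "validation": [], "test": []}
        for pos, ts in enumerate(sess):
            if roles is not None:
                try:
                    role = roles[(subject_id, ts.session_id)]
                except KeyError as exc:
                    raise ValidationError(
                        f"no role for subject {subject_id} session {ts.session_id}"
                    ) from exc
                if role not in per_role:
                    raise ValidationError(f"unknown role {role!r}")
            else:
                role = (
                    "train"
                    if pos < len(sess) - 2
                    else ("validation" if pos == len(sess) - 2 else "test")
                )
            if normalize and not ts.normalized:
                ts = normalize_timeseries(ts)
            per_role[role].append(ts)
        for role, lst in per_role.items():
            if not lst:
                raise ValidationError(f"subject {subject_id} has no {role} session")
        for role, target in (
            ("train", split.train),
            ("validation", split.validation),
            ("test", split.test),
        ):
            for ts in per_role[role]:
                target.extend(segment_clips(ts, window))
    split.label_map = {sid: i for i, sid in enumerate(sorted(sessions))}
    return split


# ---------------------------------------------------------------------------
# plain-text I/O


def write_timeseries(ts: RoiTimeSeries, path: str | os.PathLike) -> None:
    """Write the frames x ROIs matrix as headerless tab-separated text."""
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.6f")


def read_timeseries(
    path: str | os.PathLike,
    subject_id: str = "",
    session_id: str = "",
    frame_interval_s: float = 0.72,
    normalized: bool = False,
) -> RoiTimeSeries:
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return RoiTimeSeries(
        values=values,
        frame_interval_s=frame_interval_s,
        subject_id=subject_id,
        session_id=session_id,
        normalized=normalized,
    )


def write_manifest(rows: Sequence[dict], path: str | os.PathLike) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_cohort(
    manifest_path: str | os.PathLike,
) -> tuple[dict[str, list[RoiTimeSeries]], dict[tuple[str, str], str] | None]:
    """Load all sessions referenced by a manifest.

    Returns the per-subject session lists (in manifest order) and, when
    the manifest carries a ``role`` column, the role mapping for
    :func:`build_split`.
    """
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "session_id", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise FormatError(f"manifest is missing columns: {sorted(missing)}")
    base = os.path.dirname(os.fspath(manifest_path))
    sessions: dict[str, list[RoiTimeSeries]] = {}
    roles: dict[tuple[str, str], str] = {}
    for row in manifest.itertuples(index=False):
        path = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        ts = read_timeseries(path, subject_id=str(row.subject_id), session_id=str(row.session_id))
        sessions.setdefault(str(row.subject_id), []).append(ts)
        if "role" in manifest.columns:
            roles[(str(row.subject_id), str(row.session_id))] = str(row.role)
    return sessions, (roles if "role" in manifest.columns else None)
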