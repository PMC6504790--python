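"""Synthetic multi-session resting-state cohorts with learnable identity.

Each subject carries a session-stable spatiotemporal signature built
from two channels:

* a spatial ``loading`` matrix (ROIs x latent factors) mixing shared
  latent Gaussian fluctuations into the ROIs, which fixes the subject's
  spatial covariance pattern (the "functional connectivity fingerprint");
* a per-ROI AR(1) coefficient vector shaping each ROI's temporal
  autocorrelation.

The per-frame generative model for subject ``s`` is

    x[t] = ar_s * x[t-1] + L_s @ z[t] + noise_sd * eps[t]

with ``z[t]`` a standard-Gaussian latent vector and ``eps`` white noise.
``signature_strength`` dials how subject-specific both channels are:
at 0 every subject shares the same dynamics (identification is chance),
at 1 loadings have unit-scale Gaussian entries and AR coefficients are
uniform over ``ar_coeff_range``.

Streams are derived by seed-sequence spawning from ``(seed, subject,
session)``, so growing a cohort never reshuffles existing subjects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .atlas_io import RoiTimeSeries, write_manifest, write_timeseries
from .errors import ValidationError

#: frames simulated and discarded before each session to reach stationarity
BURN_IN_FRAMES = 100


@dataclass(frozen=True)
class CohortSpec:
    """Study-shape and signal parameters of a simulated cohort.

    Defaults mirror the emulated study design: 4 sessions of 1200 frames
    (TR 0.72 s) over 236 atlas-ordered ROIs, at a cohort size that a
    single CPU can train on.
    """

    n_subjects: int = 20
    n_sessions: int = 4
    frames_per_session: int = 1200
    n_rois: int = 236
    latent_dim: int = 10
    ar_coeff_range: tuple[float, float] = (0.2, 0.8)
    signature_strength: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    frame_interval_s: float = 0.72

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if self.n_sessions < 3:
            raise ValidationError("n_sessions must be >= 3 (train/validation/test)")
        for name in ("frames_per_session", "n_rois", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.ar_coeff_range
        if not (-1.0 < lo <= hi < 1.0):
            raise ValidationError("ar_coeff_range must lie within (-1, 1)")
        if self.signature_strength < 0:
            raise ValidationError("signature_strength must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


class SubjectSignature(NamedTuple):
    loading: np.ndarray  # (n_rois, latent_dim)
    ar: np.ndarray  # (n_rois,)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def simulate_subject_signature(spec: CohortSpec, subject_index: int) -> SubjectSignature:
    """Draw the session-stable signature of one subject.

    Deterministic given ``(spec.seed, subject_index)``.  The loading is
    i.i.d. Gaussian scaled by ``signature_strength``.  The AR vector is
    a uniform draw over ``ar_coeff_range`` pulled toward the range
    midpoint as the strength shrinks, so that at strength 0 all subjects
    share identical dynamics and carry no identity in either channel.
    """
    if not 0 <= subject_index < spec.n_subjects:
        raise ValidationError(
            f"subject_index {subject_index} out of range for {spec.n_subjects} subjects"
        )
    rng = _rng(spec.seed, 1, subject_index)
    loading = spec.signature_strength * rng.standard_normal((spec.n_rois, spec.latent_dim))
    lo, hi = spec.ar_coeff_range
    mid = 0.5 * (lo + hi)
    draw = rng.uniform(lo, hi, size=spec.n_rois)
    ar = np.clip(mid + spec.signature_strength * (draw - mid), lo, hi)
    return SubjectSignature(loading=loading, ar=ar)


def simulate_session(
    signature: SubjectSignature,
    spec: CohortSpec,
    session_index: int,
    subject_index: int,
) -> RoiTimeSeries:
    """Simulate one session's unnormalized frames x ROIs matrix.

    The first :data:`BURN_IN_FRAMES` frames are simulated and discarded
    so the returned series is approximately stationary.
    """
    rng = _rng(spec.seed, 2, subject_index, session_index)
    total = spec.frames_per_session + BURN_IN_FRAMES
    z = rng.standard_normal((total, spec.latent_dim))
    eps = spec.noise_sd * rng.standard_normal((total, spec.n_rois))
    drive = z @ signature.loading.T + eps
    out = np.empty((total, spec.n_rois))
    x = np.zeros(spec.n_rois)
    ar = signature.ar
    for t in range(total):
        x = ar * x + drive[t]
        out[t] = x
    return RoiTimeSeries(
        values=out[BURN_IN_FRAMES:],
        frame_interval_s=spec.frame_interval_s,
        subject_id=f"sub-{subject_index:03d}",
        session_id=f"ses-{session_index + 1}",
        normalized=False,
    )


def stationary_covariance(signature: SubjectSignature, spec: CohortSpec) -> np.ndarray:
    """Closed-form stationary ROI covariance of the generative model.

    With diagonal AR transition ``A = diag(ar)`` and innovation
    covariance ``Q = L L^T + noise_sd^2 I``, the stationary covariance
    solves ``S = A S A + Q`` entrywise: ``S_ij = Q_ij / (1 - ar_i ar_j)``.
    """
    q = signature.loading @ signature.loading.T + (spec.noise_sd**2) * np.eye(spec.n_rois)
    return q / (1.0 - np.outer(signature.ar, signature.ar))


def simulate_cohort(
    spec: CohortSpec, out_dir: str | os.PathLike | None = None
) -> dict[str, list[RoiTimeSeries]]:
    """Simulate every subject's sessions; optionally write them to disk.

    Returns the per-subject session lists (ready for
    :func:`connprint.atlas_io.build_split`).  When ``out_dir`` is given,
    sessions are written as tab-separated matrices plus a ``manifest.tsv``
    with positional roles; identical specs produce byte-identical output.
    """
    sessions: dict[str, list[RoiTimeSeries]] = {}
    rows = []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    for s in range(spec.n_subjects):
        signature = simulate_subject_signature(spec, s)
        subject_sessions = [
            simulate_session(signature, spec, j, s) for j in range(spec.n_sessions)
        ]
        sessions[subject_sessions[0].subject_id] = subject_sessions
        if out_dir is not None:
            for pos, ts in enumerate(subject_sessions):
                fname = f"{ts.subject_id}_{ts.session_id}.tsv"
                write_timeseries(ts, os.path.join(out_dir, fname))
                role = (
                    "train"
                    if pos < spec.n_sessions - 2
                    else ("validation" if pos == spec.n_sessions - 2 else "test")
                )
                rows.append(
                    {
                        "subject_id": ts.subject_id,
                        "session_id": ts.session_id,
                        "path": fname,
                        "role": role,
                    }
                )
    if out_dir is not None:
        write_manifest(rows, os.path.join(out_dir, "manifest.tsv"))
    return sessions
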