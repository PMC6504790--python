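"""Model interpretation: occlusion maps, filter activation maps, 2-D embedding.

Three complementary views of what a trained network uses:

* **occlusion**: zero out one ROI's (already normalized) input column at
  a time and record the drop in identification accuracy — the ROI's
  contribution to the decision;
* **activation maps**: the mean post-ReLU output of each ConvLSTM layer
  per filter per ROI, averaged over clips and time — where each filter
  responds along the atlas axis;
* **embedding**: t-SNE of the pre-classifier feature vectors (length
  ``n_rois * last_filters``, 3776 for the default architecture), which
  shows whether subjects form separated clusters in feature space.

Because every layer preserves the ROI axis ("same" padding, no pooling),
all maps live on the atlas and can be exported per-ROI for external
surface renderers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas_io import RoiAtlas, TimeSeriesClip
from .convrnn import ConvRnnModel, _model_forward, predict_proba
from .errors import ValidationError


@dataclass
class OcclusionMap:
    """Per-ROI accuracy degradation under single-ROI occlusion.

    ``normalized_contribution`` is ``|degradation| / max |degradation|``
    (all zeros when every degradation is zero), so the most informative
    ROI scores exactly 1.
    """

    baseline_accuracy: float
    table: pd.DataFrame  # roi_id, accuracy_when_occluded, degradation, normalized_contribution

    @property
    def values(self) -> np.ndarray:
        return self.table["normalized_contribution"].to_numpy()


@dataclass
class ActivationMap:
    """Mean post-activation per filter per ROI for one layer."""

    layer_index: int
    values: np.ndarray  # (n_filters, n_rois)


@dataclass
class EmbeddingResult:
    points: pd.DataFrame  # subject_id, x, y
    perplexity: float
    seed: int


def _clip_array(clips: Sequence[TimeSeriesClip]) -> np.ndarray:
    if not clips:
        raise ValidationError("clip list is empty")
    windows = {c.window for c in clips}
    if len(windows) != 1:
        raise ValidationError(f"clips have mixed window lengths: {sorted(windows)}")
    return np.stack([c.values for c in clips])


def occlusion_analysis(
    model: ConvRnnModel,
    clips: Sequence[TimeSeriesClip],
    atlas: RoiAtlas,
    batch_size: int = 128,
) -> OcclusionMap:
    """Accuracy drop when each ROI's input is zeroed, one ROI at a time.

    Zeroing acts on the network's actual (normalized) input, so an
    occluded ROI contributes its session-mean signal.  Deterministic
    given the model and clips.
    """
    if len(atlas) != model.config.n_rois:
        raise ValidationError(
            f"atlas has {len(atlas)} ROIs, model expects {model.config.n_rois}"
        )
    if model.label_map is None:
        raise ValidationError("model carries no label map; train it first")
    x = _clip_array(clips)
    y = np.array([model.label_map[c.subject_id] for c in clips])

    def acc(batch: np.ndarray) -> float:
        pred = predict_proba(model, batch, batch_size=batch_size).argmax(axis=1)
        return float((pred == y).mean())

    baseline = acc(x)
    occluded = np.empty(len(atlas))
    for j in range(len(atlas)):
        saved = x[:, :, j].copy()
        x[:, :, j] = 0.0
        occluded[j] = acc(x)
        x[:, :, j] = saved
    degradation = baseline - occluded
    peak = np.abs(degradation).max()
    normalized = np.abs(degradation) / peak if peak > 0 else np.zeros_like(degradation)
    table = pd.DataFrame(
        {
            "roi_id": atlas.roi_ids,
            "accuracy_when_occluded": occluded,
            "degradation": degradation,
            "normalized_contribution": normalized,
        }
    )
    return OcclusionMap(baseline_accuracy=baseline, table=table)


def activation_maps(
    model: ConvRnnModel,
    clips: Sequence[TimeSeriesClip],
    batch_size: int = 128,
) -> list[ActivationMap]:
    """Mean inference-mode post-ReLU output of every layer.

    Averaging runs over clips and time steps, leaving one value per
    (filter, ROI); invariant to clip order and batch grouping.
    """
    x = _clip_array(clips)
    n_layers = model.config.n_layers
    sums = [
        np.zeros((f, model.config.n_rois)) for f in model.config.layer_filters
    ]
    count = 0
    for start in range(0, x.shape[0], batch_size):
        xb = x[start : start + batch_size]
        out = _model_forward(
            model.weights, model.config, xb, training=False, keep_cache=True
        )
        for li in range(n_layers):
            aseq = out["caches"][li]["aseq"]  # (W, B, K, F)
            sums[li] += aseq.sum(axis=(0, 1)).T.astype(float)
        count += xb.shape[0] * x.shape[1]
    return [
        ActivationMap(layer_index=li, values=sums[li] / count) for li in range(n_layers)
    ]


def embed_features(
    model: ConvRnnModel,
    clips: Sequence[TimeSeriesClip],
    perplexity: float = 30.0,
    seed: int = 0,
) -> EmbeddingResult:
    """t-SNE of the pre-classifier feature vectors, one 2-D point per clip."""
    from sklearn.manifold import TSNE

    x = _clip_array(clips)
    if x.shape[0] < 2:
        raise ValidationError("embedding needs at least 2 clips")
    if perplexity >= x.shape[0]:
        raise ValidationError(
            f"perplexity ({perplexity}) must be smaller than the number of clips ({x.shape[0]})"
        )
    feats = []
    for start in range(0, x.shape[0], 128):
        out = _model_forward(model.weights, model.config, x[start : start + 128], training=False)
        feats.append(out["feat"].astype(float))
    features = np.concatenate(feats, axis=0)
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(features)
    points = pd.DataFrame(
        {
            "subject_id": [c.subject_id for c in clips],
            "x": coords[:, 0],
            "y": coords[:, 1],
        }
    )
    return EmbeddingResult(points=points, perplexity=float(perplexity), seed=int(seed))


def export_roi_table(
    roi_map: OcclusionMap | ActivationMap,
    atlas: RoiAtlas,
    path,
) -> pd.DataFrame:
    """Write a per-ROI value table for external (surface) renderers.

    Rows carry the atlas geometry; an :class:`OcclusionMap` contributes
    a single ``value`` column (the normalized contribution), an
    :class:`ActivationMap` one ``value_<filter>`` column per filter.
    """
    geom = atlas.to_dataframe()[["roi_id", "x_mm", "y_mm", "z_mm", "network_label"]]
    if isinstance(roi_map, OcclusionMap):
        if len(roi_map.table) != len(atlas):
            raise ValidationError("occlusion map size does not match the atlas")
        out = geom.copy()
        out["value"] = roi_map.values
    else:
        if roi_map.values.shape[1] != len(atlas):
            raise ValidationError("activation map size does not match the atlas")
        out = geom.copy()
        for f in range(roi_map.values.shape[0]):
            out[f"value_{f}"] = roi_map.values[f]
    out.to_csv(path, sep="\t", index=False)
    return out


def network_summary(occlusion: OcclusionMap, atlas: RoiAtlas) -> pd.DataFrame:
    """Mean normalized contribution per atlas network label."""
    if len(occlusion.table) != len(atlas):
        raise ValidationError("occlusion map size does not match the atlas")
    df = occlusion.table.copy()
    df["network_label"] = atlas.network_labels
    return (
        df.groupby("network_label")["normalized_contribution"]
        .mean()
        .reset_index()
        .rename(columns={"normalized_contribution": "mean_contribution"})
    )
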