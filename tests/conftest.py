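"""Shared fixtures: toy atlases, a small simulated cohort, a trained model."""

import numpy as np
import pandas as pd
import pytest

import connprint as cp


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_atlas_frame(n_rois: int, diameter: float = 10.0) -> pd.DataFrame:
    """Atlas table with centers spread on a coarse 3-D grid (MNI mm)."""
    rows = []
    for i in range(n_rois):
        rows.append(
            {
                "roi_id": i + 1,
                "x_mm": float((i % 4) * 20 - 30),
                "y_mm": float(((i // 4) % 4) * 20 - 30),
                "z_mm": float((i // 16) * 20 - 10),
                "diameter_mm": diameter,
                "network_label": f"net{i % 3}",
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_atlas_file(tmp_path):
    path = tmp_path / "atlas.tsv"
    make_atlas_frame(3).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def toy_atlas(toy_atlas_file):
    return cp.load_atlas(toy_atlas_file)


def atlas_of_size(n_rois: int) -> cp.RoiAtlas:
    df = make_atlas_frame(n_rois)
    return cp.RoiAtlas(
        rois=tuple(
            cp.atlas_io.RoiRecord(
                roi_id=int(r.roi_id),
                x_mm=r.x_mm,
                y_mm=r.y_mm,
                z_mm=r.z_mm,
                diameter_mm=r.diameter_mm,
                network_label=r.network_label,
                order_index=i,
            )
            for i, r in enumerate(df.itertuples(index=False))
        )
    )


# --- small end-to-end cohort, shared across test modules ------------------

TINY = dict(
    n_subjects=6,
    n_sessions=3,
    frames_per_session=360,
    n_rois=24,
    latent_dim=4,
    seed=11,
)
TINY_WINDOW = 60


@pytest.fixture(scope="session")
def tiny_spec():
    return cp.CohortSpec(**TINY)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return cp.simulate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_split(tiny_cohort):
    return cp.build_split(tiny_cohort, window=TINY_WINDOW)


@pytest.fixture(scope="session")
def tiny_model_config():
    return cp.ModelConfig(
        n_rois=TINY["n_rois"], n_classes=TINY["n_subjects"], layer_filters=(4, 8),
        recurrent_l2=1e-4,
    )


@pytest.fixture(scope="session")
def tiny_trained(tiny_split, tiny_model_config):
    """A ConvRNN trained on the small cohort, with its history."""
    model = cp.ConvRnnModel(
        config=tiny_model_config,
        weights=cp.initialize_weights(tiny_model_config, seed=3),
    )
    cfg = cp.TrainingConfig(
        batch_size=8, max_epochs=80, lr_patience=8, early_stop_patience=25, seed=3,
        verbose=False,
    )
    best, history = cp.train(model, tiny_split, cfg, log=None)
    return best, history


@pytest.fixture(scope="session")
def tiny_model(tiny_trained):
    return tiny_trained[0]
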