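"""Shared fixtures: small simulated experiments and a trained smoke model.

Everything is generated at run time from seeds; session scope keeps the
expensive pieces (rendering, training) to one execution per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from pathscore.dataio import Dataset, SplitSpec, split_by_plate
from pathscore.model import ModelSpec
from pathscore.simdata import DesignItem, SimParams, generate_experiment
from pathscore.training import TrainConfig, train

# small-field parameters used across tests: same per-area cell density as
# the full-scale defaults, shrunk radii so fields are not wall-to-wall
SMALL_PARAMS = SimParams(
    fov_size=128, mean_cells=55, sd_cells=8, nucleus_radius_range=(4.0, 7.0)
)

SMOKE_SPEC = ModelSpec(
    scales=(128, 64), patch=64, filters=(4, 8, 16, 32), fc_widths=(32, 32),
    dropout=0.1,
)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SMALL_PARAMS


@pytest.fixture(scope="session")
def smoke_experiment(tmp_path_factory):
    """40 small wells: 20 WT-like (alpha=0.05) vs 20 activating (alpha=0.9)."""
    out = tmp_path_factory.mktemp("smoke_exp")
    design = [
        DesignItem("KRAS", "WT", "WT", 20, 0.05),
        DesignItem("KRAS", "G12V", "activating", 20, 0.9),
    ]
    manifest = generate_experiment(design, SMALL_PARAMS, out, seed=7, plate_size=8)
    return Dataset(manifest, out)


@pytest.fixture(scope="session")
def smoke_splits(smoke_experiment):
    return split_by_plate(smoke_experiment, SplitSpec((0.6, 0.2, 0.2), seed=1))


@pytest.fixture(scope="session")
def smoke_model(smoke_splits):
    """A quickly trained small model that separates the smoke experiment."""
    train_ds, val_ds, _ = smoke_splits
    config = TrainConfig(batch_size=8, learning_rate=1e-3, max_epochs=35,
                         early_stop_patience=35, seed=0)
    net, history = train(SMOKE_SPEC, train_ds, val_ds, config)
    return net, history


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
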