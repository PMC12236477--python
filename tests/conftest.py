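import numpy as np
import pandas as pd
import pytest

from reverie import (
    SceneTable,
    SimConfig,
    generate,
    scene_table_from_songs,
)
from reverie.annotations import compact_scene_table


@pytest.fixture(scope="session")
def tiny_scenes() -> SceneTable:
    """6 scenes, 2 repeated songs: A at 1, 4, 6; B at 2, 5; scene 3 silent."""
    return scene_table_from_songs(["A", "B", None, "A", "B", "A"])


@pytest.fixture(scope="session")
def tiny_dataset(tiny_scenes):
    """Noise-free 3-per-group instance with encoding variation (so the
    permutation null is non-degenerate) and planted reactivation."""
    config = SimConfig(
        n_participants=3,
        n_parcels=2,
        voxels_per_parcel=12,
        scene_table=tiny_scenes,
        noise_sd=0.0,
        encoding_sd=0.5,
        react_gain=0.95,
        seed=7,
    )
    return generate(config)


@pytest.fixture(scope="session")
def small_dataset():
    """24-per-group dataset on the compact 3-song scene table."""
    config = SimConfig(
        n_participants=24,
        n_parcels=6,
        voxels_per_parcel=24,
        scene_table=compact_scene_table(),
        react_gain=0.95,
        seed=11,
    )
    return generate(config)


@pytest.fixture()
def simple_scores() -> pd.DataFrame:
    """Hand-built scene-level scores for two participants, one parcel."""
    rows = []
    for pid, values in (("p1", [1.0, 2.0, 0.0]), ("p2", [0.5, 1.5, -0.5])):
        for sid, z in zip((1, 2, 3), values):
            rows.append(
                {"participant_id": pid, "parcel_id": 0, "scene_id": sid, "z": z}
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def simple_recall() -> pd.DataFrame:
    rows = []
    for pid in ("p1", "p2"):
        for sid, rem in zip((1, 2, 3), (True, True, False)):
            rows.append(
                {"participant_id": pid, "scene_id": sid, "remembered": rem}
            )
    return pd.DataFrame(rows)
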