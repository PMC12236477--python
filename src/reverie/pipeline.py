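"""High-level pipeline entry points over stacked group arrays.

These functions run the per-parcel scoring across a whole dataset: extract
scene patterns over the repeated-music scene pool, score reactivation for
the music group (cross-group) or the no-music group (within-group,
held-out), and compute leave-one-out spatial ISC per parcel.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import SceneTable, build_megascenes
from .isc import spatial_isc
from .patterns import scene_patterns_tensor
from .reactivation import aggregate_pair_scores, enumerate_pairs, score_parcel

__all__ = [
    "pool_patterns",
    "music_reactivation",
    "nomusic_reactivation",
    "isc_scores",
]


def pool_patterns(
    data: np.ndarray,
    scenes: SceneTable,
    tr_s: float,
    lag_s: float = 0.0,
    scene_ids: Sequence[int] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Scene patterns over the repeated-music scene pool.

    ``data`` is (P, K, V, T); returns ``(patterns, pool_scene_ids)`` with
    patterns of shape (P, K, n_pool, V).
    """
    pool = (
        list(scene_ids)
        if scene_ids is not None
        else scenes.repeated_music_scene_ids()
    )
    pats = scene_patterns_tensor(data, scenes, pool, tr_s, lag_s)
    return pats, pool


def _score_all_parcels(
    subject_pats: np.ndarray,
    comparison_pats: np.ndarray,
    pool: list[int],
    scenes: SceneTable,
    n_perm: int,
    seed: int,
    subject_ids: Sequence[str],
    within_group: bool,
    parcel_ids: Sequence[int] | None,
) -> pd.DataFrame:
    megas = build_megascenes(scenes)
    pairs = enumerate_pairs(scenes, megas)
    n_parcels = subject_pats.shape[1]
    if parcel_ids is None:
        parcel_ids = list(range(n_parcels))
    frames = []
    for k in range(n_parcels):
        pair_scores = score_parcel(
            subject_pats[:, k],
            comparison_pats[:, k],
            pool,
            megas,
            pairs,
            n_perm=n_perm,
            seed=seed,
            parcel_index=k,
            parcel_id=int(parcel_ids[k]),
            subject_ids=subject_ids,
            within_group=within_group,
        )
        frames.append(aggregate_pair_scores(pair_scores))
    return pd.concat(frames, ignore_index=True)


def music_reactivation(
    data_music: np.ndarray,
    data_nomusic: np.ndarray,
    scenes: SceneTable,
    tr_s: float,
    n_perm: int = 1000,
    seed: int = 0,
    lag_s: float = 0.0,
    music_ids: Sequence[str] | None = None,
    parcel_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Scene-level reactivation scores for every music participant and parcel.

    Music participants' later mega-scene patterns are compared to the
    no-music group's average earlier-scene patterns (so shared music cannot
    drive the similarity), baseline-corrected within the no-music group,
    and z-scored against the permutation null.
    """
    pats_m, pool = pool_patterns(data_music, scenes, tr_s, lag_s)
    pats_n, _ = pool_patterns(data_nomusic, scenes, tr_s, lag_s)
    if music_ids is None:
        music_ids = [f"music-{i:02d}" for i in range(pats_m.shape[0])]
    return _score_all_parcels(
        pats_m, pats_n, pool, scenes, n_perm, seed, music_ids, False, parcel_ids
    )


def nomusic_reactivation(
    data_nomusic: np.ndarray,
    scenes: SceneTable,
    tr_s: float,
    n_perm: int = 1000,
    seed: int = 0,
    lag_s: float = 0.0,
    nomusic_ids: Sequence[str] | None = None,
    parcel_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Within-group control reactivation scores for the no-music group.

    Each held-out no-music participant plays the subject role against the
    remaining no-music participants; the held-out participant is excluded
    from both the comparison average and the baseline computation.
    """
    pats_n, pool = pool_patterns(data_nomusic, scenes, tr_s, lag_s)
    if nomusic_ids is None:
        nomusic_ids = [f"nomusic-{i:02d}" for i in range(pats_n.shape[0])]
    return _score_all_parcels(
        pats_n, pats_n, pool, scenes, n_perm, seed, nomusic_ids, True, parcel_ids
    )


def isc_scores(
    data: np.ndarray,
    scenes: SceneTable,
    tr_s: float,
    lag_s: float = 0.0,
    participant_ids: Sequence[str] | None = None,
    parcel_ids: Sequence[int] | None = None,
    scene_ids: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Within-condition leave-one-out spatial ISC for every parcel."""
    pats, pool = pool_patterns(data, scenes, tr_s, lag_s, scene_ids)
    if participant_ids is None:
        participant_ids = [f"sub-{i:02d}" for i in range(pats.shape[0])]
    n_parcels = pats.shape[1]
    if parcel_ids is None:
        parcel_ids = list(range(n_parcels))
    frames = [
        spatial_isc(pats[:, k], participant_ids, pool, parcel_id=int(parcel_ids[k]))
        for k in range(n_parcels)
    ]
    return pd.concat(frames, ignore_index=True)
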