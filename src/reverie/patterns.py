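"""Time-averaged spatial patterns per scene, mega-scene and group.

A participant's data for one parcel is a voxels x TRs matrix.  A scene's
pattern is the per-voxel mean over the TRs whose onset falls inside the
(optionally lag-shifted) scene interval, using the half-open convention
``[start_s + lag_s, end_s + lag_s)``.  Mega-scene patterns are unweighted
means of their member scenes' patterns (scene-wise, not TR-duration
weighted), and group-average patterns are voxelwise means over participants
with optional leave-one-out exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import MegaScene, SceneTable

__all__ = [
    "ParcelSeries",
    "ScenePattern",
    "scene_tr_indices",
    "scene_pattern",
    "megascene_pattern",
    "group_average",
    "scene_patterns_tensor",
]

logger = logging.getLogger(__name__)


@dataclass
class ParcelSeries:
    """One participant's voxels x TRs matrix for a single parcel."""

    participant_id: str
    group: str  # "music" | "nomusic"
    parcel_id: int
    data: np.ndarray  # (voxels, n_tr)
    tr_s: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ParcelSeries data must be voxels x TRs")
        if not np.isfinite(self.data).all():
            raise ValueError(
                f"non-finite values in series {self.participant_id}/parcel "
                f"{self.parcel_id}"
            )
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")


@dataclass
class ScenePattern:
    """A per-voxel mean pattern for one scene or mega-scene."""

    participant_id: str
    parcel_id: int
    scene_id: int | None
    values: np.ndarray
    excluded_participant: str | None = None


def scene_tr_indices(
    start_s: float, end_s: float, tr_s: float, n_tr: int, lag_s: float = 0.0
) -> np.ndarray:
    """TR indices whose onset lies in the shifted half-open scene interval."""
    onsets = np.arange(n_tr) * tr_s
    mask = (onsets >= start_s + lag_s) & (onsets < end_s + lag_s)
    return np.nonzero(mask)[0]


def scene_pattern(
    series: ParcelSeries, scene_row: pd.Series, lag_s: float = 0.0
) -> ScenePattern:
    """Per-voxel mean over the TRs belonging to one scene."""
    idx = scene_tr_indices(
        float(scene_row["start_s"]),
        float(scene_row["end_s"]),
        series.tr_s,
        series.data.shape[1],
        lag_s,
    )
    if idx.size == 0:
        raise ValueError(
            f"scene {int(scene_row['scene_id'])} has no TRs after lag shift "
            f"for participant {series.participant_id}"
        )
    return ScenePattern(
        series.participant_id,
        series.parcel_id,
        int(scene_row["scene_id"]),
        series.data[:, idx].mean(axis=1),
    )


def megascene_pattern(
    series: ParcelSeries,
    mega: MegaScene,
    scenes: SceneTable,
    lag_s: float = 0.0,
) -> ScenePattern:
    """Unweighted mean of the member scenes' patterns."""
    member_patterns = [
        scene_pattern(series, scenes.row(sid), lag_s).values
        for sid in mega.member_scene_ids
    ]
    return ScenePattern(
        series.participant_id,
        series.parcel_id,
        None,
        np.mean(member_patterns, axis=0),
    )


def group_average(
    patterns: list[ScenePattern], exclude_participant: str | None = None
) -> ScenePattern:
    """Voxelwise mean pattern over participants, optionally leave-one-out."""
    if exclude_participant is not None:
        kept = [p for p in patterns if p.participant_id != exclude_participant]
        if len(kept) == len(patterns):
            logger.warning(
                "exclude_participant %r not present; averaging over all %d",
                exclude_participant,
                len(patterns),
            )
        patterns = kept
        if len(patterns) == 0:
            raise ValueError("exclusion left no patterns to average")
    if len(patterns) == 0:
        raise ValueError("no patterns to average")
    values = np.mean([p.values for p in patterns], axis=0)
    first = patterns[0]
    return ScenePattern(
        "group-average",
        first.parcel_id,
        first.scene_id,
        values,
        excluded_participant=exclude_participant,
    )


def scene_patterns_tensor(
    data: np.ndarray,
    scenes: SceneTable,
    scene_ids: list[int] | np.ndarray,
    tr_s: float,
    lag_s: float = 0.0,
) -> np.ndarray:
    """Vectorized scene patterns for stacked series.

    ``data`` has shape ``(..., voxels, n_tr)``; returns an array of shape
    ``(..., n_scenes, voxels)`` of per-scene time-averaged patterns, in the
    order of ``scene_ids``.
    """
    data = np.asarray(data, dtype=float)
    n_tr = data.shape[-1]
    out = np.empty(data.shape[:-2] + (len(scene_ids), data.shape[-2]))
    for j, sid in enumerate(scene_ids):
        row = scenes.row(int(sid))
        idx = scene_tr_indices(
            float(row["start_s"]), float(row["end_s"]), tr_s, n_tr, lag_s
        )
        if idx.size == 0:
            raise ValueError(f"scene {int(sid)} has no TRs after lag shift")
        out[..., j, :] = data[..., :, idx].mean(axis=-1)
    return out
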