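"""Stimulus annotations: scene boundaries, songs, mega-scenes, recall labels.

The temporal backbone of the analysis is a table of non-overlapping movie
scenes, each an interval ``[start_s, end_s)`` with an optional song label.
Songs whose occurrences form two or more separate blocks of consecutive
scenes are *repeated songs*; only scenes carrying a repeated song enter the
reactivation analysis.  Runs of consecutive scenes sharing one song are
collapsed into *mega-scenes* whose patterns are later averaged.

Scene boundaries themselves come from human raters: a pool of raters marks
event boundaries, the pooled boundary density is smoothed with a Gaussian
kernel, and consensus boundaries are the strong local maxima of that
density.  A primary rater's finer segmentation is then reconciled against
the consensus: primary boundaries with no consensus support are dropped and
their flanking scenes merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "SceneTable",
    "RaterBoundaries",
    "MegaScene",
    "consensus_boundaries",
    "merge_scenes_to_consensus",
    "build_megascenes",
    "label_recall",
    "canonical_scene_table",
    "scene_table_from_songs",
    "compact_scene_table",
]

SCENE_COLUMNS = ["scene_id", "start_s", "end_s", "song_id"]


class SceneTable:
    """Ordered, non-overlapping scene intervals with optional song labels.

    Wraps a :class:`pandas.DataFrame` with columns ``scene_id`` (1-based,
    increasing with time), ``start_s``, ``end_s`` (seconds, half-open
    interval) and ``song_id`` (string or None for scenes without music).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy().reset_index(drop=True)
        missing = set(SCENE_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"scene table missing columns: {sorted(missing)}")
        frame = frame[SCENE_COLUMNS]
        frame["scene_id"] = frame["scene_id"].astype(int)
        frame["song_id"] = frame["song_id"].astype(object).where(
            frame["song_id"].notna() & (frame["song_id"] != ""), None
        )
        self._validate(frame)
        self.frame = frame

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        if len(frame) == 0:
            raise ValueError("scene table is empty")
        if not np.isfinite(frame[["start_s", "end_s"]].to_numpy()).all():
            raise ValueError("non-finite scene boundaries")
        if (frame["start_s"] >= frame["end_s"]).any():
            bad = frame.loc[frame["start_s"] >= frame["end_s"], "scene_id"].tolist()
            raise ValueError(f"scenes with start_s >= end_s: {bad}")
        ids = frame["scene_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate scene ids")
        order = np.argsort(frame["start_s"].to_numpy(), kind="stable")
        if not np.array_equal(ids[order], np.sort(ids)):
            raise ValueError("scene_id order must equal temporal order")
        starts = frame["start_s"].to_numpy()[order]
        ends = frame["end_s"].to_numpy()[order]
        if (starts[1:] < ends[:-1] - 1e-9).any():
            raise ValueError("scenes overlap")

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:  # pragma: no cover
        n_song = int(self.frame["song_id"].notna().sum())
        return f"SceneTable({len(self)} scenes, {n_song} with music)"

    @property
    def scene_ids(self) -> np.ndarray:
        return self.frame["scene_id"].to_numpy()

    def row(self, scene_id: int) -> pd.Series:
        sel = self.frame[self.frame["scene_id"] == scene_id]
        if len(sel) == 0:
            raise KeyError(f"unknown scene_id {scene_id}")
        return sel.iloc[0]

    @property
    def duration_s(self) -> float:
        return float(self.frame["end_s"].max())

    def song_blocks(self) -> list[tuple[str, list[int]]]:
        """Maximal runs of consecutive scenes sharing one song, in time order."""
        blocks: list[tuple[str, list[int]]] = []
        current_song = None
        current: list[int] = []
        prev_id = None
        for _, r in self.frame.iterrows():
            song = r["song_id"]
            contiguous = prev_id is not None and r["scene_id"] == prev_id + 1
            if song is not None and song == current_song and contiguous:
                current.append(int(r["scene_id"]))
            else:
                if current:
                    blocks.append((current_song, current))
                current_song, current = song, ([int(r["scene_id"])] if song else [])
                if song is None:
                    current_song = None
            prev_id = int(r["scene_id"])
        if current:
            blocks.append((current_song, current))
        return blocks

    def repeated_songs(self) -> list[str]:
        """Songs with >= 2 occurrence blocks, in order of first occurrence."""
        counts: dict[str, int] = {}
        order: list[str] = []
        for song, _ in self.song_blocks():
            if song not in counts:
                counts[song] = 0
                order.append(song)
            counts[song] += 1
        return [s for s in order if counts[s] >= 2]

    def repeated_music_scene_ids(self) -> list[int]:
        """Scene ids carrying a repeated song, ascending."""
        repeated = set(self.repeated_songs())
        ids = self.frame.loc[
            self.frame["song_id"].isin(repeated), "scene_id"
        ].astype(int)
        return sorted(ids.tolist())

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["song_id"] = out["song_id"].fillna("")
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SceneTable":
        frame = pd.read_csv(path, sep="\t", dtype={"song_id": "object"})
        return cls(frame)


@dataclass(frozen=True)
class RaterBoundaries:
    """One rater's event-boundary timestamps (seconds, unordered)."""

    rater_id: str
    times_s: tuple[float, ...]

    def __post_init__(self):
        times = np.asarray(self.times_s, dtype=float)
        if times.size and not np.isfinite(times).all():
            raise ValueError(f"rater {self.rater_id}: non-finite boundary times")
        if times.size and (times < 0).any():
            raise ValueError(f"rater {self.rater_id}: negative boundary times")
        object.__setattr__(self, "times_s", tuple(float(t) for t in times))


@dataclass(frozen=True)
class MegaScene:
    """A maximal run of consecutive scenes sharing one song."""

    mega_id: int
    song_id: str
    member_scene_ids: tuple[int, ...]

    @property
    def start_index(self) -> int:
        return min(self.member_scene_ids)


def consensus_boundaries(
    raters: Sequence[RaterBoundaries],
    sigma_s: float = 3.0,
    percentile: float = 90.0,
    grid_step_s: float = 0.1,
    duration_s: float | None = None,
) -> np.ndarray:
    """Consensus event boundaries from a pool of raters.

    All boundary times are pooled, each contributes a unit-mass Gaussian of
    width ``sigma_s``, and the resulting density is evaluated on a regular
    grid.  Local maxima of the density are candidate boundaries; those whose
    height reaches the given percentile of the candidate-peak heights are
    kept.  Returns the kept peak times, ascending.
    """
    if len(raters) == 0:
        raise ValueError("need at least one rater")
    if sigma_s <= 0:
        raise ValueError("sigma_s must be positive")
    if not 0 < percentile < 100:
        raise ValueError("percentile must lie in (0, 100)")
    if grid_step_s <= 0:
        raise ValueError("grid_step_s must be positive")
    times = np.concatenate([np.asarray(r.times_s, dtype=float) for r in raters]) \
        if any(len(r.times_s) for r in raters) else np.empty(0)
    if times.size == 0:
        return np.empty(0)
    if not np.isfinite(times).all():
        raise ValueError("non-finite boundary times")
    hi = duration_s if duration_s is not None else times.max() + 4 * sigma_s
    grid = np.arange(0.0, hi + grid_step_s, grid_step_s)
    # pooled density: sum of unit-mass Gaussians (pooling before vs after
    # smoothing is equivalent for sums of Gaussians)
    dev = grid[:, None] - times[None, :]
    density = np.exp(-0.5 * (dev / sigma_s) ** 2).sum(axis=1)
    density /= sigma_s * np.sqrt(2 * np.pi)
    peaks, _ = find_peaks(density)
    if peaks.size == 0:
        return np.empty(0)
    heights = density[peaks]
    threshold = np.percentile(heights, percentile)
    keep = peaks[heights >= threshold]
    return grid[keep]


def merge_scenes_to_consensus(
    scenes: SceneTable,
    consensus_times: Iterable[float],
    snap_tolerance_s: float = 3.0,
) -> SceneTable:
    """Reconcile a primary rater's scenes with consensus boundaries.

    An internal scene boundary is kept iff a consensus boundary lies within
    ``snap_tolerance_s`` of it; otherwise the two flanking scenes merge (so
    two primary scenes falling inside one longer consensus scene become a
    single scene).  Merged scenes keep their shared song label, or None if
    the members disagree.  Scene ids are renumbered 1-based.
    """
    consensus = np.sort(np.asarray(list(consensus_times), dtype=float))
    frame = scenes.frame
    rows: list[dict] = []
    current = dict(frame.iloc[0])
    for _, nxt in frame.iloc[1:].iterrows():
        boundary = current["end_s"]
        supported = consensus.size > 0 and np.min(
            np.abs(consensus - boundary)
        ) <= snap_tolerance_s
        if supported:
            rows.append(current)
            current = dict(nxt)
        else:
            song = current["song_id"] if current["song_id"] == nxt["song_id"] else None
            current = {
                "scene_id": current["scene_id"],
                "start_s": current["start_s"],
                "end_s": nxt["end_s"],
                "song_id": song,
            }
    rows.append(current)
    merged = pd.DataFrame(rows)
    merged["scene_id"] = np.arange(1, len(merged) + 1)
    return SceneTable(merged)


def build_megascenes(scenes: SceneTable) -> list[MegaScene]:
    """Collapse runs of consecutive same-song scenes into mega-scenes.

    Only scenes carrying a *repeated* song (>= 2 occurrence blocks) are
    included; the mega-scenes partition the repeated-music scenes.
    """
    repeated = set(scenes.repeated_songs())
    megas = []
    mega_id = 1
    for song, members in scenes.song_blocks():
        if song in repeated:
            megas.append(MegaScene(mega_id, song, tuple(members)))
            mega_id += 1
    return megas


def label_recall(
    utterance_labels: Iterable[tuple[str, str, Sequence[int]]],
    scenes: SceneTable,
    participants: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build a recall table from utterance -> scene-label records.

    ``utterance_labels`` yields ``(participant_id, utterance_id, scene_ids)``
    records; an utterance may carry several scene labels.  A scene counts as
    remembered by a participant iff at least one of their utterances is
    labeled with it; every other scene is forgotten.  Returns a long table
    with one row per (participant, scene).
    """
    known = set(int(s) for s in scenes.scene_ids)
    remembered: dict[str, set[int]] = {}
    for participant, _utt, ids in utterance_labels:
        for sid in ids:
            sid = int(sid)
            if sid not in known:
                raise ValueError(f"unknown scene_id {sid} in utterance labels")
            remembered.setdefault(participant, set()).add(sid)
    if participants is None:
        participants = sorted(remembered)
    rows = []
    for participant in participants:
        got = remembered.get(participant, set())
        for sid in scenes.scene_ids:
            rows.append(
                {
                    "participant_id": participant,
                    "scene_id": int(sid),
                    "remembered": bool(int(sid) in got),
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "scene_id", "remembered"])


# ---------------------------------------------------------------------------
# Bundled annotation fixtures
# ---------------------------------------------------------------------------

# Occurrence-block sizes of the six repeated songs in the canonical fixture:
# per-song scene counts {4, 10, 12, 18, 22, 27} (min 4, max 27, mean 15.5),
# 93 repeated-music scenes in 12 blocks, 67 strictly-earlier cue pairs, and
# the "Phone Call" second block spanning scenes 111-115.
_CANONICAL_BLOCKS: list[tuple[str, int, int]] = [
    # (song, first scene id, block length)
    ("Phone Call", 10, 22),
    ("Row", 35, 20),
    ("Lacuna", 58, 15),
    ("Montauk", 76, 7),
    ("Bookstore", 86, 2),
    ("EGL", 90, 1),
    ("Phone Call", 111, 5),
    ("EGL", 130, 3),
    ("Bookstore", 150, 8),
    ("Montauk", 170, 5),
    ("Lacuna", 200, 3),
    ("Row", 230, 2),
]

_CANONICAL_N_SCENES = 407
_CANONICAL_DURATIONS = (12.0, 14.0, 16.0, 18.0, 20.0)  # cycled; mean 16 s


def canonical_scene_table() -> SceneTable:
    """The bundled movie-scale annotation fixture.

    407 scenes; 6 repeated songs covering 93 scenes in 12 occurrence blocks
    (per-song counts 4/10/12/18/22/27, mean 15.5 scenes per song), yielding
    67 strictly-earlier cue pairs.  The "Phone Call" song repeats across
    scenes 111-115 with its earlier occurrences all before scene 111.
    """
    song_of: dict[int, str] = {}
    for song, start, length in _CANONICAL_BLOCKS:
        for sid in range(start, start + length):
            song_of[sid] = song
    rows = []
    t = 0.0
    for sid in range(1, _CANONICAL_N_SCENES + 1):
        dur = _CANONICAL_DURATIONS[(sid - 1) % len(_CANONICAL_DURATIONS)]
        rows.append(
            {
                "scene_id": sid,
                "start_s": t,
                "end_s": t + dur,
                "song_id": song_of.get(sid),
            }
        )
        t += dur
    return SceneTable(pd.DataFrame(rows))


def scene_table_from_songs(
    labels: Sequence[str | None], scene_duration_s: float = 4.5
) -> SceneTable:
    """Small scene table from an explicit per-scene song-label sequence."""
    rows = [
        {
            "scene_id": i + 1,
            "start_s": i * scene_duration_s,
            "end_s": (i + 1) * scene_duration_s,
            "song_id": lab,
        }
        for i, lab in enumerate(labels)
    ]
    return SceneTable(pd.DataFrame(rows))


def compact_scene_table(
    block_sizes: Mapping[str, Sequence[int]] | None = None,
    scene_duration_s: float = 4.5,
) -> SceneTable:
    """Scaled-down scene table for simulations.

    Defaults to 3 songs with two 4-scene occurrence blocks each (24 music
    scenes, 12 strictly-earlier cue pairs), interleaved with single no-music
    separator scenes.
    """
    if block_sizes is None:
        block_sizes = {"A": (4, 4), "B": (4, 4), "C": (4, 4)}
    n_rounds = max(len(v) for v in block_sizes.values())
    labels: list[str | None] = []
    for r in range(n_rounds):
        for song, sizes in block_sizes.items():
            if r < len(sizes):
                labels.extend([song] * int(sizes[r]))
                labels.append(None)
    if labels and labels[-1] is None:
        labels.pop()
    return scene_table_from_songs(labels, scene_duration_s)
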