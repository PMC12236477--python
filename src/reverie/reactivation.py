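"""Reactivation scoring: raw, baseline-corrected, and permutation-z scores.

The central measurement: how strongly does a later scene that repeats a
song reinstate the neural pattern of an *earlier* scene that carried the
same song?  For each cue pair (a later mega-scene and a strictly-earlier
same-song scene) we compute

* the **raw score** -- the Pearson correlation (across voxels) between the
  subject participant's mega-scene pattern and the comparison group's
  average pattern for the earlier scene;
* the **baseline score** -- the same quantity computed within the
  comparison group with a leave-one-out average, capturing ordinary
  between-scene similarity that has nothing to do with the cue;
* the **contrast** = raw - baseline; and
* the **reactivation score** -- the contrast z-scored against a
  permutation null in which the earlier-scene identity of every pair is
  shuffled among the repeated-music scene pool, with the same shuffle
  applied inside the raw and the baseline term so the null is coherent.

In the main analysis the subject group is the music group and the
comparison group is the no-music group, so any shared pattern cannot be
driven by hearing the same music.  In the within-group control the subject
is a held-out no-music participant and the comparison group is the
remaining no-music participants, with the held-out participant excluded
from both the comparison average and the baseline computation.

Pair-level z-scores are aggregated per earlier scene (unweighted mean over
the megas that cue it) into one reactivation score per
(participant, parcel, earlier scene).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import MegaScene, SceneTable

__all__ = [
    "CuePair",
    "enumerate_pairs",
    "pearson",
    "raw_pair_correlations",
    "baseline_pair_correlations",
    "score_parcel",
    "aggregate_pair_scores",
    "permutation_rng",
]

MIN_PERMUTATIONS = 100

PAIR_COLUMNS = [
    "participant_id",
    "parcel_id",
    "mega_id",
    "scene_id",
    "raw",
    "baseline",
    "contrast",
    "z",
]


@dataclass(frozen=True)
class CuePair:
    """A later mega-scene paired with a strictly-earlier same-song scene."""

    mega_id: int
    earlier_scene_id: int
    song_id: str


def enumerate_pairs(scenes: SceneTable, megas: Sequence[MegaScene]) -> list[CuePair]:
    """All (mega, earlier same-song scene) pairs under the strictly-earlier rule.

    The earlier scene must precede -- and therefore not belong to -- the
    mega-scene: ``earlier_scene_id < min(member ids)``.  Deterministic order
    (by mega, then scene).
    """
    frame = scenes.frame
    pairs: list[CuePair] = []
    for mega in sorted(megas, key=lambda m: m.mega_id):
        earlier = frame.loc[
            (frame["song_id"] == mega.song_id)
            & (frame["scene_id"] < mega.start_index),
            "scene_id",
        ]
        for sid in sorted(int(s) for s in earlier):
            pairs.append(CuePair(mega.mega_id, sid, mega.song_id))
    return pairs


def pearson(x: np.ndarray, y: np.ndarray, context: str = "") -> float:
    """Pearson correlation across voxels, erroring on zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise ValueError(f"zero-variance pattern{': ' + context if context else ''}")
    return float(xc @ yc / (nx * ny))


def _normalize_rows(mat: np.ndarray, context: str) -> np.ndarray:
    """Center and unit-normalize each row so dot products are correlations."""
    centered = mat - mat.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(centered, axis=-1, keepdims=True)
    bad = np.nonzero(norms[..., 0] == 0)
    if len(bad[0]):
        raise ValueError(f"zero-variance pattern in {context} (index {bad[0][0]})")
    return centered / norms


def _mega_matrix(
    scene_patterns: np.ndarray, megas: Sequence[MegaScene], pool_index: dict[int, int]
) -> np.ndarray:
    """Mega-scene patterns (n_mega, V) as unweighted means of member scenes."""
    rows = []
    for mega in megas:
        idx = [pool_index[sid] for sid in mega.member_scene_ids]
        rows.append(scene_patterns[..., idx, :].mean(axis=-2))
    return np.stack(rows, axis=-2)


def raw_pair_correlations(
    subject_mega: np.ndarray,
    comparison_avg: np.ndarray,
    pair_mega_idx: np.ndarray,
    pair_scene_idx: np.ndarray,
    context: str = "raw",
) -> np.ndarray:
    """Per-pair correlation between subject mega patterns and comparison averages."""
    m_hat = _normalize_rows(subject_mega, context + " subject megas")
    g_hat = _normalize_rows(comparison_avg, context + " comparison averages")
    full = m_hat @ g_hat.T
    return full[pair_mega_idx, pair_scene_idx]


def baseline_pair_correlations(
    comparison_patterns: np.ndarray,
    megas: Sequence[MegaScene],
    pool_index: dict[int, int],
    pair_mega_idx: np.ndarray,
    pair_scene_idx: np.ndarray,
) -> np.ndarray:
    """Leave-one-out baseline similarity, averaged over held-out participants."""
    full = _baseline_matrix(comparison_patterns, megas, pool_index)
    return full[pair_mega_idx, pair_scene_idx]


def _baseline_matrix(
    comparison_patterns: np.ndarray,
    megas: Sequence[MegaScene],
    pool_index: dict[int, int],
    exclude_index: int | None = None,
) -> np.ndarray:
    """Mean over held-out comparison participants of corr(their mega, LOO avg).

    ``comparison_patterns`` has shape (P, n_pool, V).  When ``exclude_index``
    is given, that participant is removed from the comparison set entirely
    (within-group control) before the leave-one-out computation.
    """
    pats = comparison_patterns
    if exclude_index is not None:
        pats = np.delete(pats, exclude_index, axis=0)
    n = pats.shape[0]
    if n < 3:
        raise ValueError(
            "baseline needs >= 3 comparison participants (leave-one-out average "
            f"undefined with {n - 1} remaining)"
        )
    total = pats.sum(axis=0)
    loo_avg = (total[None] - pats) / (n - 1)  # (P, n_pool, V)
    megas_all = _mega_matrix(pats, megas, pool_index)  # (P, n_mega, V)
    m_hat = _normalize_rows(megas_all, "baseline megas")
    g_hat = _normalize_rows(loo_avg, "baseline leave-one-out averages")
    return np.einsum("pmv,psv->ms", m_hat, g_hat) / n


def permutation_rng(seed: int, parcel_index: int, subject_index: int) -> np.random.Generator:
    """Deterministic per-(parcel, participant) permutation substream."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(parcel_index, subject_index))
    return np.random.default_rng(ss)


def _pair_z(
    raw_matrix: np.ndarray,
    base_matrix: np.ndarray,
    pair_mega_idx: np.ndarray,
    pair_scene_idx: np.ndarray,
    n_pool: int,
    rng: np.random.Generator,
    n_perm: int,
) -> tuple[np.ndarray, np.ndarray]:
    """True contrasts and permutation z-scores for one participant/parcel."""
    contrast_matrix = raw_matrix - base_matrix
    true = contrast_matrix[pair_mega_idx, pair_scene_idx]
    perms = rng.permuted(
        np.broadcast_to(np.arange(n_pool), (n_perm, n_pool)), axis=1
    )
    shuffled_scene = perms[:, pair_scene_idx]  # (n_perm, n_pairs)
    null = contrast_matrix[pair_mega_idx[None, :], shuffled_scene]
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    if (null_sd == 0).any():
        raise ValueError("degenerate permutation null (sd = 0)")
    return true, (true - null_mean) / null_sd


def score_parcel(
    subject_patterns: np.ndarray,
    comparison_patterns: np.ndarray,
    pool_scene_ids: Sequence[int],
    megas: Sequence[MegaScene],
    pairs: Sequence[CuePair],
    n_perm: int,
    seed: int,
    parcel_index: int = 0,
    parcel_id: int = 0,
    subject_ids: Sequence[str] | None = None,
    within_group: bool = False,
) -> pd.DataFrame:
    """Pair-level reactivation scores for one parcel.

    ``subject_patterns``: (P_subject, n_pool, V) scene patterns over the
    repeated-music scene pool; ``comparison_patterns``: (P_comparison,
    n_pool, V).  In ``within_group`` mode the two arrays must be the same
    group and each subject is held out of the comparison side.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")
    if len(pairs) == 0:
        raise ValueError("no cue pairs to score")
    subject_patterns = np.asarray(subject_patterns, dtype=float)
    comparison_patterns = np.asarray(comparison_patterns, dtype=float)
    pool_index = {int(s): i for i, s in enumerate(pool_scene_ids)}
    n_pool = len(pool_scene_ids)
    mega_order = {m.mega_id: i for i, m in enumerate(megas)}
    pair_mega_idx = np.array([mega_order[p.mega_id] for p in pairs])
    pair_scene_idx = np.array([pool_index[p.earlier_scene_id] for p in pairs])
    n_subject = subject_patterns.shape[0]
    if subject_ids is None:
        subject_ids = [f"sub-{i:02d}" for i in range(n_subject)]

    subject_megas = _mega_matrix(subject_patterns, megas, pool_index)  # (P, M, V)
    m_hat = _normalize_rows(
        subject_megas, f"subject megas, parcel {parcel_id}"
    )

    if within_group:
        if comparison_patterns.shape[0] < 4:
            raise ValueError(
                "within-group scoring needs >= 4 participants (held-out subject "
                "plus a leave-one-out baseline over the remaining group)"
            )
        total = comparison_patterns.sum(axis=0)
        raw_stack = np.empty((n_subject, len(megas), n_pool))
        base_stack = np.empty_like(raw_stack)
        for p in range(n_subject):
            loo_avg = (total - comparison_patterns[p]) / (
                comparison_patterns.shape[0] - 1
            )
            g_hat = _normalize_rows(loo_avg, "comparison group averages")
            raw_stack[p] = m_hat[p] @ g_hat.T
            base_stack[p] = _baseline_matrix(
                comparison_patterns, megas, pool_index, exclude_index=p
            )
    else:
        group_avg = comparison_patterns.mean(axis=0)
        g_hat = _normalize_rows(group_avg, "comparison group averages")
        raw_stack = np.einsum("pmv,sv->pms", m_hat, g_hat)
        base = _baseline_matrix(comparison_patterns, megas, pool_index)
        base_stack = np.broadcast_to(base, raw_stack.shape)

    n_pairs = len(pairs)
    raw_vals = np.empty((n_subject, n_pairs))
    true_vals = np.empty((n_subject, n_pairs))
    z_vals = np.empty((n_subject, n_pairs))
    for p in range(n_subject):
        rng = permutation_rng(seed, parcel_index, p)
        true, z = _pair_z(
            raw_stack[p], base_stack[p], pair_mega_idx, pair_scene_idx,
            n_pool, rng, n_perm,
        )
        raw_vals[p] = raw_stack[p][pair_mega_idx, pair_scene_idx]
        true_vals[p] = true
        z_vals[p] = z
    return pd.DataFrame(
        {
            "participant_id": np.repeat(list(subject_ids), n_pairs),
            "parcel_id": parcel_id,
            "mega_id": np.tile([p.mega_id for p in pairs], n_subject),
            "scene_id": np.tile([p.earlier_scene_id for p in pairs], n_subject),
            "raw": raw_vals.ravel(),
            "baseline": (raw_vals - true_vals).ravel(),
            "contrast": true_vals.ravel(),
            "z": z_vals.ravel(),
        }
    )


def aggregate_pair_scores(pair_scores: pd.DataFrame) -> pd.DataFrame:
    """Scene-level reactivation scores.

    Pair-level z values are averaged (unweighted) per earlier scene within
    participant and parcel; ``n_pairs`` records how many megas cued the
    scene.
    """
    grouped = pair_scores.groupby(
        ["participant_id", "parcel_id", "scene_id"], as_index=False
    ).agg(
        z=("z", "mean"),
        raw=("raw", "mean"),
        contrast=("contrast", "mean"),
        n_pairs=("z", "size"),
    )
    return grouped
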