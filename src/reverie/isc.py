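"""Spatial intersubject correlation (ISC) as an encoding-strength proxy.

A participant who encodes a scene attentively produces a scene pattern that
resembles the other participants' patterns; spatial ISC -- the correlation
between one participant's time-averaged scene pattern and the average of
the other N-1 participants -- therefore serves as a per-scene proxy of
initial encoding strength.  The module provides

* leave-one-out spatial ISC per (participant, scene, parcel), computed
  within condition;
* an ISC subsequent-memory screen that selects the parcels where ISC
  predicts recall at a liberal threshold; and
* sequential residualization, which removes the selected parcels' ISC from
  reactivation scores one region at a time (each step an OLS fit with
  intercept whose residuals feed the next step), so the surviving
  remembered-vs-forgotten effect cannot be an encoding-strength artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .memory_stats import searchlight_memory

__all__ = [
    "spatial_isc",
    "IscRegionSet",
    "isc_memory_screen",
    "sequential_residualize",
    "residualize_scores",
    "residual_memory",
]

logger = logging.getLogger(__name__)


def spatial_isc(
    scene_patterns: np.ndarray,
    participant_ids: Sequence[str],
    scene_ids: Sequence[int],
    parcel_id: int = 0,
) -> pd.DataFrame:
    """Leave-one-out spatial ISC per (participant, scene) for one parcel.

    ``scene_patterns`` has shape (P, n_scenes, V); each participant's scene
    pattern is correlated with the mean pattern of the other N-1
    participants.  Requires P >= 3 so the N-1 average is a genuine average.
    """
    pats = np.asarray(scene_patterns, dtype=float)
    n = pats.shape[0]
    if n < 3:
        raise ValueError(f"spatial ISC needs >= 3 participants, got {n}")
    total = pats.sum(axis=0)
    rows = []
    for p in range(n):
        loo = (total - pats[p]) / (n - 1)
        a = pats[p] - pats[p].mean(axis=-1, keepdims=True)
        b = loo - loo.mean(axis=-1, keepdims=True)
        na = np.linalg.norm(a, axis=-1)
        nb = np.linalg.norm(b, axis=-1)
        if (na == 0).any() or (nb == 0).any():
            raise ValueError(
                f"zero-variance pattern for participant {participant_ids[p]} "
                f"parcel {parcel_id}"
            )
        r = (a * b).sum(axis=-1) / (na * nb)
        for j, sid in enumerate(scene_ids):
            rows.append((participant_ids[p], parcel_id, int(sid), float(r[j])))
    return pd.DataFrame(rows, columns=["participant_id", "parcel_id", "scene_id", "r"])


@dataclass
class IscRegionSet:
    """Parcels where ISC predicted recall, in deterministic (id) order."""

    parcel_ids: tuple[int, ...]
    p_threshold: float
    effects: pd.DataFrame = field(repr=False, default=None)

    def to_json_dict(self) -> dict:
        return {
            "parcel_ids": list(self.parcel_ids),
            "p_threshold": self.p_threshold,
        }


def isc_memory_screen(
    isc_scores: pd.DataFrame,
    recall: pd.DataFrame,
    p_threshold: float = 0.05,
    test: str = "paired",
) -> IscRegionSet:
    """Select parcels where binned ISC predicts subsequent recall.

    Runs the same remembered-vs-forgotten machinery on ISC values and keeps
    parcels with one-tailed p below the liberal threshold; the full effect
    table (with q-values over all parcels) is retained for corrected
    reports.  Selected ids are ordered ascending.
    """
    effects = searchlight_memory(
        isc_scores, recall, value_col="r", test=test, q_threshold=0.1
    )
    if p_threshold >= 1.0:
        selected = sorted(int(x) for x in effects["parcel_id"])
    else:
        selected = sorted(
            int(x) for x in effects.loc[effects["p"] < p_threshold, "parcel_id"]
        )
    return IscRegionSet(tuple(selected), p_threshold, effects)


def sequential_residualize(
    scores: np.ndarray, predictors: Sequence[np.ndarray]
) -> np.ndarray:
    """Residualize a score vector against predictors one step at a time.

    Each step fits ordinary least squares with intercept of the current
    residuals on one predictor and carries the residuals forward; with zero
    predictors the input is returned unchanged.  Constant predictors are
    skipped with a warning (their slope is undefined).
    """
    resid = np.asarray(scores, dtype=float).copy()
    for k, x in enumerate(predictors):
        x = np.asarray(x, dtype=float)
        if x.shape != resid.shape:
            raise ValueError(
                f"predictor {k} has shape {x.shape}, expected {resid.shape}"
            )
        xc = x - x.mean()
        denom = xc @ xc
        if denom == 0:
            logger.warning("predictor %d is constant; step skipped", k)
            continue
        slope = (xc @ resid) / denom
        intercept = resid.mean() - slope * x.mean()
        resid = resid - (intercept + slope * x)
    return resid


def residualize_scores(
    scores: pd.DataFrame,
    isc_scores: pd.DataFrame,
    region_set: IscRegionSet,
    value_col: str = "z",
) -> pd.DataFrame:
    """Regress selected regions' ISC out of every participant's score vector.

    Within each participant, the per-scene score vector of every target
    parcel is sequentially residualized against the participant's ISC scene
    vectors for the selected regions (ascending parcel-id order).  Returns a
    copy of ``scores`` with ``value_col`` replaced by the final residuals.
    """
    if len(region_set.parcel_ids) == 0:
        return scores.copy()
    # complete-crossing fast path: every participant scores the same scenes
    score_wide = scores.pivot_table(
        index=["participant_id", "scene_id"], columns="parcel_id",
        values=value_col, sort=True,
    )
    isc_wide = isc_scores.pivot_table(
        index=["participant_id", "scene_id"], columns="parcel_id", values="r",
        sort=True,
    )
    try:
        isc_aligned = isc_wide.loc[score_wide.index, list(region_set.parcel_ids)]
    except KeyError as err:
        raise ValueError(f"missing ISC values for residualization: {err}") from None
    if isc_aligned.isna().to_numpy().any() or score_wide.isna().to_numpy().any():
        raise ValueError("missing ISC or score values for residualization")

    participants = score_wide.index.get_level_values("participant_id")
    uniq, inverse = np.unique(participants, return_inverse=True)
    counts = np.bincount(inverse)
    if not (counts == counts[0]).all():
        raise ValueError("participants score different scene sets")
    n_p, n_s = len(uniq), counts[0]
    resid = score_wide.to_numpy(dtype=float).reshape(n_p, n_s, -1)
    predictors = isc_aligned.to_numpy(dtype=float).reshape(n_p, n_s, -1)
    for k in range(predictors.shape[2]):
        x = predictors[:, :, k]  # (P, S)
        xc = x - x.mean(axis=1, keepdims=True)
        denom = (xc**2).sum(axis=1)  # (P,)
        constant = denom == 0
        if constant.any():
            logger.warning(
                "region %s is a constant predictor for %d participants; "
                "step skipped for them",
                region_set.parcel_ids[k],
                int(constant.sum()),
            )
            denom = np.where(constant, 1.0, denom)
        slope = (xc[:, :, None] * resid).sum(axis=1) / denom[:, None]  # (P, T)
        slope[constant] = 0.0
        intercept = resid.mean(axis=1) - slope * x.mean(axis=1)[:, None]
        intercept[constant] = 0.0
        resid = resid - (intercept[:, None, :] + slope[:, None, :] * x[:, :, None])
    flat = pd.DataFrame(
        resid.reshape(n_p * n_s, -1), index=score_wide.index,
        columns=score_wide.columns,
    )
    long = flat.stack().rename(value_col).reset_index()
    out = scores.drop(columns=[value_col]).merge(
        long, on=["participant_id", "scene_id", "parcel_id"], how="left"
    )
    return out[scores.columns]


def residual_memory(
    residual_scores: pd.DataFrame,
    recall: pd.DataFrame,
    correction_parcels: Sequence[int] | None = None,
    q_threshold: float = 0.1,
    value_col: str = "z",
    test: str = "paired",
    pre_effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Remembered-vs-forgotten statistics on residual scores.

    Identical machinery to the pre-regression analysis; when the
    pre-regression effect table is supplied, the output carries ``t_pre``
    for a pre-vs-post comparison.
    """
    effects = searchlight_memory(
        residual_scores,
        recall,
        correction_parcels=correction_parcels,
        q_threshold=q_threshold,
        value_col=value_col,
        test=test,
    )
    if pre_effects is not None:
        effects = effects.merge(
            pre_effects[["parcel_id", "t"]].rename(columns={"t": "t_pre"}),
            on="parcel_id",
            how="left",
        )
    return effects
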