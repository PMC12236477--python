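"""Remembered-vs-forgotten statistics over per-scene scores.

Per participant, scores (reactivation z, ISC r, or residuals) are sorted
into a subsequently-remembered and a subsequently-forgotten bin and
averaged within each bin; the binned means are compared with a one-tailed
t-test (remembered > forgotten), paired by default.  Per-parcel p-values
are corrected with Benjamini-Hochberg FDR within a stated correction set.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bin_scores",
    "remembered_vs_forgotten",
    "fdr",
    "searchlight_memory",
    "roi_memory",
]

logger = logging.getLogger(__name__)

EFFECT_COLUMNS = [
    "parcel_id",
    "t",
    "p",
    "q",
    "n",
    "mean_remembered",
    "mean_forgotten",
    "significant",
    "degenerate",
]


def bin_scores(
    scores: pd.DataFrame,
    recall: pd.DataFrame,
    value_col: str = "z",
) -> pd.DataFrame:
    """Per-participant remembered/forgotten bin means.

    ``scores`` is long-format with participant_id, parcel_id, scene_id and
    ``value_col``; ``recall`` has participant_id, scene_id, remembered.
    Returns one row per (participant, parcel) with ``mean_remembered``,
    ``mean_forgotten``, bin counts, and ``complete`` marking participants
    with both bins non-empty (only those enter paired tests).
    """
    merged = scores.merge(
        recall[["participant_id", "scene_id", "remembered"]],
        on=["participant_id", "scene_id"],
        how="left",
    )
    if merged["remembered"].isna().any():
        bad = merged.loc[merged["remembered"].isna()].iloc[0]
        raise ValueError(
            "missing recall label for participant "
            f"{bad['participant_id']} scene {int(bad['scene_id'])}"
        )
    rows = []
    for (participant, parcel), grp in merged.groupby(
        ["participant_id", "parcel_id"], sort=True
    ):
        rem = grp.loc[grp["remembered"].astype(bool), value_col]
        forg = grp.loc[~grp["remembered"].astype(bool), value_col]
        rows.append(
            {
                "participant_id": participant,
                "parcel_id": parcel,
                "mean_remembered": rem.mean() if len(rem) else np.nan,
                "mean_forgotten": forg.mean() if len(forg) else np.nan,
                "n_remembered": len(rem),
                "n_forgotten": len(forg),
                "complete": bool(len(rem) and len(forg)),
            }
        )
    out = pd.DataFrame(rows)
    n_flagged = int((~out["complete"]).sum())
    if n_flagged:
        logger.warning(
            "%d participant/parcel cells have an empty recall bin and are "
            "excluded from paired testing",
            n_flagged,
        )
    return out


def _one_tailed_paired(diffs: np.ndarray) -> tuple[float, float, bool]:
    """One-tailed paired t on differences vs 0; flags degenerate variance."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.std(ddof=1) == 0:
        if np.allclose(diffs, 0):
            return 0.0, 0.5, True
        return (np.inf if diffs.mean() > 0 else -np.inf), (
            0.0 if diffs.mean() > 0 else 1.0
        ), True
    res = stats.ttest_1samp(diffs, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue), False


def remembered_vs_forgotten(
    binned: pd.DataFrame, test: str = "paired"
) -> tuple[float, float, int, bool]:
    """One-tailed test (remembered > forgotten) over participants.

    Returns ``(t, p, n, degenerate)``.  ``test`` is "paired" (default; the
    binned means are within-participant pairs) or "independent".
    Participants with an empty bin are dropped listwise.
    """
    usable = binned[binned["complete"]]
    n = len(usable)
    if n < 3:
        raise ValueError(f"need >= 3 complete remembered/forgotten pairs, got {n}")
    rem = usable["mean_remembered"].to_numpy(dtype=float)
    forg = usable["mean_forgotten"].to_numpy(dtype=float)
    if test == "paired":
        t, p, degenerate = _one_tailed_paired(rem - forg)
    elif test == "independent":
        res = stats.ttest_ind(rem, forg, alternative="greater")
        t, p, degenerate = float(res.statistic), float(res.pvalue), False
    else:
        raise ValueError(f"unknown test {test!r}")
    return t, p, n, degenerate


def fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone adjusted p-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def searchlight_memory(
    scores: pd.DataFrame,
    recall: pd.DataFrame,
    correction_parcels: Sequence[int] | None = None,
    q_threshold: float = 0.1,
    value_col: str = "z",
    test: str = "paired",
) -> pd.DataFrame:
    """Per-parcel remembered-vs-forgotten effects with FDR over a stated set.

    Tests every parcel present in ``scores``; q-values are computed within
    ``correction_parcels`` (default: all tested parcels), mirroring a
    correction restricted to an a-priori network.  Parcels outside the
    correction set get ``q = NaN``.
    """
    binned = bin_scores(scores, recall, value_col=value_col)
    rows = []
    for parcel, grp in binned.groupby("parcel_id", sort=True):
        t, p, n, degenerate = remembered_vs_forgotten(grp, test=test)
        rows.append(
            {
                "parcel_id": parcel,
                "t": t,
                "p": p,
                "n": n,
                "mean_remembered": grp.loc[grp["complete"], "mean_remembered"].mean(),
                "mean_forgotten": grp.loc[grp["complete"], "mean_forgotten"].mean(),
                "degenerate": degenerate,
            }
        )
    effects = pd.DataFrame(rows)
    if correction_parcels is None:
        in_set = np.ones(len(effects), dtype=bool)
    else:
        wanted = set(int(x) for x in correction_parcels)
        in_set = effects["parcel_id"].astype(int).isin(wanted).to_numpy()
        missing = wanted - set(effects["parcel_id"].astype(int))
        if missing:
            raise ValueError(f"no scores for correction-set parcels {sorted(missing)}")
    effects["q"] = np.nan
    effects.loc[in_set, "q"] = fdr(effects.loc[in_set, "p"])
    effects["significant"] = effects["q"] <= q_threshold
    return effects[EFFECT_COLUMNS]


def roi_memory(
    scores: pd.DataFrame,
    recall: pd.DataFrame,
    roi_map: Mapping[str, Sequence[int]],
    q_threshold: float = 0.1,
    value_col: str = "z",
    test: str = "paired",
) -> pd.DataFrame:
    """Remembered-vs-forgotten effects for multi-parcel ROIs.

    Scene scores are averaged over each ROI's member parcels (within
    participant and scene) before binning, then tested as usual; FDR across
    ROIs.
    """
    rows = []
    for roi, parcels in roi_map.items():
        parcels = [int(x) for x in parcels]
        if len(parcels) == 0:
            raise ValueError(f"ROI {roi!r} has no member parcels")
        sub = scores[scores["parcel_id"].astype(int).isin(parcels)]
        if sub["parcel_id"].nunique() != len(set(parcels)):
            missing = set(parcels) - set(sub["parcel_id"].astype(int))
            raise ValueError(f"ROI {roi!r}: no scores for parcels {sorted(missing)}")
        pooled = sub.groupby(["participant_id", "scene_id"], as_index=False).agg(
            value=(value_col, "mean")
        )
        pooled["parcel_id"] = -1  # single pseudo-parcel per ROI
        binned = bin_scores(pooled, recall, value_col="value")
        t, p, n, degenerate = remembered_vs_forgotten(binned, test=test)
        rows.append(
            {
                "roi": roi,
                "t": t,
                "p": p,
                "n": n,
                "mean_remembered": binned.loc[binned["complete"], "mean_remembered"].mean(),
                "mean_forgotten": binned.loc[binned["complete"], "mean_forgotten"].mean(),
                "degenerate": degenerate,
            }
        )
    effects = pd.DataFrame(rows)
    effects["q"] = fdr(effects["p"])
    effects["significant"] = effects["q"] <= q_threshold
    return effects
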