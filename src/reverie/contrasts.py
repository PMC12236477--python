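"""Music vs no-music condition contrasts.

The subsequent-memory effect (remembered > forgotten, per parcel) is
computed separately in the music and no-music conditions, the per-parcel
t statistics are converted to z-scores by tail-probability matching, and
the conditions are contrasted three ways:

* **parcel-wise**: a one-tailed paired t-test (music > no-music) on the
  per-parcel z difference across the parcels of an a-priori set (e.g. the
  79 DMN parcels, df = 78).  This treats participants as a fixed effect and
  does not license generalization to new participants; the caveat is
  recorded in the result.
* **participant-wise**: per participant, the reliability of the
  remembered-vs-forgotten difference across DMN parcels (paired t across
  parcels, converted to z), then a one-tailed two-sample t-test comparing
  music vs no-music participants (df = n1 + n2 - 2).
* **network-wise**: the parcel-wise contrast run within each of the 9
  collapsed cortical networks, with BH-FDR over the 9 network p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .memory_stats import bin_scores, fdr, remembered_vs_forgotten

__all__ = [
    "t_to_z",
    "condition_zmap",
    "parcelwise_condition_contrast",
    "participant_reliability_contrast",
    "network_contrast",
]

logger = logging.getLogger(__name__)

FIXED_EFFECT_CAVEAT = (
    "parcels-as-observations contrast treats participants as a fixed effect; "
    "it does not license generalization to new participants"
)


def t_to_z(t: float, df: int) -> float:
    """Convert a t statistic to a z-score with the same tail probability.

    Quantile matching through the standard normal (not the crude z = t),
    which matters at modest degrees of freedom.  Antisymmetric in t.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = float(t)
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    # work in the smaller tail for numerical precision
    if t >= 0:
        return float(stats.norm.isf(stats.t.sf(t, df)))
    return float(-stats.norm.isf(stats.t.sf(-t, df)))


def condition_zmap(
    effects_music: pd.DataFrame, effects_nomusic: pd.DataFrame
) -> pd.DataFrame:
    """Per-parcel subsequent-memory z-scores for both conditions.

    Joins the two per-parcel effect tables, converts each condition's t to
    z (using that condition's df = n - 1), and records the music - no-music
    difference.
    """
    merged = effects_music[["parcel_id", "t", "n"]].merge(
        effects_nomusic[["parcel_id", "t", "n"]],
        on="parcel_id",
        suffixes=("_music", "_nomusic"),
    )
    merged["z_music"] = [
        t_to_z(t, int(n) - 1) for t, n in zip(merged["t_music"], merged["n_music"])
    ]
    merged["z_nomusic"] = [
        t_to_z(t, int(n) - 1)
        for t, n in zip(merged["t_nomusic"], merged["n_nomusic"])
    ]
    merged["z_diff"] = merged["z_music"] - merged["z_nomusic"]
    return merged[
        ["parcel_id", "z_music", "z_nomusic", "z_diff", "t_music", "t_nomusic"]
    ]


def parcelwise_condition_contrast(
    zmap: pd.DataFrame, parcel_set: Sequence[int] | None = None
) -> dict:
    """One-tailed paired t (music > no-music) on per-parcel z-scores.

    df equals the number of parcels in the set minus one.
    """
    sub = zmap
    if parcel_set is not None:
        sub = zmap[zmap["parcel_id"].astype(int).isin(set(int(x) for x in parcel_set))]
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 parcels for the condition contrast, got {n}")
    diffs = sub["z_diff"].to_numpy(dtype=float)
    if diffs.std(ddof=1) == 0 and np.allclose(diffs, 0):
        t_stat, p_val = 0.0, 0.5  # identical conditions
    else:
        res = stats.ttest_1samp(diffs, 0.0, alternative="greater")
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return {
        "t": t_stat,
        "p": p_val,
        "df": n - 1,
        "n_parcels": n,
        "mean_z_diff": float(diffs.mean()),
        "caveat": FIXED_EFFECT_CAVEAT,
    }


def participant_reliability_contrast(
    scores_music: pd.DataFrame,
    scores_nomusic: pd.DataFrame,
    recall_music: pd.DataFrame,
    recall_nomusic: pd.DataFrame,
    parcel_set: Sequence[int] | None = None,
    value_col: str = "z",
) -> dict:
    """Across-parcel reliability per participant, contrasted across groups.

    For each participant, a one-tailed paired t (remembered > forgotten)
    across the parcels of the set measures how reliably that participant
    shows the effect; the per-participant t values (df = n_parcels - 1) are
    converted to z and compared music vs no-music with a one-tailed
    two-sample t-test (df = n1 + n2 - 2).
    """

    def per_participant_z(scores: pd.DataFrame, recall: pd.DataFrame) -> np.ndarray:
        sub = scores
        if parcel_set is not None:
            sub = scores[
                scores["parcel_id"].astype(int).isin(set(int(x) for x in parcel_set))
            ]
        binned = bin_scores(sub, recall, value_col=value_col)
        zs = []
        for participant, grp in binned.groupby("participant_id", sort=True):
            usable = grp[grp["complete"]]
            if len(usable) < 3:
                logger.warning(
                    "participant %s has < 3 usable parcels; skipped", participant
                )
                continue
            diffs = (
                usable["mean_remembered"] - usable["mean_forgotten"]
            ).to_numpy(dtype=float)
            if diffs.std(ddof=1) == 0:
                logger.warning(
                    "participant %s has zero-variance parcel differences; skipped",
                    participant,
                )
                continue
            res = stats.ttest_1samp(diffs, 0.0, alternative="greater")
            zs.append(t_to_z(float(res.statistic), len(diffs) - 1))
        return np.asarray(zs)

    z_music = per_participant_z(scores_music, recall_music)
    z_nomusic = per_participant_z(scores_nomusic, recall_nomusic)
    if len(z_music) < 3 or len(z_nomusic) < 3:
        raise ValueError("both conditions need >= 3 participants")
    res = stats.ttest_ind(z_music, z_nomusic, alternative="greater")
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": len(z_music) + len(z_nomusic) - 2,
        "n_music": len(z_music),
        "n_nomusic": len(z_nomusic),
        "mean_z_music": float(z_music.mean()),
        "mean_z_nomusic": float(z_nomusic.mean()),
    }


def network_contrast(
    zmap: pd.DataFrame,
    parcel_meta: pd.DataFrame,
    min_parcels: int = 3,
) -> pd.DataFrame:
    """Parcel-wise condition contrast within each collapsed network.

    Networks with fewer than ``min_parcels`` parcels are skipped with a
    warning; BH-FDR is applied across the tested networks' p-values.
    """
    min_parcels = max(min_parcels, 3)  # paired contrast needs >= 3 parcels
    meta = parcel_meta.set_index("parcel_id")["network"]
    unmapped = set(zmap["parcel_id"].astype(int)) - set(meta.index.astype(int))
    if unmapped:
        raise ValueError(f"parcels without a network mapping: {sorted(unmapped)}")
    rows = []
    for network, ids in meta.groupby(meta).groups.items():
        parcel_ids = [int(x) for x in ids]
        in_map = zmap[zmap["parcel_id"].astype(int).isin(parcel_ids)]
        if len(in_map) < min_parcels:
            logger.warning(
                "network %s has %d parcels (< %d); skipped",
                network,
                len(in_map),
                min_parcels,
            )
            continue
        res = parcelwise_condition_contrast(in_map)
        rows.append(
            {
                "network": network,
                "t": res["t"],
                "p": res["p"],
                "df": res["df"],
                "n_parcels": res["n_parcels"],
                "mean_z_diff": res["mean_z_diff"],
            }
        )
    columns = ["network", "t", "p", "df", "n_parcels", "mean_z_diff"]
    if not rows:
        return pd.DataFrame(columns=columns + ["q"])
    out = pd.DataFrame(rows).sort_values("network").reset_index(drop=True)
    out["q"] = fdr(out["p"])
    return out
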