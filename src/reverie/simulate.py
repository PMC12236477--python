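"""Synthetic two-group parcellated datasets with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* every scene ``s`` has a fixed random unit-norm spatial signature
  ``u_{k,s}`` per parcel ``k``, shared across participants and groups, so
  cross-participant scene evidence is meaningful;
* participant ``p`` encodes scene ``s`` with a multiplicative strength
  ``e_{p,s} = exp(encoding_sd * N(0,1))`` (lognormal, median 1), scaling the
  signature amplitude ``e_{p,s} * g`` during the scene's TRs;
* in the **music group only**, scenes belonging to a later occurrence block
  of a repeated song additionally carry the mean of the strictly-earlier
  same-song scenes' signatures, each weighted by a planted reactivation
  amplitude ``gamma_{p,s'} = react_gain * e_{p,s'}**kappa *
  exp(react_sd * eta_{p,s'})`` (restricted to the affected parcels).  The
  coupling exponent ``kappa`` ties reactivation to encoding strength --
  well-encoded scenes are reinstated more strongly -- which is exactly the
  confound the ISC-control analysis exists to remove; ``eta`` is the
  encoding-independent retrieval latent;
* i.i.d. Gaussian voxel noise with ``noise_sd``;
* recall is Bernoulli with ``logit = a + b * e_tilde + c * eta`` where
  ``e_tilde = log(e)/encoding_sd`` is the standardized encoding latent and
  the ``c * eta`` retrieval term applies only to cued scenes of music
  participants (and only when reactivation is planted at all).  The
  no-music group is generated by the identical process with the
  reactivation injection forced to zero.

No hemodynamic convolution is simulated: the pipeline consumes
time-averaged patterns, so a boxcar-at-TR model keeps the generator
analytically tractable for oracle tests.  One seed fixes all randomness
end-to-end; the same seed reproduces the dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import SceneTable, build_megascenes, canonical_scene_table
from .parcels import make_parcel_meta
from .patterns import scene_tr_indices
from .reactivation import enumerate_pairs

__all__ = ["SimConfig", "SimDataset", "generate"]

GROUPS = ("music", "nomusic")


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Defaults follow the study design being emulated: 24 participants per
    group viewing a movie whose scene/song structure is the bundled
    407-scene table (6 repeated songs, 93 repeated-music scenes).  Parcel
    count and voxel count are artifact sizes, kept small.
    """

    n_participants: int = 24
    n_parcels: int = 4
    voxels_per_parcel: int = 30
    tr_s: float = 1.5
    scene_table: SceneTable | None = None  # None -> canonical 407-scene table
    signature_gain: float = 1.0
    encoding_sd: float = 0.5
    react_gain: float = 0.95
    react_sd: float = 0.5
    react_encoding_coupling: float = 1.0
    affected_parcels: tuple[int, ...] | None = None  # None -> all parcels
    recall_intercept: float = 0.0
    recall_encoding: float = 1.0
    recall_react: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_parcels < 1 or self.voxels_per_parcel < 1:
            raise ValueError("need at least one parcel and one voxel")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        for name in ("signature_gain", "encoding_sd", "react_gain", "react_sd",
                     "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def resolved_scene_table(self) -> SceneTable:
        return self.scene_table if self.scene_table is not None else canonical_scene_table()


@dataclass
class SimDataset:
    """A generated dataset plus its ground-truth latent variables."""

    config: SimConfig
    scenes: SceneTable
    parcel_meta: pd.DataFrame
    participant_ids: dict[str, list[str]]
    data: dict[str, np.ndarray]  # group -> (P, K, V, T)
    recall: pd.DataFrame  # participant_id, scene_id, remembered
    ground_truth: dict[str, np.ndarray]
    cued_scene_ids: tuple[int, ...]

    @property
    def tr_s(self) -> float:
        return self.config.tr_s

    def recall_for_group(self, group: str) -> pd.DataFrame:
        ids = set(self.participant_ids[group])
        return self.recall[self.recall["participant_id"].isin(ids)].reset_index(
            drop=True
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(config: SimConfig) -> SimDataset:
    """Generate a two-group dataset with planted reactivation and recall."""
    config.validate()
    scenes = config.resolved_scene_table()
    n_scenes = len(scenes)
    scene_ids = [int(s) for s in scenes.scene_ids]
    scene_pos = {sid: i for i, sid in enumerate(scene_ids)}
    megas = build_megascenes(scenes)
    pairs = enumerate_pairs(scenes, megas)
    cued = tuple(sorted({p.earlier_scene_id for p in pairs}))
    cued_mask = np.zeros(n_scenes, dtype=bool)
    cued_mask[[scene_pos[s] for s in cued]] = True

    P, K, V = config.n_participants, config.n_parcels, config.voxels_per_parcel
    n_tr = int(np.ceil(scenes.duration_s / config.tr_s))
    if n_tr < 1:
        raise ValueError("scene table yields zero TRs")
    affected = (
        np.arange(K)
        if config.affected_parcels is None
        else np.asarray(sorted(config.affected_parcels), dtype=int)
    )
    if affected.size and (affected.min() < 0 or affected.max() >= K):
        raise ValueError("affected_parcels out of range")

    rng = np.random.default_rng(config.seed)
    # fixed draw order so one seed reproduces the dataset bit-for-bit
    signatures = rng.standard_normal((K, n_scenes, V))
    signatures /= np.linalg.norm(signatures, axis=-1, keepdims=True)

    e = {g: np.exp(config.encoding_sd * rng.standard_normal((P, n_scenes)))
         for g in GROUPS}
    eta = {g: rng.standard_normal((P, n_scenes)) for g in GROUPS}
    gamma = {g: np.zeros((P, n_scenes)) for g in GROUPS}
    if config.react_gain > 0:
        gamma["music"] = np.where(
            cued_mask[None, :],
            config.react_gain
            * e["music"] ** config.react_encoding_coupling
            * np.exp(config.react_sd * eta["music"]),
            0.0,
        )

    tr_idx = {
        sid: scene_tr_indices(
            float(scenes.row(sid)["start_s"]),
            float(scenes.row(sid)["end_s"]),
            config.tr_s,
            n_tr,
        )
        for sid in scene_ids
    }

    data: dict[str, np.ndarray] = {}
    for group in GROUPS:
        x = config.noise_sd * rng.standard_normal((P, K, V, n_tr))
        # scene signatures scaled by per-participant encoding strength
        for sid in scene_ids:
            idx = tr_idx[sid]
            if idx.size == 0:
                continue
            j = scene_pos[sid]
            amp = config.signature_gain * e[group][:, j]  # (P,)
            x[:, :, :, idx] += (
                amp[:, None, None] * signatures[None, :, j, :]
            )[..., None]
        if group == "music" and config.react_gain > 0 and affected.size:
            song_scenes: dict[str, list[int]] = {}
            for mega in megas:
                earlier = [
                    pr.earlier_scene_id for pr in pairs if pr.mega_id == mega.mega_id
                ]
                if not earlier:
                    continue
                cols = [scene_pos[s] for s in earlier]
                # mean of earlier-scene signatures, each weighted by the
                # participant's planted reactivation amplitude
                inj = np.einsum(
                    "pj,kjv->pkv",
                    gamma[group][:, cols] / len(cols),
                    signatures[affected][:, cols, :],
                )
                for sid in mega.member_scene_ids:
                    idx = tr_idx[sid]
                    if idx.size:
                        for a_i, k in enumerate(affected):
                            x[:, k][:, :, idx] += inj[:, a_i, :, None]
        data[group] = x

    # Bernoulli recall from standardized latents
    recall_rows = []
    participant_ids = {
        g: [f"{g}-{i:02d}" for i in range(P)] for g in GROUPS
    }
    for group in GROUPS:
        if config.encoding_sd > 0:
            e_tilde = np.log(e[group]) / config.encoding_sd
        else:
            e_tilde = np.zeros((P, n_scenes))
        logit = config.recall_intercept + config.recall_encoding * e_tilde
        if group == "music" and config.react_gain > 0:
            logit = logit + config.recall_react * eta[group] * cued_mask[None, :]
        p_rem = _sigmoid(logit)
        draws = rng.random((P, n_scenes))
        remembered = draws < p_rem
        for i, pid in enumerate(participant_ids[group]):
            for j, sid in enumerate(scene_ids):
                recall_rows.append((pid, sid, bool(remembered[i, j])))

    recall = pd.DataFrame(
        recall_rows, columns=["participant_id", "scene_id", "remembered"]
    )
    ground_truth = {
        "encoding_music": e["music"],
        "encoding_nomusic": e["nomusic"],
        "eta_music": eta["music"],
        "eta_nomusic": eta["nomusic"],
        "gamma_music": gamma["music"],
        "gamma_nomusic": gamma["nomusic"],
    }
    return SimDataset(
        config=config,
        scenes=scenes,
        parcel_meta=make_parcel_meta(range(K)),
        participant_ids=participant_ids,
        data=data,
        recall=recall,
        ground_truth=ground_truth,
        cued_scene_ids=cued,
    )
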