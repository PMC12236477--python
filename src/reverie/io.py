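"""Reading and writing the on-disk dataset bundle.

A dataset directory holds:

* ``data.h5`` -- one HDF5 group per condition (``music`` / ``nomusic``),
  one subgroup per participant, one ``parcel-XXXX`` dataset per parcel of
  shape (voxels, TRs), with ``tr_s`` stored as a root attribute;
* ``scenes.tsv`` -- the scene annotation table;
* ``recall.tsv`` -- participant x scene remembered flags;
* ``parcels.tsv`` -- parcel metadata (hemisphere, 17-network-style label);
* ``ground_truth.json`` -- the generator's latent variables (synthetic
  datasets only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .annotations import SceneTable
from .simulate import SimDataset

__all__ = ["DataBundle", "write_dataset", "read_dataset"]


@dataclass
class DataBundle:
    """An in-memory dataset as loaded from disk."""

    scenes: SceneTable
    parcel_meta: pd.DataFrame
    participant_ids: dict[str, list[str]]
    data: dict[str, np.ndarray]  # group -> (P, K, V, T)
    recall: pd.DataFrame
    tr_s: float

    def recall_for_group(self, group: str) -> pd.DataFrame:
        ids = set(self.participant_ids[group])
        return self.recall[self.recall["participant_id"].isin(ids)].reset_index(
            drop=True
        )


def write_dataset(dataset: SimDataset, outdir: str | Path) -> Path:
    """Write a generated dataset as an HDF5 + TSV + JSON bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with h5py.File(outdir / "data.h5", "w") as f:
        f.attrs["tr_s"] = dataset.tr_s
        for group, arr in dataset.data.items():
            g = f.create_group(group)
            for i, pid in enumerate(dataset.participant_ids[group]):
                sub = g.create_group(pid)
                for k in range(arr.shape[1]):
                    sub.create_dataset(f"parcel-{k:04d}", data=arr[i, k])
    dataset.scenes.to_tsv(outdir / "scenes.tsv")
    dataset.recall.to_csv(outdir / "recall.tsv", sep="\t", index=False)
    dataset.parcel_meta.to_csv(outdir / "parcels.tsv", sep="\t", index=False)
    truth = {k: v.tolist() for k, v in dataset.ground_truth.items()}
    truth["cued_scene_ids"] = list(dataset.cued_scene_ids)
    (outdir / "ground_truth.json").write_text(json.dumps(truth))
    return outdir


def read_dataset(path: str | Path) -> DataBundle:
    """Load a dataset bundle written by :func:`write_dataset`."""
    path = Path(path)
    scenes = SceneTable.from_tsv(path / "scenes.tsv")
    recall = pd.read_csv(path / "recall.tsv", sep="\t")
    recall["remembered"] = recall["remembered"].astype(bool)
    parcel_meta = pd.read_csv(path / "parcels.tsv", sep="\t")
    data: dict[str, np.ndarray] = {}
    participant_ids: dict[str, list[str]] = {}
    with h5py.File(path / "data.h5", "r") as f:
        tr_s = float(f.attrs["tr_s"])
        for group in f:
            pids = sorted(f[group])
            participant_ids[group] = pids
            stacks = []
            for pid in pids:
                parcels = sorted(f[group][pid])
                stacks.append(
                    np.stack([f[group][pid][k][()] for k in parcels], axis=0)
                )
            data[group] = np.stack(stacks, axis=0)
    return DataBundle(
        scenes=scenes,
        parcel_meta=parcel_meta,
        participant_ids=participant_ids,
        data=data,
        recall=recall,
        tr_s=tr_s,
    )
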