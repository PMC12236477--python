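"""Parcel metadata: hemispheres, 17-network-style labels, network collapsing.

Parcels carry labels in the style of the Schaefer 400 / 17-network atlas
(e.g. ``DefaultA``, ``VisPeri``).  Collapsing across hemispheres and
subnetworks -- stripping the trailing A/B/C subnetwork letter while keeping
the central and peripheral visual networks distinct -- yields exactly 9
bilateral cortical networks.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

__all__ = [
    "SEVENTEEN_NETWORKS",
    "NINE_NETWORKS",
    "collapse_network",
    "make_parcel_meta",
]

SEVENTEEN_NETWORKS: tuple[str, ...] = (
    "VisCent",
    "VisPeri",
    "SomMotA",
    "SomMotB",
    "DorsAttnA",
    "DorsAttnB",
    "SalVentAttnA",
    "SalVentAttnB",
    "LimbicA",
    "LimbicB",
    "ContA",
    "ContB",
    "ContC",
    "DefaultA",
    "DefaultB",
    "DefaultC",
    "TempPar",
)

NINE_NETWORKS: tuple[str, ...] = (
    "VisCent",
    "VisPeri",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
    "TempPar",
)


def collapse_network(subnetwork: str) -> str:
    """Collapse a 17-network-style label to its bilateral network.

    The trailing subnetwork letter (A/B/C) is stripped; ``VisCent`` and
    ``VisPeri`` are kept distinct.
    """
    if subnetwork in ("VisCent", "VisPeri"):
        return subnetwork
    if len(subnetwork) > 1 and subnetwork[-1] in "ABC":
        return subnetwork[:-1]
    return subnetwork


def make_parcel_meta(
    parcel_ids: Sequence[int],
    subnetworks: Sequence[str] | None = None,
    hemispheres: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Parcel metadata table with collapsed network labels.

    When ``subnetworks`` is omitted, the 17 canonical labels are cycled over
    the parcels (alternating hemispheres), which is convenient for synthetic
    datasets.
    """
    parcel_ids = [int(p) for p in parcel_ids]
    if subnetworks is None:
        subnetworks = [
            SEVENTEEN_NETWORKS[i % len(SEVENTEEN_NETWORKS)]
            for i in range(len(parcel_ids))
        ]
    if hemispheres is None:
        hemispheres = ["L" if i % 2 == 0 else "R" for i in range(len(parcel_ids))]
    frame = pd.DataFrame(
        {
            "parcel_id": parcel_ids,
            "hemisphere": list(hemispheres),
            "subnetwork": list(subnetworks),
        }
    )
    frame["network"] = frame["subnetwork"].map(collapse_network)
    return frame
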