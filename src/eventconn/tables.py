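"""Channel-pair labelling and assembly of the long-format pair table.

Each unordered channel pair gets a seizure-onset-zone label (``inside`` when
both contacts sit in the SOZ, ``outside`` when neither does, ``between``
otherwise) and a regional-network label from the mesial / lateral /
extratemporal classes (M-M, M-L, M-E, L-L, L-E, E-E, canonically ordered).
The resulting per-pair table — connectivity per band, spike coupling rate,
distance, labels, patient and outcome — is the input contract of the
statistics stage.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .geometry import DistanceMatrix
from .spikes import SpikeCouplingMatrix

__all__ = [
    "PAIR_TABLE_COLUMNS",
    "zone_pair_label",
    "region_pair_label",
    "build_pair_table",
]

REGION_ORDER = {"M": 0, "L": 1, "E": 2}

PAIR_TABLE_COLUMNS = [
    "patient", "channel_i", "channel_j",
    "h_theta", "h_lg", "h_hg",
    "spike_rate", "distance_mm",
    "zone_pair", "region_pair", "outcome",
]


def zone_pair_label(soz_a: bool, soz_b: bool) -> str:
    """inside / outside / between from the two contacts' SOZ flags."""
    if soz_a is None or soz_b is None:
        raise ValueError("missing SOZ flag")
    if soz_a and soz_b:
        return "inside"
    if not soz_a and not soz_b:
        return "outside"
    return "between"


def region_pair_label(region_a: str, region_b: str) -> str:
    """Canonical regional network label with ordering M < L < E."""
    for r in (region_a, region_b):
        if r not in REGION_ORDER:
            raise ValueError(f"unknown region code: {r!r}")
    a, b = sorted((region_a, region_b), key=REGION_ORDER.__getitem__)
    return f"{a}-{b}"


def _lookup(matrix: np.ndarray, labels: list[str], a: str, b: str) -> float:
    return float(matrix[labels.index(a), labels.index(b)])


def build_pair_table(
    band_matrices: dict[str, ConnectivityMatrix],
    spike_matrix: SpikeCouplingMatrix,
    dist_matrix: DistanceMatrix,
    metadata: pd.DataFrame,
    patient: str,
    outcome: str,
    split_hemispheres: bool = False,
) -> pd.DataFrame:
    """One record per unordered channel pair, Nc(Nc-1)/2 rows.

    Non-SOZ contacts are pooled across hemispheres by default; with
    ``split_hemispheres`` a ``laterality`` column (ipsi/contra) is added so
    ipsilateral and contralateral pairs can be analyzed separately.
    """
    labels = list(metadata["label"])
    for name, m in band_matrices.items():
        if m.channel_labels != labels:
            raise ValueError(f"channel set mismatch in band '{name}'")
    if spike_matrix.channel_labels != labels:
        raise ValueError("channel set mismatch in spike matrix")
    if dist_matrix.channel_labels != labels:
        raise ValueError("channel set mismatch in distance matrix")

    meta = metadata.set_index("label")
    records = []
    for a, b in itertools.combinations(labels, 2):
        rec = {
            "patient": patient,
            "channel_i": a,
            "channel_j": b,
            "h_theta": _h(band_matrices, "theta", labels, a, b),
            "h_lg": _h(band_matrices, "low_gamma", labels, a, b),
            "h_hg": _h(band_matrices, "high_gamma", labels, a, b),
            "spike_rate": _lookup(spike_matrix.r, labels, a, b),
            "distance_mm": _lookup(dist_matrix.d, labels, a, b),
            "zone_pair": zone_pair_label(
                bool(meta.at[a, "soz"]), bool(meta.at[b, "soz"])
            ),
            "region_pair": region_pair_label(
                meta.at[a, "region"], meta.at[b, "region"]
            ),
            "outcome": outcome,
        }
        if split_hemispheres:
            rec["laterality"] = (
                "ipsi" if meta.at[a, "hemisphere"] == meta.at[b, "hemisphere"]
                else "contra"
            )
        records.append(rec)
    cols = PAIR_TABLE_COLUMNS + (["laterality"] if split_hemispheres else [])
    return pd.DataFrame.from_records(records, columns=cols)


def _h(band_matrices, name, labels, a, b):
    if name not in band_matrices:
        return np.nan
    return _lookup(band_matrices[name].h, labels, a, b)
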