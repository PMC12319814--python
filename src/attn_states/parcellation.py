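"""Parcel/network lookup tables.

A parcellation maps analysis units (voxels or parcels) onto named
parcels, each belonging to exactly one functional network. The packaged
fixture is a synthetic stand-in for a Gordon-style cortical atlas: 333
parcels across 13 networks with the real atlas's network sizes, but
synthetic centroid coordinates generated by clustering parcels of a
network around a random network center. It exists so that
network-coverage, effect-size and spatial-null code can run without any
atlas download; it makes no anatomical claim.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["gordon_like_parcellation", "load_parcellation", "write_parcellation"]

# parcel counts per network in the 333-parcel, 13-network cortical atlas
GORDON_NETWORK_SIZES: dict[str, int] = {
    "Default": 41,
    "SMhand": 38,
    "SMmouth": 8,
    "Visual": 39,
    "FrontoParietal": 24,
    "Auditory": 24,
    "CinguloParietal": 5,
    "RetrosplenialTemporal": 8,
    "CinguloOperc": 40,
    "VentralAttn": 23,
    "Salience": 4,
    "DorsalAttn": 32,
    "None": 47,
}


def gordon_like_parcellation(seed: int = 7) -> pd.DataFrame:
    """Synthetic 333-parcel / 13-network parcellation table.

    Columns: parcel_id (0..332), network, x/y/z centroid (mm, synthetic).
    Deterministic for a given seed. Networks are spatially clustered so
    that maps defined on the centroids carry spatial autocorrelation,
    which the variogram-matching null generator needs to be exercised
    against.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for network, size in GORDON_NETWORK_SIZES.items():
        center = rng.uniform(-60.0, 60.0, size=3)
        offsets = rng.normal(0.0, 18.0, size=(size, 3))
        for k in range(size):
            x, y, z = center + offsets[k]
            rows.append((pid, network, round(float(x), 2), round(float(y), 2),
                         round(float(z), 2)))
            pid += 1
    return pd.DataFrame(rows, columns=["parcel_id", "network", "x", "y", "z"])


def write_parcellation(parcellation: pd.DataFrame, path: str | Path) -> None:
    parcellation.to_csv(path, sep="\t", index=False)


def load_parcellation(path: str | Path) -> pd.DataFrame:
    """Read a parcel table (TSV with parcel_id, network and optional
    x/y/z centroid columns) supplied by the user or written by
    :func:`write_parcellation`."""
    # keep_default_na: the atlas's unassigned network is literally "None"
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    missing = {"parcel_id", "network"} - set(df.columns)
    if missing:
        raise ValueError(f"parcellation table lacks columns: {sorted(missing)}")
    if df["parcel_id"].duplicated().any():
        raise ValueError("parcel ids must be unique")
    return df
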