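"""Electrode geometry: the shipped 62-channel extended 10-20 layout and
channel adjacency derived from it.

The layout file stores 2-D azimuthal-equidistant projections of the standard
10-20 positions, ordered anterior to posterior, so "the posterior fraction of
channels" is simply a suffix of the list.  Channel adjacency is the Delaunay
triangulation of the 2-D positions, which yields on average ~6 neighbors per
channel on the 62-channel cap; exact neighbor counts are a property of the
layout, not of any analysis.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay


def standard_montage_62() -> pd.DataFrame:
    """The shipped 62-channel layout: columns ``name, x, y``, anterior first."""
    with resources.files("ctxdecode.data").joinpath("montage62.csv").open() as f:
        return pd.read_csv(f)


def synthetic_montage(n_channels: int) -> pd.DataFrame:
    """Deterministic generic layout for simulations with n != 62 channels.

    Channels are placed on a spiral inside the unit disk, ordered from the
    front (positive y) to the back, mirroring the anterior-to-posterior
    ordering of the standard layout.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    k = np.arange(n_channels)
    # sunflower/spiral layout: well-spread, deterministic
    r = np.sqrt((k + 0.5) / n_channels)
    theta = k * np.pi * (3 - np.sqrt(5.0))
    x, y = r * np.cos(theta), r * np.sin(theta)
    order = np.argsort(-y, kind="stable")
    names = [f"CH{i + 1:02d}" for i in range(n_channels)]
    return pd.DataFrame({"name": names, "x": x[order], "y": y[order]})


def channel_positions(channel_names: list[str]) -> pd.DataFrame:
    """Resolve positions for a channel list.

    Names found in the standard layout get their standard coordinates; a
    fully synthetic list (``CHxx``) gets the spiral layout.  Mixing is not
    supported.
    """
    std = standard_montage_62().set_index("name")
    if all(n in std.index for n in channel_names):
        sub = std.loc[list(channel_names)].reset_index()
        return sub
    if all(n.startswith("CH") for n in channel_names):
        syn = synthetic_montage(len(channel_names))
        syn["name"] = list(channel_names)
        return syn
    missing = [n for n in channel_names if n not in std.index]
    raise KeyError(f"channels without known positions: {missing}")


def adjacency_from_positions(positions: pd.DataFrame) -> dict[str, set[str]]:
    """Delaunay-triangulation channel neighbor map (symmetric)."""
    names = list(positions["name"])
    pts = positions[["x", "y"]].to_numpy()
    adj: dict[str, set[str]] = {n: set() for n in names}
    if len(names) < 3:
        for a in names:
            adj[a] = set(names) - {a}
        return adj
    tri = Delaunay(pts)
    for simplex in tri.simplices:
        for i in simplex:
            for j in simplex:
                if i != j:
                    adj[names[i]].add(names[j])
    return adj


def channel_adjacency(channel_names: list[str]) -> dict[str, set[str]]:
    """Neighbor map for a channel list (positions resolved automatically)."""
    return adjacency_from_positions(channel_positions(channel_names))
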