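"""Origin-destination travel times and the nearest-facility measures.

Block-group centroids and facilities are snapped to their nearest road
node by Euclidean distance (access time to the node itself counts as
zero); the travel-time matrix holds shortest-path times in minutes over
the network, with an infinite entry for an unreachable pair.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


def _node_tree(network: nx.Graph):
    nodes = list(network.nodes)
    coords = np.array([[network.nodes[n]["x"], network.nodes[n]["y"]] for n in nodes])
    return nodes, cKDTree(coords)


def snap_to_network(network: nx.Graph, x, y) -> list:
    """Nearest network node (Euclidean) for each coordinate pair."""
    nodes, tree = _node_tree(network)
    _, idx = tree.query(np.column_stack([np.asarray(x, float), np.asarray(y, float)]))
    return [nodes[i] for i in idx]


def od_matrix(
    network: nx.Graph,
    blockgroups: pd.DataFrame,
    facilities: pd.DataFrame,
    weight: str = "minutes",
) -> pd.DataFrame:
    """Shortest-path travel-time matrix (block groups x facilities).

    Edge attribute ``weight`` must already be in minutes.  One Dijkstra
    pass is run from each facility's snapped node; an unreachable pair
    gets ``inf`` and is logged.
    """
    bg_nodes = snap_to_network(network, blockgroups["x"], blockgroups["y"])
    fac_nodes = snap_to_network(network, facilities["x"], facilities["y"])

    times = np.full((len(blockgroups), len(facilities)), np.inf)
    for j, fnode in enumerate(fac_nodes):
        dist = nx.single_source_dijkstra_path_length(network, fnode, weight=weight)
        for k, bnode in enumerate(bg_nodes):
            if bnode in dist:
                times[k, j] = dist[bnode]
    n_unreach = int(np.isinf(times).sum())
    if n_unreach:
        logger.warning("%d origin-destination pairs are unreachable", n_unreach)
    return pd.DataFrame(times, index=blockgroups.index, columns=facilities.index)


def _check_rows(times: pd.DataFrame) -> np.ndarray:
    t = times.to_numpy(dtype=float)
    if (t < 0).any():
        raise ValueError("negative travel times")
    dead = ~np.isfinite(t).any(axis=1)
    if dead.any():
        bad = list(times.index[dead])
        raise ValueError(f"block groups with no reachable facility: {bad}")
    return t


def dst(times: pd.DataFrame) -> pd.Series:
    """Shortest travel time to the nearest facility, per block group."""
    t = _check_rows(times)
    return pd.Series(np.nanmin(np.where(np.isfinite(t), t, np.nan), axis=1),
                     index=times.index, name="DST")


def dst5(times: pd.DataFrame, k: int = 5) -> pd.Series:
    """Mean travel time to the ``k`` nearest reachable facilities.

    Rows with fewer than ``k`` finite entries average over what is
    available; infinite (unreachable) times are never counted among the
    nearest facilities.
    """
    t = _check_rows(times)
    out = np.empty(t.shape[0])
    for i, row in enumerate(t):
        finite = np.sort(row[np.isfinite(row)])
        out[i] = finite[: min(k, finite.size)].mean()
    return pd.Series(out, index=times.index, name="DST5")
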