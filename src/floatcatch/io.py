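"""Plain-text readers and writers: CSV tables, edge-list networks, GeoJSON."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


def write_od_long(times: pd.DataFrame, path) -> None:
    """Travel-time matrix to long CSV (bg_id, facility_id, minutes)."""
    long = times.stack().rename("minutes").rename_axis(["bg_id", "fac_id"]).reset_index()
    long.to_csv(path, index=False)


def read_od_long(path) -> pd.DataFrame:
    long = pd.read_csv(path)
    return long.pivot(index="bg_id", columns="fac_id", values="minutes")


def write_network(network: nx.Graph, edge_path, node_path) -> None:
    edges = pd.DataFrame(
        [(u, v, d["minutes"]) for u, v, d in network.edges(data=True)],
        columns=["node_from", "node_to", "minutes"],
    )
    edges.to_csv(edge_path, index=False)
    nodes = pd.DataFrame(
        [(n, d["x"], d["y"]) for n, d in network.nodes(data=True)],
        columns=["node", "x", "y"],
    )
    nodes.to_csv(node_path, index=False)


def read_network(edge_path, node_path) -> nx.Graph:
    g = nx.Graph()
    for row in pd.read_csv(node_path).itertuples(index=False):
        g.add_node(row.node, x=float(row.x), y=float(row.y))
    for row in pd.read_csv(edge_path).itertuples(index=False):
        g.add_edge(row.node_from, row.node_to, minutes=float(row.minutes))
    return g


def write_facilities_long(facilities: pd.DataFrame, path) -> None:
    """Facility table to long CSV (fac_id, year, machines) plus coordinates."""
    cols = [c for c in facilities.columns if c.startswith("machines_")]
    rows = []
    for fac_id, row in facilities.iterrows():
        for i, c in enumerate(cols, start=1):
            rows.append((fac_id, row["x"], row["y"], i, int(row[c])))
    pd.DataFrame(rows, columns=["fac_id", "x", "y", "year", "machines"]).to_csv(
        path, index=False
    )


def read_facilities_long(path) -> pd.DataFrame:
    long = pd.read_csv(path)
    wide = long.pivot(index="fac_id", columns="year", values="machines")
    wide.columns = [f"machines_y{y}" for y in wide.columns]
    coords = long.groupby("fac_id")[["x", "y"]].first()
    return coords.join(wide)


def write_blockgroups_geojson(blockgroups: pd.DataFrame, path,
                              extra: pd.DataFrame | None = None) -> None:
    """Block-group centroids as GeoJSON point features."""
    features = []
    for bg_id, row in blockgroups.iterrows():
        props = {"bg_id": str(bg_id)}
        for col in blockgroups.columns:
            if col not in ("x", "y"):
                props[col] = _jsonable(row[col])
        if extra is not None and bg_id in extra.index:
            for col in extra.columns:
                props[col] = _jsonable(extra.loc[bg_id, col])
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["x"]), float(row["y"])]},
            "properties": props,
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, sort_keys=True
    ))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
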