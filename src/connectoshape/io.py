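"""Plain-text readers and writers for every artifact the pipeline exchanges.

Conventions: node indices are 0-based everywhere; thickness is in mm and age
in years; matrices are stored as dense CSV at study scale.  Readers validate
headers and basic invariants (symmetry, monotone scan ages, edge normal
form) and raise on violations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome
from .parcellation import Parcellation
from .synthetic import GenePanel, ScanTable

NODE_COLUMNS = ["node_id", "hemi", "x", "y", "z", "system", "laminar"]


def write_node_table(parcellation: Parcellation, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "node_id": np.arange(parcellation.n_nodes),
            "hemi": parcellation.hemisphere,
            "x": parcellation.centroids[:, 0],
            "y": parcellation.centroids[:, 1],
            "z": parcellation.centroids[:, 2],
            "system": parcellation.system,
            "laminar": parcellation.laminar,
        }
    )
    df.to_csv(path, index=False)


def write_spatial_adjacency(parcellation: Parcellation, path: str | Path) -> None:
    i, j = np.nonzero(np.triu(parcellation.spatial_adjacency, 1))
    pd.DataFrame({"i": i, "j": j}).to_csv(path, sep="\t", index=False, header=False)


def read_node_table(
    path: str | Path, adjacency_path: str | Path | None = None
) -> Parcellation:
    df = pd.read_csv(path)
    if list(df.columns) != NODE_COLUMNS:
        raise ValueError(f"node table must have columns {NODE_COLUMNS}")
    if not (df["node_id"].to_numpy() == np.arange(len(df))).all():
        raise ValueError("node_id must be 0-based and consecutive")
    n = len(df)
    if adjacency_path is not None:
        adjacency = np.zeros((n, n), dtype=bool)
        for i, j in read_edge_list(adjacency_path, n):
            adjacency[i, j] = adjacency[j, i] = True
    else:
        raise ValueError("a spatial adjacency edge list is required")
    return Parcellation(
        centroids=df[["x", "y", "z"]].to_numpy(float),
        hemisphere=df["hemi"].to_numpy(),
        system=df["system"].to_numpy(int),
        laminar=df["laminar"].to_numpy(int),
        spatial_adjacency=adjacency,
    )


def write_edge_list(connectome_or_adjacency, path: str | Path) -> None:
    adj = (
        connectome_or_adjacency.adjacency
        if isinstance(connectome_or_adjacency, Connectome)
        else np.asarray(connectome_or_adjacency)
    )
    i, j = np.nonzero(np.triu(adj, 1))
    pd.DataFrame({"i": i, "j": j}).to_csv(path, sep="\t", index=False, header=False)


def read_edge_list(path: str | Path, n_nodes: int) -> np.ndarray:
    """Edge list TSV -> (m, 2) array, normalized to i < j; rejects duplicates."""
    df = pd.read_csv(path, sep="\t", header=None, names=["i", "j"])
    edges = df.to_numpy(int)
    if edges.size == 0:
        return edges.reshape(0, 2)
    if edges.min() < 0 or edges.max() >= n_nodes:
        raise ValueError("edge indices out of range for the node table")
    edges = np.sort(edges, axis=1)
    if (edges[:, 0] == edges[:, 1]).any():
        raise ValueError("self-loop in edge list")
    keys = set()
    for i, j in edges:
        if (i, j) in keys:
            raise ValueError(f"duplicate edge ({i}, {j})")
        keys.add((int(i), int(j)))
    return edges


def read_connectome(
    edge_path: str | Path, parcellation: Parcellation
) -> Connectome:
    from .parcellation import euclidean_distance_matrix

    n = parcellation.n_nodes
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in read_edge_list(edge_path, n):
        adj[i, j] = adj[j, i] = 1
    return Connectome(adj, euclidean_distance_matrix(parcellation), parcellation=parcellation)


def write_scan_table(scans: ScanTable, meta_path: str | Path, ct_path: str | Path) -> None:
    scans.meta.to_csv(meta_path, index=False)
    pd.DataFrame(scans.ct).to_csv(ct_path, index=False)


def read_scan_table(meta_path: str | Path, ct_path: str | Path) -> ScanTable:
    meta = pd.read_csv(meta_path)
    required = {"subject", "scan_index", "age", "sex", "group"}
    if not required <= set(meta.columns):
        raise ValueError(f"scan metadata must contain columns {sorted(required)}")
    ct = pd.read_csv(ct_path).to_numpy(float)
    if len(meta) != ct.shape[0]:
        raise ValueError("scan metadata rows and CT matrix rows must match")
    return ScanTable(meta=meta, ct=ct)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(matrix)).to_csv(path, index=False)


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(float)


def write_gene_panel(
    panel: GenePanel, expr_path: str | Path, samples_path: str | Path, sets_path: str | Path
) -> None:
    panel.expression.to_csv(expr_path)
    panel.samples.to_csv(samples_path, index=False)
    Path(sets_path).write_text(json.dumps(panel.gene_sets, indent=1))


def read_gene_panel(
    expr_path: str | Path, samples_path: str | Path, sets_path: str | Path
) -> GenePanel:
    expression = pd.read_csv(expr_path, index_col=0)
    if expression.isna().any().any():
        raise ValueError("gene panel contains missing expression values")
    samples = pd.read_csv(samples_path)
    gene_sets = json.loads(Path(sets_path).read_text())
    return GenePanel(expression=expression, samples=samples, gene_sets=gene_sets)


def write_maturation_map(map_obj, path: str | Path) -> None:
    df = pd.DataFrame({"node_id": np.arange(map_obj.value.size), "value": map_obj.value})
    if map_obj.p_value is not None:
        df["p"] = map_obj.p_value
    if map_obj.significance_mask is not None:
        df["mask"] = map_obj.significance_mask.astype(int)
    df.to_csv(path, index=False)
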