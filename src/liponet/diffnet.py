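"""Node connectivity, differential connectivity, and topology profiling.

Connectivity of a node is the sum of the absolute weights of its significant
edges.  Differential connectivity between two group networks subtracts the
per-node connectivities and standardizes the differences across the panel;
nodes beyond |z| > 2 are flagged as differentially connected.

Topology profiles collect standard unweighted graph measures per node
(computed on the binarized masked network) and are compared across
conditions by per-node cosine distance after joint min-max scaling, and by
joint PCA of the node x measure matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .dimensionality import PcaModel, fit_pca
from .network import AssociationNetwork
from .preprocess import autoscale

#: The measures computed by default.
DEFAULT_MEASURES = (
    "Average Shortest Path Length",
    "Betweenness Centrality",
    "Closeness Centrality",
    "Clustering Coefficient",
    "Degree",
    "Eccentricity",
    "Neighborhood Connectivity",
    "Number of Undirected Edges",
    "Radiality",
    "Stress",
    "Topological Coefficient",
)

#: Additional standard measures available through the ``measures`` argument.
EXTRA_MEASURES = (
    "Degree Centrality",
    "Harmonic Closeness",
    "Local Efficiency",
    "Eccentricity Centrality",
)


# --------------------------------------------------------------------------
# connectivity and differential connectivity
# --------------------------------------------------------------------------

def connectivity(net: AssociationNetwork) -> pd.Series:
    """Per-node sum of absolute significant edge weights (self-term removed)."""
    w = np.abs(net.weights).sum(axis=1) - np.abs(np.diag(net.weights))
    return pd.Series(w, index=net.nodes, name="connectivity")


@dataclass
class DiffConnectivityReport:
    """Per-node connectivity difference, z-score and selection flag."""

    table: pd.DataFrame  # columns: connectivity_a, connectivity_b, delta, z, selected
    degenerate: bool = False


def differential_connectivity(
    net_a: AssociationNetwork,
    net_b: AssociationNetwork,
    z_threshold: float = 2.0,
) -> DiffConnectivityReport:
    """Delta_i = X_i(A) - X_i(B), z-scored across the panel (sample sd).

    Identical networks give all-zero differences; the z-scores are then
    undefined and the report is returned all-null with a warning.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("networks must share the same node set and order")
    xa = connectivity(net_a)
    xb = connectivity(net_b)
    delta = xa - xb
    sd = float(delta.std(ddof=1))
    degenerate = sd == 0
    if degenerate:
        warnings.warn(
            "all connectivity differences are zero: z-scores undefined",
            stacklevel=2,
        )
        z = pd.Series(np.nan, index=delta.index)
        selected = pd.Series(False, index=delta.index)
    else:
        z = (delta - delta.mean()) / sd
        selected = z.abs() > z_threshold
    table = pd.DataFrame(
        {
            "connectivity_a": xa,
            "connectivity_b": xb,
            "delta": delta,
            "z": z,
            "selected": selected,
        }
    )
    return DiffConnectivityReport(table=table, degenerate=degenerate)


# --------------------------------------------------------------------------
# topology measures
# --------------------------------------------------------------------------

def _per_component(g: nx.Graph):
    for comp in nx.connected_components(g):
        yield g.subgraph(comp), comp


def _stress(g: nx.Graph) -> dict:
    """Number of shortest paths passing through each node (endpoints excluded)."""
    stress = dict.fromkeys(g, 0)
    for sub, comp in _per_component(g):
        nodes = list(comp)
        for s, t in combinations(nodes, 2):
            for path in nx.all_shortest_paths(sub, s, t):
                for v in path[1:-1]:
                    stress[v] += 1
    return stress


def _topological_coefficient(g: nx.Graph) -> dict:
    tc = {}
    for v in g:
        neighbors = set(g[v])
        if len(neighbors) < 2:
            tc[v] = 0.0
            continue
        shared = []
        for u in g:
            if u == v:
                continue
            overlap = len(neighbors & set(g[u]))
            if overlap > 0:
                shared.append(overlap + (1 if g.has_edge(u, v) else 0))
        tc[v] = float(np.mean(shared)) / len(neighbors) if shared else 0.0
    return tc


def _topology_measures(g: nx.Graph) -> dict[str, dict]:
    n = g.number_of_nodes()
    degree = dict(g.degree())

    aspl = dict.fromkeys(g, 0.0)
    ecc = dict.fromkeys(g, 0.0)
    radiality = dict.fromkeys(g, 0.0)
    for sub, comp in _per_component(g):
        if sub.number_of_nodes() < 2:
            continue
        spl = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in spl.values())
        for v in comp:
            others = [d for u, d in spl[v].items() if u != v]
            aspl[v] = float(np.mean(others))
            ecc[v] = float(max(others))
            if diam > 0 and n > 1:
                radiality[v] = sum(diam + 1 - d for d in others) / ((n - 1) * diam)

    neigh_conn = {
        v: (float(np.mean([degree[u] for u in g[v]])) if degree[v] > 0 else 0.0)
        for v in g
    }
    ecc_centrality = {v: (1.0 / e if e > 0 else 0.0) for v, e in ecc.items()}

    return {
        "Average Shortest Path Length": aspl,
        "Betweenness Centrality": nx.betweenness_centrality(g, normalized=True),
        "Closeness Centrality": nx.closeness_centrality(g, wf_improved=False),
        "Clustering Coefficient": nx.clustering(g),
        "Degree": {v: float(d) for v, d in degree.items()},
        "Eccentricity": ecc,
        "Neighborhood Connectivity": neigh_conn,
        "Number of Undirected Edges": {v: float(d) for v, d in degree.items()},
        "Radiality": radiality,
        "Stress": {v: float(s) for v, s in _stress(g).items()},
        "Topological Coefficient": _topological_coefficient(g),
        "Degree Centrality": nx.degree_centrality(g) if n > 1 else dict.fromkeys(g, 0.0),
        "Harmonic Closeness": {
            v: h / (n - 1) if n > 1 else 0.0
            for v, h in nx.harmonic_centrality(g).items()
        },
        "Local Efficiency": {
            v: (nx.global_efficiency(g.subgraph(g[v])) if degree[v] > 1 else 0.0)
            for v in g
        },
        "Eccentricity Centrality": ecc_centrality,
    }


@dataclass
class TopologyProfile:
    """Node x measure matrix for one network (unweighted graph measures)."""

    table: pd.DataFrame
    condition: str = ""

    @property
    def measures(self) -> list[str]:
        return list(self.table.columns)


def topology_profile(
    net: AssociationNetwork,
    measures: tuple[str, ...] = DEFAULT_MEASURES,
    condition: str | None = None,
) -> TopologyProfile:
    """Compute the selected topology measures on the binarized network."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    idx = np.argwhere(np.triu(net.weights, k=1) != 0)
    g.add_edges_from((net.nodes[i], net.nodes[j]) for i, j in idx)
    everything = _topology_measures(g)
    unknown = set(measures) - set(everything)
    if unknown:
        raise ValueError(f"unknown topology measure(s): {sorted(unknown)}")
    table = pd.DataFrame(
        {name: everything[name] for name in measures}
    ).loc[list(net.nodes)]
    return TopologyProfile(
        table=table,
        condition=condition or str(net.metadata.get("group", "")),
    )


# --------------------------------------------------------------------------
# cross-condition node comparison
# --------------------------------------------------------------------------

def node_topology_distance(
    prof_a: TopologyProfile,
    prof_b: TopologyProfile,
) -> pd.DataFrame:
    """Per-node cosine distance between two topology profiles.

    The two profiles are min-max scaled jointly per measure (so large-scale
    measures such as Stress do not dominate the angle), then
    ``d_i = 1 - cos(v_i^A, v_i^B)`` is computed per node and z-scored across
    nodes; selection flags at z > 1 and z > 2 are reported.  A node with a
    zero vector in either profile gets distance 1 with a warning.
    """
    if list(prof_a.table.columns) != list(prof_b.table.columns):
        raise ValueError("profiles must share the same measure set")
    if list(prof_a.table.index) != list(prof_b.table.index):
        raise ValueError("profiles must share the same node set")
    joint = pd.concat([prof_a.table, prof_b.table])
    lo, hi = joint.min(), joint.max()
    span = (hi - lo).replace(0, 1.0)
    a = ((prof_a.table - lo) / span).to_numpy()
    b = ((prof_b.table - lo) / span).to_numpy()
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    d = np.ones(a.shape[0])
    ok = (na > 0) & (nb > 0)
    if not ok.all():
        warnings.warn("zero topology vector: cosine distance set to 1", stacklevel=2)
    d[ok] = 1.0 - np.sum(a[ok] * b[ok], axis=1) / (na[ok] * nb[ok])
    d = np.clip(d, 0.0, 2.0)
    sd = d.std(ddof=1)
    z = (d - d.mean()) / sd if sd > 0 else np.full_like(d, np.nan)
    return pd.DataFrame(
        {
            "cosine_distance": d,
            "z": z,
            "selected_z1": np.nan_to_num(z) > 1,
            "selected_z2": np.nan_to_num(z) > 2,
        },
        index=prof_a.table.index,
    )


def topology_pca(
    profiles: dict[str, TopologyProfile],
) -> tuple[PcaModel, pd.DataFrame]:
    """Joint PCA of node x measure matrices from several conditions.

    Rows are (node, condition) pairs, columns the shared measures; constant
    measure columns are dropped with a warning, the rest autoscaled, and a
    single PCA is fitted so paired nodes are directly comparable in score
    space.  Returns the model and a row-annotation frame (node, condition).
    """
    if len(profiles) < 2:
        raise ValueError("need profiles from at least two conditions")
    frames, meta = [], []
    for cond, prof in profiles.items():
        frames.append(prof.table)
        meta.extend((node, cond) for node in prof.table.index)
    stacked = pd.concat(frames, ignore_index=True)
    constant = stacked.columns[stacked.std(ddof=1) == 0]
    if len(constant):
        warnings.warn(
            f"constant measure column(s) dropped: {list(constant)}", stacklevel=2
        )
        stacked = stacked.drop(columns=constant)
    model = fit_pca(autoscale(stacked).to_numpy())
    annotation = pd.DataFrame(meta, columns=["node", "condition"])
    return model, annotation
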