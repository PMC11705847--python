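"""Thresholded Spearman co-occurrence networks and keystone-role analysis.

Edges are retained when |rho| >= rho_min AND p < p_max on relative
abundances; modules come from Louvain modularity maximization on the
unsigned graph; node roles follow the Zi/Pi threshold rules
(network hub: Zi > 2.5 & Pi > 0.62; module hub: Zi > 2.5 & Pi <= 0.62;
connector: Zi <= 2.5 & Pi > 0.62; peripheral otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import OtuTable, SampleMetadata

__all__ = [
    "CorrelationGraph",
    "correlation_graph",
    "detect_modules",
    "topology",
    "zi_pi",
    "classify_roles",
    "subnetworks",
    "write_graphml",
    "write_edge_list",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class CorrelationGraph:
    """Thresholded undirected co-occurrence graph."""

    graph: nx.Graph
    rho_min: float
    p_max: float
    modules: dict[str, int] | None = None
    modularity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_signs(self) -> tuple[int, int]:
        pos = sum(1 for *_, d in self.graph.edges(data=True) if d["sign"] == "positive")
        return pos, self.graph.number_of_edges() - pos


def correlation_graph(
    table: OtuTable,
    rho_min: float = 0.6,
    p_max: float = 0.01,
    min_prevalence: float = 0.0,
) -> CorrelationGraph:
    """All-pairs Spearman correlation network on relative abundances.

    Taxa below `min_prevalence` (fraction of samples with a nonzero count)
    are excluded before correlation; constant taxa are skipped with a
    warning. Needs >= 8 samples for meaningful Spearman p-values.
    """
    if table.n_samples < 8:
        raise ValueError("correlation network needs >= 8 samples")
    prevalence = table.presence().mean(axis=1)
    keep = prevalence >= min_prevalence
    rel = table.relative_abundance()[keep]
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    constant = rel.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"skipping {int(constant.sum())} constant taxa", stacklevel=2
        )
        rel = rel[~constant]
        taxa = [t for t, c in zip(taxa, constant) if not c]
    abund = table.taxon_totals()
    abund_of = dict(zip(table.taxon_ids, abund.tolist()))
    rho, p = stats.spearmanr(rel, axis=1)
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-taxon case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    g = nx.Graph()
    for t in taxa:
        g.add_node(t, abundance=abund_of[t])
    n = len(taxa)
    for i in range(n):
        for j in range(i + 1, n):
            r, pv = rho[i, j], p[i, j]
            if np.isfinite(r) and abs(r) >= rho_min and pv < p_max:
                g.add_edge(
                    taxa[i],
                    taxa[j],
                    rho=float(r),
                    p_value=float(pv),
                    sign="positive" if r > 0 else "negative",
                    weight=abs(float(r)),
                )
    return CorrelationGraph(g, rho_min, p_max)


def detect_modules(cg: CorrelationGraph, seed: int = 0, weighted: bool = False) -> CorrelationGraph:
    """Louvain modularity maximization (unsigned; unweighted by default)."""
    if cg.n_edges == 0:
        raise ValueError("cannot detect modules on an empty graph")
    weight = "weight" if weighted else None
    communities = nx.community.louvain_communities(cg.graph, weight=weight, seed=seed)
    modules = {}
    for m, members in enumerate(communities):
        for node in members:
            modules[node] = m
    q = nx.community.modularity(cg.graph, communities, weight=weight)
    cg.modules = modules
    cg.modularity = float(q)
    nx.set_node_attributes(cg.graph, modules, "module")
    return cg


def topology(cg: CorrelationGraph) -> tuple[dict, pd.DataFrame]:
    """Network-level metrics plus per-node degree/betweenness/clustering."""
    g = cg.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        raise ValueError("empty graph")
    pos, neg = cg.edge_signs()
    if n > 1:
        components = list(nx.connected_components(g))
        lcc = g.subgraph(max(components, key=len))
        avg_path = (
            nx.average_shortest_path_length(lcc) if lcc.number_of_nodes() > 1 else 0.0
        )
    else:
        avg_path = 0.0
    net = {
        "n_nodes": n,
        "n_edges": e,
        "avg_degree": 2 * e / n,
        "density": 2 * e / (n * (n - 1)) if n > 1 else 0.0,
        "avg_clustering": nx.average_clustering(g),
        "avg_path_length_lcc": float(avg_path),
        "modularity": cg.modularity,
        "positive_edge_fraction": pos / e if e else float("nan"),
        "n_positive_edges": pos,
        "n_negative_edges": neg,
    }
    betweenness = nx.betweenness_centrality(g)
    clustering = nx.clustering(g)
    nodes = pd.DataFrame(
        {
            "taxon": list(g.nodes),
            "degree": [g.degree(v) for v in g.nodes],
            "betweenness": [betweenness[v] for v in g.nodes],
            "clustering": [clustering[v] for v in g.nodes],
        }
    )
    return net, nodes


def zi_pi(cg: CorrelationGraph, modules: dict[str, int] | None = None) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    Zi standardizes a node's within-module degree against its module's
    members (population sd; sd = 0 gives Zi = 0). Pi = 1 - sum_t (k_it/k_i)^2
    over modules t; isolated nodes get Pi = 0.
    """
    if modules is None:
        modules = cg.modules
    if modules is None:
        raise ValueError("no module assignment; run detect_modules first")
    g = cg.graph
    unassigned = [v for v in g.nodes if v not in modules]
    if unassigned:
        raise ValueError(f"nodes without module assignment: {unassigned[:5]}")
    nodes = list(g.nodes)
    within_degree = {}
    for v in nodes:
        within_degree[v] = sum(1 for u in g.neighbors(v) if modules[u] == modules[v])
    zi = {}
    for m in set(modules.values()):
        members = [v for v in nodes if modules[v] == m]
        kd = np.array([within_degree[v] for v in members], dtype=float)
        mean, sd = kd.mean(), kd.std()  # population sd
        for v, k in zip(members, kd):
            zi[v] = (k - mean) / sd if sd > 0 else 0.0
    pi = {}
    for v in nodes:
        k = g.degree(v)
        if k == 0:
            pi[v] = 0.0
            continue
        per_module: dict[int, int] = {}
        for u in g.neighbors(v):
            per_module[modules[u]] = per_module.get(modules[u], 0) + 1
        pi[v] = 1.0 - sum((c / k) ** 2 for c in per_module.values())
    return pd.DataFrame(
        {
            "taxon": nodes,
            "module": [modules[v] for v in nodes],
            "Zi": [zi[v] for v in nodes],
            "Pi": [pi[v] for v in nodes],
        }
    )


def classify_roles(zipi: pd.DataFrame) -> pd.DataFrame:
    """Assign keystone roles from (Zi, Pi) thresholds.

    Boundary handling follows the quoted rule text literally: Zi = 2.5 is
    not a hub; Pi = 0.62 is not a connector.
    """
    def role(zi: float, pi: float) -> str:
        if zi > ZI_THRESHOLD:
            return "network_hub" if pi > PI_THRESHOLD else "module_hub"
        return "connector" if pi > PI_THRESHOLD else "peripheral"

    out = zipi.copy()
    out["role"] = [role(z, p) for z, p in zip(out["Zi"], out["Pi"])]
    return out


def subnetworks(
    cg: CorrelationGraph,
    table: OtuTable,
    metadata: SampleMetadata,
    by: str,
) -> dict[str, CorrelationGraph]:
    """Induce one subgraph per metadata group on the taxa present there.

    Sub-networks inherit the parent's edges (no re-thresholding); a group
    whose taxa are absent from the graph yields an empty subgraph warning.
    """
    labels = metadata.groups(table, by)
    out = {}
    for g in np.unique(labels):
        cols = labels == g
        present = table.presence()[:, cols].any(axis=1)
        taxa = {t for t, p in zip(table.taxon_ids, present) if p}
        nodes = [v for v in cg.graph.nodes if v in taxa]
        if not nodes:
            warnings.warn(f"group {g!r} induces an empty subgraph", stacklevel=2)
        sub = CorrelationGraph(
            cg.graph.subgraph(nodes).copy(), cg.rho_min, cg.p_max
        )
        out[str(g)] = sub
    return out


def write_edge_list(cg: CorrelationGraph, path) -> None:
    rows = [
        {"source": u, "target": v, "rho": d["rho"], "p": d["p_value"], "sign": d["sign"]}
        for u, v, d in cg.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(cg: CorrelationGraph, path) -> None:
    """Gephi-compatible GraphML export."""
    nx.write_graphml(cg.graph, path)
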