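"""Pearson co-occurrence network inference and graph summaries.

Edges are admitted when |r| exceeds a cutoff (0.58 in the reference
setting) AND the two-sided p-value of the correlation is below a cutoff
(0.05); note the absolute-value rule — co-occurrence networks carry both
positive and negative edges.  At n = 12 observations the r-rule dominates:
|r| > 0.58 already implies p < 0.05.

``average_degree_paper`` is edges/nodes (the convention under which a
19-node, 88-edge graph has average degree 4.632); the standard mean degree
2E/N is reported alongside.  Communities come from Louvain modularity
optimisation on the unweighted, unsigned graph; the modularity value
Q = Σ_c (e_c/m − (d_c/2m)²) is computed by this module's own evaluator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .io_model import SampleTable, ValidationError

logger = logging.getLogger(__name__)

MODES = ("enzyme-ion", "ion-ion", "all")


@dataclass(frozen=True)
class CorrelationResult:
    """All-pairs Pearson correlations with two-sided p-values."""

    variable_ids: tuple
    categories: tuple
    r: np.ndarray
    p: np.ndarray
    n_obs: int
    dropped: tuple = ()

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.p, dtype=float)
        k = len(self.variable_ids)
        if r.shape != (k, k) or p.shape != (k, k):
            raise ValidationError("correlation matrices must be square over variables")
        if not np.allclose(r, r.T, atol=1e-12) or not np.allclose(p, p.T, atol=1e-12):
            raise ValidationError("correlation matrices must be symmetric")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValidationError("|r| must be <= 1")
        if not np.allclose(np.diag(r), 1.0):
            raise ValidationError("correlation diagonal must be 1")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)


def pearson_matrix(table: SampleTable, sample_ids=None) -> CorrelationResult:
    """All-pairs Pearson r with p from t = r·sqrt(n−2)/sqrt(1−r²).

    Zero-variance variables are dropped with a warning and recorded in
    ``dropped``.  Needs at least 4 observations.
    """
    if sample_ids is not None:
        table = table.subset_samples(list(sample_ids))
    if table.n_samples < 4:
        raise ValidationError(
            f"need >= 4 samples for correlation, got {table.n_samples}"
        )
    values = np.asarray(table.values, dtype=float)
    variances = values.var(axis=0)
    keep = variances > 0
    dropped = tuple(v for v, k in zip(table.variable_ids, keep) if not k)
    if dropped:
        logger.warning("dropping zero-variance variables: %s", ", ".join(dropped))
    values = values[:, keep]
    variable_ids = tuple(v for v, k in zip(table.variable_ids, keep) if k)
    categories = tuple(c for c, k in zip(table.categories, keep) if k)

    n = values.shape[0]
    r = np.corrcoef(values, rowvar=False)
    r = np.clip(np.atleast_2d(r), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2.0
    return CorrelationResult(variable_ids, categories, r, p, n, dropped)


@dataclass
class CorrelationNetwork:
    """Signed co-occurrence graph; nodes are variables with >= 1 admitted
    edge (isolated variables are excluded from the node set)."""

    graph: nx.Graph
    mode: str
    r_cutoff: float
    p_cutoff: float
    communities: dict | None = None
    modularity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _pair_eligible(cat_u: str, cat_v: str, mode: str) -> bool:
    if mode == "enzyme-ion":
        return {cat_u, cat_v} == {"enzyme", "ion"}
    if mode == "ion-ion":
        return cat_u == cat_v == "ion"
    return True  # "all"


def build_network(
    corr: CorrelationResult,
    r_cutoff: float = 0.58,
    p_cutoff: float = 0.05,
    mode: str = "enzyme-ion",
) -> CorrelationNetwork:
    """Admit edge (u, v) iff |r_uv| > r_cutoff and p_uv < p_cutoff, among
    mode-eligible pairs; record the correlation sign on each edge."""
    if not 0.0 <= r_cutoff < 1.0:
        raise ValidationError(f"r_cutoff must be in [0, 1), got {r_cutoff}")
    if not 0.0 < p_cutoff <= 1.0:
        raise ValidationError(f"p_cutoff must be in (0, 1], got {p_cutoff}")
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")

    graph = nx.Graph()
    k = len(corr.variable_ids)
    for i in range(k):
        for j in range(i + 1, k):
            if not _pair_eligible(corr.categories[i], corr.categories[j], mode):
                continue
            r_ij = float(corr.r[i, j])
            if abs(r_ij) > r_cutoff and float(corr.p[i, j]) < p_cutoff:
                u, v = corr.variable_ids[i], corr.variable_ids[j]
                graph.add_node(u, category=corr.categories[i])
                graph.add_node(v, category=corr.categories[j])
                graph.add_edge(u, v, r=r_ij,
                               sign="positive" if r_ij > 0 else "negative")
    for node, degree in graph.degree():
        graph.nodes[node]["degree"] = int(degree)
    return CorrelationNetwork(graph, mode, r_cutoff, p_cutoff)


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    average_degree_paper: float
    average_degree_standard: float
    average_path_length: float
    diameter: float
    cumulative_degree_distribution: dict
    n_communities: int
    modularity: float
    path_metrics_defined: bool = True


def network_stats(net: CorrelationNetwork) -> NetworkStats:
    """Summary statistics; path length and diameter are taken over
    connected pairs / components of the unweighted graph."""
    graph = net.graph
    n_nodes, n_edges = graph.number_of_nodes(), graph.number_of_edges()
    if n_edges == 0:
        return NetworkStats(0, 0, 0, 0, float("nan"), float("nan"),
                            float("nan"), float("nan"), {}, 0, float("nan"),
                            path_metrics_defined=False)
    signs = [data["sign"] for _, _, data in graph.edges(data=True)]
    n_positive = sum(s == "positive" for s in signs)

    total_dist, total_pairs, diameter = 0.0, 0, 0
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        if sub.number_of_nodes() < 2:
            continue
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        for u, targets in lengths.items():
            for v, dist in targets.items():
                if u < v:
                    total_dist += dist
                    total_pairs += 1
                    diameter = max(diameter, dist)
    avg_path = total_dist / total_pairs if total_pairs else float("nan")

    degrees = np.array([d for _, d in graph.degree()], dtype=int)
    cumulative = {
        int(k): float(np.mean(degrees >= k)) for k in range(1, int(degrees.max()) + 1)
    }
    if net.communities is not None:
        n_comm = len(set(net.communities.values()))
        modularity = float(net.modularity)
    else:
        n_comm, modularity = 0, float("nan")
    return NetworkStats(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_positive=n_positive,
        n_negative=n_edges - n_positive,
        average_degree_paper=n_edges / n_nodes,
        average_degree_standard=2.0 * n_edges / n_nodes,
        average_path_length=avg_path,
        diameter=float(diameter),
        cumulative_degree_distribution=cumulative,
        n_communities=n_comm,
        modularity=modularity,
    )


def modularity_score(graph: nx.Graph, communities: dict) -> float:
    """Q = Σ_c (e_c/m − (d_c/2m)²) over communities c of an unweighted graph."""
    m = graph.number_of_edges()
    if m == 0:
        raise ValidationError("modularity undefined for an edgeless graph")
    by_community: dict = {}
    for node, comm in communities.items():
        by_community.setdefault(comm, set()).add(node)
    q = 0.0
    for members in by_community.values():
        e_c = sum(1 for u, v in graph.edges(members) if u in members and v in members)
        d_c = sum(deg for _, deg in graph.degree(members))
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return q


def detect_communities(net: CorrelationNetwork, seed: int = 0, resolution: float = 1.0):
    """Louvain community detection (unweighted, unsigned); deterministic
    for a fixed seed.  Returns (node → community id, modularity) and
    annotates the network in place."""
    if net.graph.number_of_edges() == 0:
        raise ValidationError("community detection requires at least one edge")
    partition = nx.community.louvain_communities(
        net.graph, weight=None, resolution=resolution, seed=int(seed)
    )
    # stable community ids: order communities by their lexicographically
    # smallest member
    ordered = sorted(partition, key=lambda members: min(members))
    communities = {node: idx for idx, members in enumerate(ordered) for node in members}
    q = modularity_score(net.graph, communities)
    net.communities = communities
    net.modularity = q
    for node, comm in communities.items():
        net.graph.nodes[node]["community"] = int(comm)
    return communities, q


def identify_generalists(net: CorrelationNetwork, top_k: int | None = None) -> list:
    """Nodes ranked by degree (descending, ties broken lexicographically),
    each with its fraction of negative incident edges."""
    rows = []
    for node in net.graph.nodes:
        degree = net.graph.degree(node)
        negative = sum(
            1 for _, _, data in net.graph.edges(node, data=True)
            if data["sign"] == "negative"
        )
        rows.append({
            "variable_id": node,
            "category": net.graph.nodes[node].get("category", ""),
            "degree": int(degree),
            "negative_fraction": negative / degree if degree else float("nan"),
        })
    rows.sort(key=lambda row: (-row["degree"], row["variable_id"]))
    return rows[:top_k] if top_k is not None else rows


def export_network(net: CorrelationNetwork, path, format: str = "gexf") -> None:
    """Write the graph (with node/edge attributes) as GEXF, GraphML or a
    tab-separated edge list."""
    if format == "gexf":
        nx.write_gexf(net.graph, path)
    elif format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tr\tsign\n")
            for u, v, data in sorted(net.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data['r']:.12g}\t{data['sign']}\n")
    else:
        raise ValidationError(
            f"unknown format {format!r}; expected gexf, graphml or edgelist"
        )


def read_network(path, format: str = "gexf") -> nx.Graph:
    if format == "gexf":
        return nx.read_gexf(path)
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValidationError(f"unknown format {format!r}; expected gexf or graphml")
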