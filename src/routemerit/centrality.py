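"""Twelve node-centrality measures and hub-candidate merge procedures.

The measure set mirrors the CentiScaPe panel commonly used for hub-gene
prioritization: degree, betweenness, closeness, centroid value, stress,
bridging, radiality, eccentricity, eigenvector centrality, clustering
coefficient, topological coefficient and neighborhood connectivity.
Formulas for the less standard measures:

* ``centroid``: ``min_w (gamma_v(w) - gamma_w(v))`` over nodes ``w`` in the
  same component, where ``gamma_v(w)`` counts nodes strictly closer to ``v``
  than to ``w``.
* ``stress``: number of shortest paths passing through the node (endpoints
  excluded), summed over unordered source-target pairs.
* ``bridging``: raw betweenness times the bridging coefficient
  ``(1/deg(v)) / sum_{u in N(v)} 1/deg(u)``.
* ``radiality``: ``sum_w (diam_C + 1 - d(v, w)) / (n_C - 1)`` within the
  node's component ``C``.
* ``eccentricity``: reciprocal of the maximum distance within the component,
  so that larger values mean more central.
* ``topological coefficient``: mean over partners sharing a neighbour of
  ``(shared neighbours + adjacency) / deg(v)``.
* ``closeness``: reciprocal of the total distance to same-component nodes.

Values that are undefined for a node (e.g. closeness of an isolated node)
carry the ``-1`` sentinel.  Betweenness and stress are *raw* counts over
unordered pairs, not normalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEASURES = (
    "degree",
    "betweenness",
    "closeness",
    "centroid",
    "stress",
    "bridging",
    "radiality",
    "eccentricity",
    "eigenvector",
    "clustering coefficient",
    "topological coefficient",
    "neighborhood connectivity",
)

#: measures defined for directed graphs in this implementation
DIRECTED_OK = frozenset(
    {"degree", "betweenness", "closeness", "stress", "eccentricity", "eigenvector"}
)

SENTINEL = -1.0


class ConfigurationError(ValueError):
    pass


def load_graph(path: str | Path, directed: bool = False) -> nx.Graph:
    """Read a graph from a 2/3-column tab-separated edge list or GraphML.

    Self-loops are dropped after loading.  A third numeric column, when
    present, is stored as the edge ``weight`` (must be positive).
    """
    path = Path(path)
    create = nx.DiGraph if directed else nx.Graph
    if path.suffix.lower() == ".graphml":
        g = nx.read_graphml(path)
        g = create(g)
    else:
        g = create()
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{ln}: need at least two columns")
                u, v = parts[0], parts[1]
                if len(parts) >= 3:
                    w = float(parts[2])
                    if w <= 0:
                        raise ValueError(f"{path}:{ln}: weight must be positive")
                    g.add_edge(u, v, weight=w)
                else:
                    g.add_edge(u, v)
    loops = list(nx.selfloop_edges(g))
    if loops:
        logger.warning("dropping %d self-loop(s)", len(loops))
        g.remove_edges_from(loops)
    return g


def _bfs_counts(g: nx.Graph, nodes: list) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs hop distances and shortest-path counts (unweighted BFS)."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        queue = [s]
        while queue:
            nxt = []
            for u in queue:
                ui = idx[u]
                for w in g.neighbors(u):
                    wi = idx[w]
                    if np.isinf(dist[si, wi]):
                        dist[si, wi] = dist[si, ui] + 1
                        nxt.append(w)
                    if dist[si, wi] == dist[si, ui] + 1:
                        sigma[si, wi] += sigma[si, ui]
            queue = nxt
    return dist, sigma


@dataclass
class CentralityProfile:
    """Per-node centrality values, one column per measure (-1 = undefined)."""

    values: pd.DataFrame

    @property
    def nodes(self) -> list:
        return list(self.values.index)

    @property
    def measures(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="node")


@dataclass
class RankedList:
    """Deduplicated node list with the (measure, rank) pairs that admitted each."""

    entries: list
    provenance: dict

    def __post_init__(self) -> None:
        assert len(self.entries) == len(set(self.entries))
        assert all(self.provenance.get(n) for n in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def compute_centrality_suite(
    graph: nx.Graph, measures: tuple[str, ...] | list[str] = MEASURES
) -> CentralityProfile:
    """Compute the requested centrality measures for every node."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if not measures:
        raise ConfigurationError("measure list is empty")
    unknown = [m for m in measures if m not in MEASURES]
    if unknown:
        raise ConfigurationError(f"unknown measure(s): {unknown}")
    if graph.is_directed():
        bad = [m for m in measures if m not in DIRECTED_OK]
        if bad:
            raise ConfigurationError(
                f"measure(s) {bad} are undirected-only; build the graph undirected "
                "or restrict the measure set"
            )

    nodes = sorted(graph.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    ug = graph.to_undirected() if graph.is_directed() else graph
    need_paths = bool(
        {"betweenness", "closeness", "centroid", "stress", "bridging", "radiality",
         "eccentricity"} & set(measures)
    )
    if need_paths:
        dist, sigma = _bfs_counts(graph, nodes)
        finite = np.isfinite(dist)

    cols: dict[str, np.ndarray] = {}
    deg = np.array([graph.degree(v) for v in nodes], dtype=float)

    for m in measures:
        vals = np.full(n, SENTINEL)
        if m == "degree":
            vals = deg.copy()
        elif m == "betweenness":
            bc = nx.betweenness_centrality(graph, normalized=False)
            vals = np.array([bc[v] for v in nodes])
        elif m == "stress":
            for vi in range(n):
                on_path = (
                    (dist[:, vi][:, None] + dist[vi, :][None, :] == dist)
                    & finite
                )
                contrib = sigma[:, vi][:, None] * sigma[vi, :][None, :] * on_path
                contrib[vi, :] = 0
                contrib[:, vi] = 0
                np.fill_diagonal(contrib, 0)
                total = contrib.sum()
                vals[vi] = total / 2 if not graph.is_directed() else total
        elif m == "closeness":
            for vi in range(n):
                d = dist[vi]
                reach = finite[vi] & (np.arange(n) != vi)
                vals[vi] = 1.0 / d[reach].sum() if reach.any() else SENTINEL
        elif m == "eccentricity":
            for vi in range(n):
                reach = finite[vi] & (np.arange(n) != vi)
                vals[vi] = 1.0 / dist[vi][reach].max() if reach.any() else SENTINEL
        elif m == "radiality":
            for comp in nx.connected_components(ug):
                cn = sorted(comp)
                if len(cn) < 2:
                    continue
                ci = [idx[v] for v in cn]
                sub = dist[np.ix_(ci, ci)]
                diam = sub.max()
                for j, vi in enumerate(ci):
                    vals[vi] = (diam + 1 - sub[j]).sum() - (diam + 1)
                    vals[vi] /= len(cn) - 1
        elif m == "centroid":
            for comp in nx.connected_components(ug):
                cn = sorted(comp)
                if len(cn) < 2:
                    continue
                ci = [idx[v] for v in cn]
                sub = dist[np.ix_(ci, ci)]
                for j, vi in enumerate(ci):
                    best = None
                    for k2, wi in enumerate(ci):
                        if wi == vi:
                            continue
                        others = [
                            u for u in range(len(cn)) if u != j and u != k2
                        ]
                        closer_v = sum(sub[u, j] < sub[u, k2] for u in others)
                        closer_w = sum(sub[u, k2] < sub[u, j] for u in others)
                        f = closer_v - closer_w
                        best = f if best is None else min(best, f)
                    vals[vi] = best
        elif m == "bridging":
            bc = nx.betweenness_centrality(graph, normalized=False)
            for vi, v in enumerate(nodes):
                if deg[vi] == 0:
                    continue
                inv_nbr = sum(1.0 / graph.degree(u) for u in graph.neighbors(v))
                vals[vi] = bc[v] * (1.0 / deg[vi]) / inv_nbr
        elif m == "eigenvector":
            adj = nx.to_numpy_array(ug, nodelist=nodes)
            w, vecs = np.linalg.eigh(adj)
            vec = vecs[:, int(np.argmax(w))]
            if vec.sum() < 0:
                vec = -vec
            vals = np.clip(vec, 0.0, None)
        elif m == "clustering coefficient":
            cc = nx.clustering(ug)
            vals = np.array([cc[v] for v in nodes])
        elif m == "topological coefficient":
            nbrs = {v: set(graph.neighbors(v)) for v in nodes}
            for vi, v in enumerate(nodes):
                if deg[vi] == 0:
                    continue
                js = []
                for u in nodes:
                    if u == v:
                        continue
                    shared = len(nbrs[v] & nbrs[u])
                    if shared:
                        js.append(shared + (1 if graph.has_edge(v, u) else 0))
                vals[vi] = np.mean(js) / deg[vi] if js else SENTINEL
        elif m == "neighborhood connectivity":
            for vi, v in enumerate(nodes):
                if deg[vi] == 0:
                    continue
                vals[vi] = float(np.mean([graph.degree(u) for u in graph.neighbors(v)]))
        cols[m] = vals

    return CentralityProfile(pd.DataFrame(cols, index=nodes)[list(measures)])


def top_k_union(profile: CentralityProfile, k: int) -> RankedList:
    """Union of the top-``k`` nodes of every measure.

    Ties with the k-th score are all included (stable superset) and logged.
    Provenance records, per admitted node, every (measure, rank) that admitted
    it; ranks are 1-based positions after sorting by descending value with
    node identifier as a stable tiebreak.
    """
    if profile.values.empty:
        raise ValueError("empty centrality profile")
    if not (0 < k <= len(profile.nodes)):
        raise ValueError(f"k={k} must be in 1..{len(profile.nodes)}")
    entries: list = []
    provenance: dict = {}
    for measure in profile.measures:
        col = profile.values[measure]
        ordered = sorted(col.items(), key=lambda kv: (-kv[1], str(kv[0])))
        cutoff = ordered[k - 1][1]
        admitted = [(node, val) for node, val in ordered if val >= cutoff]
        if len(admitted) > k:
            logger.info(
                "measure %r: %d nodes tie with the rank-%d score %s",
                measure, len(admitted) - k, k, cutoff,
            )
        for rank, (node, _) in enumerate(admitted, 1):
            provenance.setdefault(node, set()).add((measure, rank))
            if node not in entries:
                entries.append(node)
    return RankedList(entries, provenance)


def merge_and_select(
    lists: list[RankedList], merged_graph: nx.Graph, k_final: int
) -> RankedList:
    """Two-stage merge: union the candidate lists, recompute the full measure
    panel on the union's induced subgraph of ``merged_graph``, and return the
    union of the top-``k_final`` nodes per measure."""
    if not lists:
        raise ValueError("no ranked lists given")
    union: list = []
    for rl in lists:
        for node in rl.entries:
            if node not in union:
                union.append(node)
    missing = [v for v in union if v not in merged_graph]
    if missing:
        logger.warning("%d union node(s) absent from merged graph: %s",
                       len(missing), missing)
        union = [v for v in union if v not in missing]
    if not union:
        raise ValueError("no union node is present in the merged graph")
    sub = merged_graph.subgraph(union).copy()
    profile = compute_centrality_suite(sub, MEASURES)
    if k_final > len(union):
        logger.warning(
            "k_final=%d exceeds union size %d; returning the whole union",
            k_final, len(union),
        )
        k_final = len(union)
    return top_k_union(profile, k_final)
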