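"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles on explicit data
structures: distances by Floyd-Warshall, shortest paths by exhaustive
recursive enumeration over the distance matrix, eigenvectors by power
iteration.  Nothing imports the package's centrality code.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


class BruteForceCentrality:
    """Centralities recomputed naively from an undirected edge list."""

    def __init__(self, nodes, edges):
        self.nodes = sorted(nodes)
        self.idx = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.adj = np.zeros((n, n), dtype=int)
        for u, v in edges:
            if u == v:
                continue
            self.adj[self.idx[u], self.idx[v]] = 1
            self.adj[self.idx[v], self.idx[u]] = 1
        # Floyd-Warshall
        d = np.where(self.adj == 1, 1.0, np.inf)
        np.fill_diagonal(d, 0.0)
        for k in range(n):
            d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
        self.dist = d
        self._paths_cache: dict[tuple[int, int], list[tuple[int, ...]]] = {}

    # -------------------------------------------------------- path machinery
    def shortest_paths(self, s: int, t: int) -> list[tuple[int, ...]]:
        """All shortest s-t paths, enumerated explicitly."""
        key = (s, t)
        if key in self._paths_cache:
            return self._paths_cache[key]
        if not np.isfinite(self.dist[s, t]):
            out: list[tuple[int, ...]] = []
        elif s == t:
            out = [(s,)]
        else:
            out = []
            for u in np.nonzero(self.adj[s])[0]:
                if self.dist[u, t] == self.dist[s, t] - 1:
                    out.extend((s,) + p for p in self.shortest_paths(int(u), t))
        self._paths_cache[key] = out
        return out

    def components(self) -> list[list[int]]:
        seen: set[int] = set()
        comps = []
        for i in range(len(self.nodes)):
            if i in seen:
                continue
            comp = [j for j in range(len(self.nodes)) if np.isfinite(self.dist[i, j])]
            seen.update(comp)
            comps.append(comp)
        return comps

    # ------------------------------------------------------------- measures
    def degree(self):
        return self.adj.sum(axis=1).astype(float)

    def betweenness(self):
        n = len(self.nodes)
        out = np.zeros(n)
        for s, t in combinations(range(n), 2):
            paths = self.shortest_paths(s, t)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(v in p for p in paths)
                out[v] += through / len(paths)
        return out

    def stress(self):
        n = len(self.nodes)
        out = np.zeros(n)
        for s, t in combinations(range(n), 2):
            for p in self.shortest_paths(s, t):
                for v in p[1:-1]:
                    out[v] += 1
        return out

    def closeness(self):
        out = np.full(len(self.nodes), -1.0)
        for v in range(len(self.nodes)):
            ds = [self.dist[v, w] for w in range(len(self.nodes))
                  if w != v and np.isfinite(self.dist[v, w])]
            if ds:
                out[v] = 1.0 / sum(ds)
        return out

    def eccentricity(self):
        out = np.full(len(self.nodes), -1.0)
        for v in range(len(self.nodes)):
            ds = [self.dist[v, w] for w in range(len(self.nodes))
                  if w != v and np.isfinite(self.dist[v, w])]
            if ds:
                out[v] = 1.0 / max(ds)
        return out

    def radiality(self):
        out = np.full(len(self.nodes), -1.0)
        for comp in self.components():
            if len(comp) < 2:
                continue
            diam = max(self.dist[v, w] for v in comp for w in comp)
            for v in comp:
                total = sum(diam + 1 - self.dist[v, w] for w in comp if w != v)
                out[v] = total / (len(comp) - 1)
        return out

    def centroid(self):
        out = np.full(len(self.nodes), -1.0)
        for comp in self.components():
            if len(comp) < 2:
                continue
            for v in comp:
                fs = []
                for w in comp:
                    if w == v:
                        continue
                    others = [u for u in comp if u not in (v, w)]
                    gv = sum(self.dist[u, v] < self.dist[u, w] for u in others)
                    gw = sum(self.dist[u, w] < self.dist[u, v] for u in others)
                    fs.append(gv - gw)
                out[v] = min(fs)
        return out

    def bridging(self):
        deg = self.degree()
        btw = self.betweenness()
        out = np.full(len(self.nodes), -1.0)
        for v in range(len(self.nodes)):
            if deg[v] == 0:
                continue
            nbrs = np.nonzero(self.adj[v])[0]
            out[v] = btw[v] * (1.0 / deg[v]) / sum(1.0 / deg[u] for u in nbrs)
        return out

    def eigenvector(self, iters: int = 20000, tol: float = 1e-14):
        x = np.ones(len(self.nodes))
        x /= np.linalg.norm(x)
        for _ in range(iters):
            y = self.adj @ x
            norm = np.linalg.norm(y)
            if norm == 0:
                return np.zeros_like(x)
            y /= norm
            if np.abs(y - x).max() < tol:
                x = y
                break
            x = y
        if x.sum() < 0:
            x = -x
        return np.clip(x, 0.0, None)

    def clustering(self):
        deg = self.degree()
        out = np.zeros(len(self.nodes))
        for v in range(len(self.nodes)):
            if deg[v] < 2:
                continue
            nbrs = np.nonzero(self.adj[v])[0]
            links = sum(
                self.adj[a, b] for a, b in combinations(nbrs, 2)
            )
            out[v] = 2.0 * links / (deg[v] * (deg[v] - 1))
        return out

    def topological_coefficient(self):
        out = np.full(len(self.nodes), -1.0)
        deg = self.degree()
        for v in range(len(self.nodes)):
            if deg[v] == 0:
                continue
            js = []
            for u in range(len(self.nodes)):
                if u == v:
                    continue
                shared = int((self.adj[v] & self.adj[u]).sum())
                if shared:
                    js.append(shared + self.adj[v, u])
            if js:
                out[v] = float(np.mean(js)) / deg[v]
        return out

    def neighborhood_connectivity(self):
        deg = self.degree()
        out = np.full(len(self.nodes), -1.0)
        for v in range(len(self.nodes)):
            if deg[v] == 0:
                continue
            nbrs = np.nonzero(self.adj[v])[0]
            out[v] = float(np.mean(deg[nbrs]))
        return out

    def all_measures(self) -> dict[str, np.ndarray]:
        return {
            "degree": self.degree(),
            "betweenness": self.betweenness(),
            "closeness": self.closeness(),
            "centroid": self.centroid(),
            "stress": self.stress(),
            "bridging": self.bridging(),
            "radiality": self.radiality(),
            "eccentricity": self.eccentricity(),
            "eigenvector": self.eigenvector(),
            "clustering coefficient": self.clustering(),
            "topological coefficient": self.topological_coefficient(),
            "neighborhood connectivity": self.neighborhood_connectivity(),
        }
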