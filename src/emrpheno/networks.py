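"""Comorbidity co-occurrence networks and node topology metrics.

A group's network has a node for every diagnosis feature shared by
strictly more than a threshold fraction of the group's patients and an
undirected edge for every feature pair co-occurring in strictly more than
that fraction (both endpoints must themselves be nodes).  Six node-level
metrics — degree, closeness centrality, eccentricity, neighborhood
connectivity, stress centrality and topological coefficient — are
computed from scratch with the Network Analyzer conventions:

* closeness of a node is (number of other nodes reachable) divided by the
  sum of shortest-path distances to them, restricted to the node's
  connected component; an isolated node scores 0;
* eccentricity is the maximum shortest-path distance within the component;
* stress counts, over unordered pairs of *other* nodes, the shortest
  paths passing through the node;
* the topological coefficient of n averages J(n, m)/degree(n) over the
  nodes m that share at least one neighbor with n, where J is the shared
  neighbor count plus 1 when n and m are adjacent; nodes of degree < 2
  (or with no qualifying m) score 0.

Metric distributions of two networks are compared per metric with a
two-sided Mann-Whitney U test (asymptotic, tie-corrected, no continuity
correction so identical networks give p = 1 exactly), with singleton
nodes kept or removed.  For cross-site comparison, metrics are z-scored
per metric pooled across all listed networks and correlated between sites
by Spearman rank on per-network mean z (node-level aggregation is also
exposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("degree", "closeness", "eccentricity", "neighborhood_connectivity",
           "stress", "topological_coefficient")


@dataclass
class CoNetwork:
    label: str
    threshold: float
    group_size: int
    nodes: dict[str, float] = field(default_factory=dict)   # feature -> share
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj


def build_conetwork(sets: dict[str, set[str]], threshold: float,
                    label: str = "") -> CoNetwork:
    """Patient-share-thresholded co-occurrence network for one group.

    Shares are strict: a feature (or pair) qualifies only when its share
    exceeds the threshold, so a pair present in exactly 10% of patients is
    excluded at threshold 0.10.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    if not sets:
        raise ValueError("group must be nonempty")
    n = len(sets)
    features = sorted(set().union(*sets.values()) if sets else set())
    idx = {f: j for j, f in enumerate(features)}
    mat = np.zeros((n, len(features)), dtype=np.int32)
    for i, s in enumerate(sets.values()):
        for f in s:
            mat[i, idx[f]] = 1
    shares = mat.mean(axis=0)
    keep = shares > threshold
    nodes = {features[j]: float(shares[j]) for j in np.flatnonzero(keep)}
    kept_idx = np.flatnonzero(keep)
    sub = mat[:, kept_idx]
    co = (sub.T @ sub) / n
    edges = {}
    kept_feats = [features[j] for j in kept_idx]
    for p, q in combinations(range(len(kept_feats)), 2):
        if co[p, q] > threshold:
            u, v = sorted((kept_feats[p], kept_feats[q]))
            edges[(u, v)] = float(co[p, q])
    return CoNetwork(label, threshold, n, nodes, edges)


def _bfs_all(adj: dict[str, set[str]], order: list[str]):
    """All-pairs BFS distances and shortest-path counts (sigma)."""
    n = len(order)
    pos = {u: i for i, u in enumerate(order)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in order:
        si = pos[s]
        dist[si, si] = 0
        sigma[si, si] = 1
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                ui = pos[u]
                for w in adj[u]:
                    wi = pos[w]
                    if np.isinf(dist[si, wi]):
                        dist[si, wi] = d + 1
                        nxt.append(w)
                    if dist[si, wi] == d + 1:
                        sigma[si, wi] += sigma[si, ui]
            frontier = nxt
            d += 1
    return dist, sigma


def node_metrics(network: CoNetwork, drop_singletons: bool = False) -> pd.DataFrame:
    """The six per-node topology metrics, one row per node."""
    adj = network.adjacency()
    if drop_singletons:
        adj = {u: vs for u, vs in adj.items() if vs}
    order = sorted(adj)
    n = len(order)
    if n == 0:
        return pd.DataFrame(columns=list(METRICS))
    pos = {u: i for i, u in enumerate(order)}
    dist, sigma = _bfs_all(adj, order)

    degree = np.array([len(adj[u]) for u in order], dtype=float)
    A = np.zeros((n, n), dtype=np.int64)
    for u in order:
        for v in adj[u]:
            A[pos[u], pos[v]] = 1

    reach = np.isfinite(dist) & ~np.eye(n, dtype=bool)
    closeness = np.zeros(n)
    eccentricity = np.zeros(n, dtype=int)
    for i in range(n):
        r = reach[i]
        if r.any():
            closeness[i] = r.sum() / dist[i, r].sum()
            eccentricity[i] = int(dist[i, r].max())

    neigh_conn = np.array([
        degree[[pos[v] for v in adj[u]]].mean() if adj[u] else 0.0
        for u in order
    ])

    # stress: shortest paths between unordered pairs of other nodes through v
    stress = np.zeros(n)
    finite = np.where(np.isfinite(dist), dist, -1.0)
    for vi in range(n):
        through = (finite[:, vi][:, None] + finite[vi, None, :] == finite) \
            & (finite >= 0) & (finite[:, vi][:, None] > 0) \
            & (finite[vi, None, :] > 0)
        np.fill_diagonal(through, False)
        cnt = np.where(through, sigma[:, vi][:, None] * sigma[vi, None, :], 0.0)
        stress[vi] = cnt.sum() / 2.0

    # topological coefficient
    shared = A @ A  # shared-neighbor counts
    topo = np.zeros(n)
    for i in range(n):
        if degree[i] < 2:
            continue
        js = []
        for m in range(n):
            if m == i or shared[i, m] == 0:
                continue
            js.append(shared[i, m] + (1 if A[i, m] else 0))
        if js:
            topo[i] = np.mean(js) / degree[i]

    return pd.DataFrame({
        "degree": degree.astype(int), "closeness": closeness,
        "eccentricity": eccentricity, "neighborhood_connectivity": neigh_conn,
        "stress": stress, "topological_coefficient": topo,
    }, index=order)


def _mwu_ties_ok(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided MWU, asymptotic tie-corrected without continuity correction
    (z = 0 on identical samples gives p = 1 exactly); degenerate all-equal
    pooled samples return (n1*n2/2, 1.0)."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return len(x) * len(y) / 2.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def compare_networks(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame) -> pd.DataFrame:
    """Per-metric two-sided Mann-Whitney comparison of node metric
    distributions between two networks."""
    if metrics_a.empty or metrics_b.empty:
        raise ValueError("cannot compare an empty network")
    rows = []
    for m in METRICS:
        u, p = _mwu_ties_ok(metrics_a[m].to_numpy(dtype=float),
                            metrics_b[m].to_numpy(dtype=float))
        rows.append({"metric": m, "U": u, "p": p,
                     "n_a": len(metrics_a), "n_b": len(metrics_b)})
    return pd.DataFrame(rows)


def normalize_and_correlate(tables: dict[tuple[str, str], pd.DataFrame],
                            aggregation: str = "network"
                            ) -> tuple[pd.DataFrame, float, float]:
    """Z-score metrics across all listed networks and correlate sites.

    *tables* maps (site, network_role) to a node-metric frame.  Per metric,
    values are z-scored pooled over every (network, node); a constant
    metric z-scores to 0.  With aggregation="network" the cross-site
    Spearman is computed on per-(role, metric) network mean z; with
    "node" on per-(role, metric, node) values present at both sites.
    Requires exactly two sites.
    """
    sites = sorted({site for site, _ in tables})
    if len(sites) != 2:
        raise ValueError("normalize_and_correlate expects networks from exactly 2 sites")
    long = []
    for (site, role), frame in tables.items():
        for m in METRICS:
            for node, v in frame[m].items():
                long.append({"site": site, "role": role, "metric": m,
                             "node": node, "value": float(v)})
    df = pd.DataFrame(long)
    zs = []
    for m, grp in df.groupby("metric"):
        mu, sd = grp["value"].mean(), grp["value"].std(ddof=1)
        z = (grp["value"] - mu) / sd if sd > 0 else pd.Series(0.0, index=grp.index)
        zs.append(z)
    df["z"] = pd.concat(zs).sort_index()

    a, b = sites
    if aggregation == "network":
        mean_z = df.groupby(["site", "role", "metric"])["z"].mean().reset_index()
        piv = mean_z.pivot_table(index=["role", "metric"], columns="site", values="z")
    elif aggregation == "node":
        piv = df.pivot_table(index=["role", "metric", "node"], columns="site",
                             values="z")
    else:
        raise ValueError("aggregation must be 'network' or 'node'")
    piv = piv.dropna()
    if len(piv) < 3:
        raise ValueError("too few shared (role, metric) pairs to correlate")
    rho, p = stats.spearmanr(piv[a], piv[b])
    return df, float(rho), float(p)
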