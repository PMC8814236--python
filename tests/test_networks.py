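"""Co-occurrence networks and the six node topology metrics.

The metric oracle below recomputes every metric at definition level:
exhaustive BFS shortest-path enumeration (explicit path lists for stress)
on graphs small enough to enumerate.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import emrpheno as ep
from emrpheno.networks import CoNetwork, METRICS


def graph_from_edges(nodes, edges):
    net = CoNetwork("test", 0.0, 1, {n: 1.0 for n in nodes},
                    {tuple(sorted(e)): 1.0 for e in edges})
    return net


# ---------------------------------------------------------------------------
# brute-force oracle

def _reachable(adj, s):
    seen, stack = {s}, [s]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def _all_shortest_paths(adj, s, t):
    """Every shortest path s->t by breadth-first enumeration of paths."""
    if s == t:
        return [[s]]
    if t not in _reachable(adj, s):
        return []
    best, out = None, []
    frontier = [[s]]
    while frontier and best is None or (frontier and len(frontier[0]) <= best):
        nxt = []
        for path in frontier:
            for w in sorted(adj[path[-1]]):
                if w in path:
                    continue
                if w == t:
                    if best is None:
                        best = len(path) + 1
                    if len(path) + 1 == best:
                        out.append(path + [w])
                else:
                    nxt.append(path + [w])
        if best is not None:
            nxt = [p for p in nxt if len(p) < best]
        frontier = nxt
    return out


def oracle_metrics(net: CoNetwork) -> pd.DataFrame:
    adj = net.adjacency()
    nodes = sorted(adj)
    paths = {}
    for s, t in combinations(nodes, 2):
        paths[(s, t)] = _all_shortest_paths(adj, s, t)
    rows = {}
    for n in nodes:
        deg = len(adj[n])
        dists = {m: len(ps[0]) - 1
                 for m in nodes if m != n
                 for ps in [paths[tuple(sorted((n, m)))]] if ps}
        reach = len(dists)
        closeness = reach / sum(dists.values()) if reach else 0.0
        ecc = max(dists.values()) if dists else 0
        nc = np.mean([len(adj[m]) for m in adj[n]]) if adj[n] else 0.0
        stress = sum(
            sum(1 for p in ps if n in p[1:-1])
            for (s, t), ps in paths.items() if s != n and t != n)
        js = []
        for m in nodes:
            if m == n:
                continue
            shared = len(adj[n] & adj[m])
            if shared:
                js.append(shared + (1 if m in adj[n] else 0))
        topo = (np.mean(js) / deg) if deg >= 2 and js else 0.0
        rows[n] = dict(degree=deg, closeness=closeness, eccentricity=ecc,
                       neighborhood_connectivity=nc, stress=stress,
                       topological_coefficient=topo)
    return pd.DataFrame.from_dict(rows, orient="index")[list(METRICS)]


def random_graph(rng, n_max=12):
    n = int(rng.integers(2, n_max + 1))
    nodes = [f"n{i}" for i in range(n)]
    p = rng.uniform(0.1, 0.7)
    edges = [(a, b) for a, b in combinations(nodes, 2) if rng.random() < p]
    return graph_from_edges(nodes, edges)


def test_metrics_match_bruteforce_oracle():
    rng = np.random.default_rng(17)
    for _ in range(200):
        net = random_graph(rng)
        got = ep.node_metrics(net).sort_index()
        want = oracle_metrics(net).sort_index()
        pd.testing.assert_frame_equal(got.astype(float), want.astype(float),
                                      atol=1e-12, rtol=0)


def test_triangle_path_and_square_examples():
    tri = ep.node_metrics(graph_from_edges("ABC", [("A", "B"), ("B", "C"),
                                                   ("A", "C")]))
    assert (tri.degree == 2).all()
    assert (tri.eccentricity == 1).all()
    assert (tri.stress == 0).all()

    path = ep.node_metrics(graph_from_edges("ABC", [("A", "B"), ("B", "C")]))
    assert path.loc["B", "stress"] == 1
    assert path.loc["B", "closeness"] == 1.0
    assert path.loc["A", "neighborhood_connectivity"] == 2

    square = ep.node_metrics(graph_from_edges("ABCD",
                                              [("A", "B"), ("B", "C"),
                                               ("C", "D"), ("D", "A")]))
    assert square.loc["A", "topological_coefficient"] == 1.0


def test_build_conetwork_thresholds_strict():
    # 100 patients: X in 12, pair (X,Y) in exactly 10
    sets = {}
    for i in range(100):
        s = set()
        if i < 12:
            s.add("X")
        if i < 20:
            s.add("Y")
        if i < 10:
            s.add("Z")
        sets[f"p{i}"] = s
    net = ep.build_conetwork(sets, 0.10, "g")
    assert "X" in net.nodes and "Y" in net.nodes
    assert "Z" not in net.nodes            # exactly 10% is excluded (strict >)
    assert ("X", "Y") in net.edges         # co-occurrence 12% > 10%
    sets2 = {f"p{i}": ({"A", "B"} if i < 10 else set()) for i in range(100)}
    net2 = ep.build_conetwork(sets2, 0.10, "g")
    assert net2.n_edges == 0               # pair share exactly 10%: no edge

    tiny = ep.build_conetwork({"p1": {"A", "B"}, "p2": {"A", "B"}}, 0.0, "g")
    assert set(tiny.nodes) == {"A", "B"} and ("A", "B") in tiny.edges

    with pytest.raises(ValueError):
        ep.build_conetwork(sets, 1.0, "g")


def test_threshold_monotonicity():
    rng = np.random.default_rng(3)
    sets = {f"p{i}": {f"F{j}" for j in range(15) if rng.random() < 0.3}
            for i in range(200)}
    n1 = ep.build_conetwork(sets, 0.05, "g")
    n2 = ep.build_conetwork(sets, 0.15, "g")
    assert set(n2.nodes) <= set(n1.nodes)
    assert set(n2.edges) <= set(n1.edges)


def test_relabeling_invariance():
    rng = np.random.default_rng(9)
    for _ in range(20):
        net = random_graph(rng, n_max=10)
        perm = {n: f"z{j}" for j, n in enumerate(
            rng.permutation(sorted(net.nodes)))}
        relabeled = graph_from_edges([perm[n] for n in net.nodes],
                                     [(perm[u], perm[v]) for u, v in net.edges])
        a = ep.node_metrics(net).rename(index=perm).sort_index()
        b = ep.node_metrics(relabeled).sort_index()
        pd.testing.assert_frame_equal(a.astype(float), b.astype(float))


def test_compare_identical_networks_p_one():
    net = graph_from_edges("ABCD", [("A", "B"), ("B", "C"), ("C", "D")])
    m = ep.node_metrics(net)
    comp = ep.compare_networks(m, m)
    assert (comp.p == 1.0).all()


def test_drop_singletons_keeps_metric_values():
    net = graph_from_edges("ABCDE", [("A", "B"), ("B", "C")])  # D, E isolated
    kept = ep.node_metrics(net, drop_singletons=False)
    dropped = ep.node_metrics(net, drop_singletons=True)
    assert set(dropped.index) == {"A", "B", "C"}
    pd.testing.assert_frame_equal(kept.loc[["A", "B", "C"]], dropped)


def test_normalize_and_correlate():
    rng = np.random.default_rng(2)
    tables = {}
    base = {}
    for role in ("AD", "control", "AD_F", "AD_M", "ctrl_F", "ctrl_M"):
        net = random_graph(rng, n_max=10)
        base[role] = ep.node_metrics(net)
    for site in ("site_a", "site_b"):
        for role, m in base.items():
            tables[(site, role)] = m  # identical sites
    zdf, rho, p = ep.normalize_and_correlate(tables)
    assert rho == pytest.approx(1.0)
    for metric, grp in zdf.groupby("metric"):
        if grp.z.std(ddof=1) > 0:
            assert grp.z.mean() == pytest.approx(0.0, abs=1e-10)
            assert grp.z.std(ddof=1) == pytest.approx(1.0)
    # independent random metric tables decorrelate
    rhos = []
    for seed in range(30):
        r2 = np.random.default_rng(seed + 100)
        t2 = {(site, role): ep.node_metrics(random_graph(r2))
              for site in ("a", "b") for role in ("x", "y", "z")}
        try:
            _, rho2, _ = ep.normalize_and_correlate(t2)
            rhos.append(abs(rho2))
        except ValueError:
            continue
    assert np.median(rhos) < 0.5
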