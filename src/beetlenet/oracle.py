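"""Brute-force shortest-path enumeration for small graphs.

Independent reference implementation used to validate the centrality
metrics: all shortest paths between every ordered pair are enumerated
explicitly (BFS distances + recursive predecessor expansion), and NCC,
NBC, EBC, path counts and characteristic path length are recomputed from
the raw path lists. Deliberately uses no networkx algorithms beyond graph
storage, and is capped at 12 nodes.
"""

from __future__ import annotations

from collections import deque

MAX_NODES = 12


def _bfs(adj: dict, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return dist


def _adjacency(net) -> dict:
    return {v: sorted(net.neighbors(v)) for v in net.nodes}


def brute_force_paths(net) -> dict:
    """Enumerate every shortest path between every ordered reachable pair.

    Returns ``{(s, t): [path, ...]}`` where each path is a node tuple from
    s to t. Refuses graphs with more than 12 nodes.
    """
    if net.number_of_nodes() > MAX_NODES:
        raise ValueError(f"brute-force enumeration capped at {MAX_NODES} nodes")
    adj = _adjacency(net)
    all_paths: dict = {}
    for s in adj:
        dist = _bfs(adj, s)

        def extend(path):
            u = path[-1]
            yield tuple(path)
            for w in adj[u]:
                if dist.get(w) == dist[u] + 1:
                    yield from extend(path + [w])

        for path in extend([s]):
            t = path[-1]
            if t != s and len(path) - 1 == dist[t]:
                all_paths.setdefault((s, t), []).append(path)
    return all_paths


def oracle_metrics(net) -> dict:
    """Recompute NCC/NBC/EBC and path attributes from enumerated paths.

    Conventions match the main implementation: ordered-pair counting for
    shortest_paths and EBC; NCC and NBC normalised within components.
    """
    paths = brute_force_paths(net)
    nodes = list(net.nodes)

    # component membership via the reachability implied by the path table
    comp_of = {v: {v} for v in nodes}
    for s, t in paths:
        comp_of[s].add(t)

    ncc = {}
    for v in nodes:
        dists = [len(ps[0]) - 1 for (s, t), ps in paths.items() if s == v]
        ncc[v] = (len(dists) / sum(dists)) if dists else 0.0

    nbc = {v: 0.0 for v in nodes}
    for (s, t), ps in paths.items():
        if s > t:  # unordered pairs for node betweenness
            continue
        sigma = len(ps)
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in ps if v in p)
            nbc[v] += through / sigma
    for v in nodes:
        n_comp = len(comp_of[v])
        denom = (n_comp - 1) * (n_comp - 2) / 2.0
        nbc[v] = nbc[v] / denom if denom > 0 else 0.0

    ebc = {tuple(sorted(e)): 0.0 for e in net.edges}
    for (s, t), ps in paths.items():  # ordered pairs
        sigma = len(ps)
        for p in ps:
            for u, w in zip(p[:-1], p[1:]):
                ebc[tuple(sorted((u, w)))] += 1.0 / sigma

    ordered_pairs = len(paths)
    total_len = sum(len(ps[0]) - 1 for ps in paths.values())
    cpl = total_len / ordered_pairs if ordered_pairs else 0.0

    return {
        "ncc": ncc,
        "nbc": nbc,
        "ebc": ebc,
        "shortest_paths": ordered_pairs,
        "characteristic_path_length": cpl,
    }
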