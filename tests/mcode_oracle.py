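"""Brute-force re-derivation of MCODE used as an independent test oracle.

Pure-python adjacency sets; core numbers by iterative peeling; cluster
membership as depth-limited reachability through qualifying vertices —
no shared code with the package implementation.
"""

from __future__ import annotations


def _peel_core_numbers(nodes, adj):
    """k-core numbers by repeatedly removing minimum-degree vertices."""
    deg = {v: len(adj[v] & nodes) for v in nodes}
    alive = set(nodes)
    core = {}
    k = 0
    while alive:
        v = min(alive, key=lambda u: (deg[u], str(u)))
        k = max(k, deg[v])
        core[v] = k
        alive.discard(v)
        for u in adj[v]:
            if u in alive:
                deg[u] -= 1
    return core


def _density(members, adj):
    n = len(members)
    if n < 2:
        return 0.0
    edges = sum(len(adj[v] & members) for v in members) // 2
    return 2.0 * edges / (n * (n - 1))


def _weight(v, adj, degree_cutoff):
    if len(adj[v]) < degree_cutoff:
        return 0.0
    nbhd = adj[v] | {v}
    core = _peel_core_numbers(nbhd, {u: adj[u] & nbhd for u in nbhd})
    kmax = max(core.values())
    top = {u for u, k in core.items() if k >= kmax}
    return kmax * _density(top, {u: adj[u] & top for u in top})


def oracle_mcode(edges, nodes=None, degree_cutoff=2, node_score_cutoff=0.2,
                 k_core=2, max_depth=100):
    """Return [(frozenset members, score)] in the implementation's sort order."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    for v in nodes or []:
        adj.setdefault(v, set())
    if not adj:
        return []

    weights = {v: _weight(v, adj, degree_cutoff) for v in adj}
    order = sorted(adj, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    raw = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1 - node_score_cutoff)
        # membership = depth-limited reachability through qualifying vertices
        members = {seed}
        depth = {seed: 0}
        queue = [seed]
        while queue:
            v = queue.pop(0)
            if depth[v] >= max_depth:
                continue
            for u in adj[v]:
                if u in members or u in assigned:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    depth[u] = depth[v] + 1
                    queue.append(u)
        assigned |= members
        raw.append((seed, members))

    clusters = []
    for seed, members in raw:
        keep = set(members)
        # peel to the k-core
        changed = True
        while changed:
            changed = False
            for v in sorted(keep):
                if len(adj[v] & keep) < k_core:
                    keep.discard(v)
                    changed = True
        if not keep:
            continue
        score = _density(keep, {u: adj[u] & keep for u in keep}) * len(keep)
        if score <= 0:
            continue
        cseed = seed if seed in keep else min(keep)
        clusters.append((frozenset(keep), cseed, score))
    clusters.sort(key=lambda c: (-c[2], -len(c[0]), str(c[1])))
    return [(m, s) for m, _, s in clusters]
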