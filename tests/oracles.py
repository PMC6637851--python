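"""Independent brute-force oracles used to validate the package's algorithms.

These deliberately avoid the package's search/fitting code paths: the MCS
oracle enumerates atom subsets exhaustively, and the LOO oracle refits each
fold with scikit-learn's PLS implementation.
"""

from itertools import combinations

import numpy as np


def _oracle_atoms_compatible(ref, probe, i, j, ring_relaxed):
    a, b = ref.atoms[i], probe.atoms[j]
    if a.element != b.element or a.aromatic != b.aromatic:
        return False
    if ref.in_ring(i) != probe.in_ring(j):
        return False
    if ref.in_ring(i) and not ring_relaxed:
        if not set(ref.ring_sizes(i)) & set(probe.ring_sizes(j)):
            return False
    return True


def brute_force_mcs_size(ref, probe, ring_relaxed=False):
    """Maximum connected common subgraph size by exhaustive enumeration.

    For every ref-connected atom subset (largest first), every injective
    assignment to compatible probe atoms is tried; a hit requires the graph
    of common bonds (equal order on both sides) to connect the subset.
    """
    ref_heavy = ref.heavy_indices
    probe_heavy = probe.heavy_indices
    compat = {i: [j for j in probe_heavy
                  if _oracle_atoms_compatible(ref, probe, i, j, ring_relaxed)]
              for i in ref_heavy}

    def connected_in_ref(subset):
        subset = set(subset)
        seen = {next(iter(subset))}
        frontier = list(seen)
        while frontier:
            k = frontier.pop()
            for n in ref.neighbors(k):
                if n in subset and n not in seen:
                    seen.add(n)
                    frontier.append(n)
        return seen == subset

    def common_edges(subset, assign):
        edges = []
        for a, b in combinations(subset, 2):
            o_ref = ref.bond_order(a, b)
            if o_ref is None:
                continue
            o_probe = probe.bond_order(assign[a], assign[b])
            if o_probe is not None and o_probe == o_ref:
                edges.append((a, b))
        return edges

    def connected_via(subset, edges):
        adj = {k: set() for k in subset}
        for a, b in edges:
            adj[a].add(b)
            adj[b].add(a)
        seen = {subset[0]}
        frontier = [subset[0]]
        while frontier:
            k = frontier.pop()
            for n in adj[k]:
                if n not in seen:
                    seen.add(n)
                    frontier.append(n)
        return len(seen) == len(subset)

    def assignments(subset, pos, assign, used):
        if pos == len(subset):
            yield dict(assign)
            return
        i = subset[pos]
        for j in compat[i]:
            if j in used:
                continue
            assign[i] = j
            used.add(j)
            yield from assignments(subset, pos + 1, assign, used)
            del assign[i]
            used.discard(j)

    upper = min(len(ref_heavy), len(probe_heavy))
    for size in range(upper, 0, -1):
        for subset in combinations(ref_heavy, size):
            if not all(compat[i] for i in subset):
                continue
            if not connected_in_ref(subset):
                continue
            for assign in assignments(list(subset), 0, {}, set()):
                if size == 1 or connected_via(list(subset),
                                              common_edges(subset, assign)):
                    return size
    return 0


def sklearn_loo_q2(X, y, nc):
    """LOO Q² with scikit-learn refits per fold (reference implementation)."""
    from sklearn.cross_decomposition import PLSRegression

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        m = PLSRegression(n_components=min(nc, n - 2), scale=False)
        m.fit(X[keep], y[keep].reshape(-1, 1))
        press += float((m.predict(X[i:i + 1]).ravel()[0] - y[i]) ** 2)
    sstot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sstot, float(np.sqrt(press / n))
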