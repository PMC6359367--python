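"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: full dynamic-programming matrices,
all-pairs loops, reachability by transitive closure, exhaustive spanning
trees. None of it shares code with the package paths it validates.
"""

from __future__ import annotations

from itertools import combinations


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook full-matrix edit distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ai = a[i - 1]
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ai != b[j - 1]),
            )
        prev = cur
    return prev[n]


def brute_force_pairs(sequences: dict[int, str], t: int) -> set[tuple[int, int, int]]:
    """All-vs-all pairs with 1 <= LD <= t, canonical order."""
    out = set()
    for (ia, sa), (ib, sb) in combinations(sorted(sequences.items()), 2):
        d = dp_levenshtein(sa, sb)
        if 1 <= d <= t:
            a, b = sorted((ia, ib))
            out.add((a, b, d))
    return out


def brute_force_components(vertex_ids, edges) -> list[frozenset[int]]:
    """Connected components by repeated reachability expansion."""
    adj: dict[int, set[int]] = {v: set() for v in vertex_ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    unseen = set(vertex_ids)
    comps = []
    while unseen:
        frontier = {min(unseen)}
        comp: set[int] = set()
        while frontier:
            comp |= frontier
            frontier = set().union(*(adj[v] for v in frontier)) - comp
        comps.append(frozenset(comp))
        unseen -= comp
    return sorted(comps, key=min)


def all_spanning_tree_weights(vertices, weighted_edges) -> list[int]:
    """Total weights of every spanning tree, by exhaustive edge-subset search.

    Only usable on tiny graphs; used to certify MST minimality.
    """
    n = len(vertices)
    weights = []
    for subset in combinations(weighted_edges, n - 1):
        comps = brute_force_components(vertices, [(a, b) for a, b, _ in subset])
        if len(comps) == 1:
            weights.append(sum(w for _, _, w in subset))
    return weights


def brute_force_sweep(
    sequences: dict[int, str],
    ratios_fn,
    t_values,
    min_component_size: int = 3,
    ratio_cutoff: float = 0.3,
):
    """Low-ratio vertex tallies per threshold, computed from first principles.

    ``ratios_fn(member_ids) -> float`` supplies the HCDR3 ratio of a
    vertex set, so the oracle stays agnostic of annotation internals.
    """
    out = {}
    for t in t_values:
        edges = [(a, b) for a, b, _ in brute_force_pairs(sequences, t)]
        comps = brute_force_components(sequences.keys(), edges)
        low = 0
        for comp in comps:
            if len(comp) < min_component_size:
                continue
            if ratios_fn(comp) < ratio_cutoff:
                low += len(comp)
        out[t] = low
    return out
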