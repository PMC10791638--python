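"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — plain dict/loop counting with no
shared code or vectorization — so they can certify the package's fast
paths on small instances.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence


def brute_sri_counts(
    observations: Mapping[object, Mapping[str, str]], bats: Sequence[str]
):
    """Per-dyad (x, y_ab, y_a, y_b) and SRI from day -> {bat: roost} maps."""
    out = {}
    for a, b in itertools.combinations(bats, 2):
        x = yab = ya = yb = 0
        for day_map in observations.values():
            in_a, in_b = a in day_map, b in day_map
            if in_a and in_b:
                if day_map[a] == day_map[b]:
                    x += 1
                else:
                    yab += 1
            elif in_a:
                ya += 1
            elif in_b:
                yb += 1
        den = x + yab + ya + yb
        sri = x / den if den else 0.0
        out[(a, b)] = (x, yab, ya, yb, sri)
    return out


def brute_lar(
    observations: Mapping[int, Mapping[str, str]],
    bats: Sequence[str],
    max_lag: int,
):
    """Per-lag (numerator, denominator) by quadruple loop.

    ``observations`` maps integer day -> {bat: roost}.  Ordered pairs;
    numerator counts (i, j, t) associated at t and t+tau, denominator
    counts (i, j, t) associated at t with i observed at t+tau.
    """
    days = sorted(observations)
    num = {tau: 0 for tau in range(1, max_lag + 1)}
    den = {tau: 0 for tau in range(1, max_lag + 1)}
    for t1 in days:
        for t2 in days:
            tau = t2 - t1
            if tau < 1 or tau > max_lag:
                continue
            d1, d2 = observations[t1], observations[t2]
            for i in bats:
                for j in bats:
                    if i == j:
                        continue
                    assoc_t1 = i in d1 and j in d1 and d1[i] == d1[j]
                    if not assoc_t1:
                        continue
                    if i in d2:
                        den[tau] += 1
                        if j in d2 and d2[i] == d2[j]:
                            num[tau] += 1
    return num, den


def brute_null_rate(associates: Mapping[str, set]) -> float:
    """Mean degree / (N - 1) from a bat -> set-of-ever-associates map."""
    n = len(associates)
    return sum(len(v) / (n - 1) for v in associates.values()) / n


def _all_paths(adj, src, dst, n):
    """All simple paths src -> dst as node tuples (DFS enumeration)."""
    paths = []
    stack = [(src, (src,))]
    while stack:
        node, path = stack.pop()
        if node == dst:
            paths.append(path)
            continue
        for nxt in range(n):
            if adj[node][nxt] and nxt not in path:
                stack.append((nxt, path + (nxt,)))
    return paths

def brute_betweenness(adj) -> list[float]:
    """Unnormalized betweenness by exhaustive simple-path enumeration.

    ``adj`` is a boolean adjacency matrix (list of lists or ndarray).
    For each unordered pair, all shortest paths get equal credit split
    among their interior nodes.
    """
    n = len(adj)
    bc = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_paths(adj, s, t, n)
            if not paths:
                continue
            min_len = min(len(p) for p in paths)
            shortest = [p for p in paths if len(p) == min_len]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def brute_weighted_betweenness(weights) -> list[float]:
    """Unnormalized betweenness under additive edge lengths.

    ``weights[i][j]`` is the edge length (0 or None = no edge).  Paths tie
    when their total lengths agree to 1e-9.
    """
    n = len(weights)
    adj = [[bool(weights[i][j]) for j in range(n)] for i in range(n)]
    bc = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_paths(adj, s, t, n)
            if not paths:
                continue
            lengths = [
                sum(weights[p[k]][p[k + 1]] for k in range(len(p) - 1)) for p in paths
            ]
            best = min(lengths)
            shortest = [p for p, L in zip(paths, lengths) if L <= best + 1e-9]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc
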