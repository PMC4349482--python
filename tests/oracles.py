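"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: enumeration, direct
definitions and plain breadth-first searches only.
"""

from __future__ import annotations

import math

import numpy as np


def binomial_tail_enum(k: int, n: int, p: float) -> float:
    """P[X >= k] by explicit summation of the binomial pmf."""
    return sum(
        math.comb(n, i) * p**i * (1.0 - p) ** (n - i) for i in range(k, n + 1)
    )


def bh_brute(p_values: list[float]) -> list[float]:
    """Step-up BH by the literal definition, one value at a time."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    rank_of = {idx: r + 1 for r, idx in enumerate(order)}
    out = [0.0] * m
    for i in range(m):
        r = rank_of[i]
        candidates = [
            p_values[order[j - 1]] * m / j for j in range(r, m + 1)
        ]
        out[i] = min(1.0, min(candidates))
    return out


def closure_bfs(edges: list[tuple[str, str, str]], start: str, relations: set[str]) -> set[str]:
    """Ancestor closure by repeated scanning of the raw edge list."""
    seen: set[str] = set()
    frontier = {start}
    while frontier:
        nxt = set()
        for child, parent, rel in edges:
            if child in frontier and rel in relations and parent not in seen:
                nxt.add(parent)
        seen |= nxt
        frontier = nxt
    seen.discard(start)
    return seen


def mc_tail(rng: np.random.Generator, background: np.ndarray, m: int, S: float,
            reps: int = 10**6, chunk: int = 200_000) -> float:
    """Monte-Carlo estimate of P[sum of m iid draws >= S]."""
    hits = 0
    remaining = reps
    while remaining > 0:
        c = min(chunk, remaining)
        idx = rng.integers(0, background.size, size=(c, m))
        sums = background[idx].sum(axis=1)
        hits += int(np.count_nonzero(sums >= S - 1e-12))
        remaining -= c
    return hits / reps


def reachable_pairs(edges: set[tuple[str, str]], nodes: set[str]) -> set[tuple[str, str]]:
    """All ordered reachable pairs (u, v), u != v, by per-node BFS."""
    adj: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    pairs = set()
    for start in nodes:
        seen = set()
        stack = list(adj.get(start, []))
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(adj.get(node, []))
        pairs |= {(start, v) for v in seen if v != start}
    return pairs
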