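"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (exact
rational arithmetic, naive enumeration, repeated deletion to fixpoint) and
shares no code path with the package implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction

import networkx as nx
import numpy as np


def ac_p_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Two-sided exact Poisson-ratio p-value by direct rational tail summation.

    Builds the conditional pmf p(k | x) term by term from its ratio
    recurrence p(k)/p(k-1) = (x + k)/k * n2/(n1 + n2), starting from
    p(0) = (n1/(n1+n2))^(x+1), and sums the lower tail exactly.
    """
    q = Fraction(n1, n1 + n2)
    term = q ** (x + 1)
    lower = term
    for k in range(1, y + 1):
        term = term * Fraction(x + k, k) * (1 - q)
        lower += term
    upper = 1 - (lower - term)  # P(Y >= y) = 1 - P(Y <= y-1)
    return min(Fraction(1), 2 * min(lower, upper))


def hypergeom_upper_exact(N: int, M: int, n: int, m: int) -> Fraction:
    """P(X >= m) by enumerating sequential draws without replacement.

    Dynamic program over (draws made, annotated drawn) with exact
    probabilities — no binomial coefficients involved.
    """
    states: dict[int, Fraction] = {0: Fraction(1)}
    for d in range(n):
        new: dict[int, Fraction] = {}
        remaining = N - d
        for k, prob in states.items():
            ann_left = M - k
            if ann_left > 0:
                new[k + 1] = new.get(k + 1, Fraction(0)) + prob * Fraction(ann_left, remaining)
            non_left = remaining - ann_left
            if non_left > 0:
                new[k] = new.get(k, Fraction(0)) + prob * Fraction(non_left, remaining)
        states = new
    return sum((p for k, p in states.items() if k >= m), Fraction(0))


def bh_brute(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values: sort, p*m/i, cummin from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def kcore_brute(graph: nx.Graph) -> dict:
    """Core numbers by, for each k, deleting degree-<k nodes to fixpoint."""
    core = {v: 0 for v in graph.nodes}
    k = 1
    while True:
        g = graph.copy()
        changed = True
        while changed:
            drop = [v for v, d in g.degree() if d < k]
            changed = bool(drop)
            g.remove_nodes_from(drop)
        if g.number_of_nodes() == 0:
            break
        for v in g.nodes:
            core[v] = k
        k += 1
    return core


def rpkm_exact(count: int, total: int, length: int) -> Fraction:
    return Fraction(10**9 * count, total * length)


def pearson_exact(x, y) -> Fraction:
    """Sample Pearson correlation as an exact rational (inputs rational)."""
    x = [Fraction(v) for v in x]
    y = [Fraction(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy, sxx, syy  # r = sxy / sqrt(sxx*syy), left rational for the caller
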