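"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: exact rational
arithmetic instead of log-gamma, from-scratch cross-pair means instead of
Lance-Williams updates, exhaustive descendant walks instead of BFS
propagation, and hypergeometric enumeration instead of scipy's Fisher test.
"""

from fractions import Fraction
from math import comb, factorial

import networkx as nx


def ac_point_prob_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Eq-definition point probability with big-integer rationals."""
    r = Fraction(n2, n1)
    return (
        r**y
        * Fraction(factorial(x + y), factorial(x) * factorial(y))
        / (1 + r) ** (x + y + 1)
    )


def ac_tail_c_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    return sum(ac_point_prob_exact(x, k, n1, n2) for k in range(y + 1))


def average_linkage_from_scratch(ids, dmat):
    """Between-group-linkage merge history recomputing every cluster
    distance as the mean over all cross pairs of the original matrix."""
    index = {i: k for k, i in enumerate(ids)}
    clusters = [frozenset([i]) for i in ids]
    history = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                mean = sum(dmat[index[p], index[q]] for p in a for q in b) / (len(a) * len(b))
                ra, rb = sorted((min(a), min(b)))
                key = (mean, ra, rb)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (mean, _, _), i, j = best
        a, b = clusters[i], clusters[j]
        # orient the pair the same way the implementation pops it: by the
        # representative order used in the tie-break
        if min(a) > min(b):
            a, b = b, a
        history.append((a, b, mean))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [a | b]
    return history


def propagated_by_walk(graph, term_direct):
    """Union of direct annotations over a term and all its descendants,
    found by explicit reachability (child -> parent edges)."""
    out = {}
    for term in graph.graph.nodes:
        below = nx.ancestors(graph.graph, term) | {term}
        genes = set()
        for t in below:
            genes |= set(term_direct.get(t, ()))
        out[term] = frozenset(genes)
    return out


def enrichment_score_by_walk(graph, term_direct, term, alpha):
    """Eq-definition score: every descendant with direct annotations
    contributes seq * alpha^dist at its shortest descending distance, the
    distance found by exhaustive path enumeration."""
    down = graph.graph.reverse(copy=True)
    score = 0.0
    for node in nx.descendants(down, term) | {term}:
        seq = len(term_direct.get(node, ()))
        if not seq:
            continue
        dist = min(
            len(p) - 1 for p in nx.all_simple_paths(down, term, node)
        ) if node != term else 0
        score += seq * alpha**dist
    return score


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-tailed Fisher p by full hypergeometric enumeration: sum the
    probabilities of all tables (same margins) whose point probability does
    not exceed the observed one.  Exact rational arithmetic throughout."""
    r1, n = a + b, a + b + c + d
    c1 = a + c
    if n == 0:
        return Fraction(1)
    denom = comb(n, r1)

    def point(k: int) -> Fraction:
        return Fraction(comb(c1, k) * comb(n - c1, r1 - k), denom)

    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    p_obs = point(a)
    return sum(point(k) for k in range(lo, hi + 1) if point(k) <= p_obs)
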