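"""Independent brute-force oracles used to check the analytic routines.

All oracles work by exhaustive enumeration with exact rational
arithmetic; none of them share code with the implementation under test.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from itertools import combinations
from math import comb
from typing import Dict, List, Sequence, Set, Tuple


def intersection_tail_p(N: int, na: int, nb: int, nc: int) -> Fraction:
    """P(|A∩B| >= nc) for uniform random subsets of sizes na, nb of [N].

    By symmetry A can be fixed; all C(N, nb) choices of B are enumerated.
    """
    a = set(range(na))
    hits = 0
    total = 0
    for b in combinations(range(N), nb):
        total += 1
        if len(a & set(b)) >= nc:
            hits += 1
    return Fraction(hits, total)


def intersection_distribution(N: int, na: int, nb: int) -> Dict[int, Fraction]:
    """Full distribution of |A∩B| under the same null."""
    a = set(range(na))
    counts: Counter = Counter()
    total = 0
    for b in combinations(range(N), nb):
        total += 1
        counts[len(a & set(b))] += 1
    return {k: Fraction(v, total) for k, v in counts.items()}


def overlap_tail_p(N: int, K: int, n: int, k: int) -> Fraction:
    """P(overlap >= k) drawing an n-gene query from N with K marked genes."""
    marked = set(range(K))
    hits = 0
    total = 0
    for q in combinations(range(N), n):
        total += 1
        if len(marked & set(q)) >= k:
            hits += 1
    return Fraction(hits, total)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """U statistic for x, with midrank handling of ties."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def mann_whitney_exact_two_sided(
    x: Sequence[float], y: Sequence[float]
) -> Fraction:
    """Two-sided exact p by enumerating all labelings of the pooled sample.

    p = min(1, 2 * min(P(U <= u_obs), P(U >= u_obs))).  Requires a
    tie-free pooled sample.
    """
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1 = len(x)
    u_obs = mann_whitney_u(x, y)
    lo = hi = 0
    total = 0
    idx = range(len(pooled))
    for labels in combinations(idx, n1):
        xs = [pooled[i] for i in labels]
        ys = [pooled[i] for i in idx if i not in set(labels)]
        u = mann_whitney_u(xs, ys)
        total += 1
        if u <= u_obs:
            lo += 1
        if u >= u_obs:
            hi += 1
    p = 2 * min(Fraction(lo, total), Fraction(hi, total))
    return min(p, Fraction(1))


def graph_components(nodes: Sequence[str],
                     edges: Sequence[Tuple[str, str]]) -> List[Set[str]]:
    """Connected components by naive label propagation (no graph library)."""
    comp = {n: {n} for n in nodes}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            merged = comp[a] | comp[b]
            if merged != comp[a] or merged != comp[b]:
                for n in merged:
                    comp[n] = merged
                changed = True
    seen: List[Set[str]] = []
    for n in nodes:
        if comp[n] not in seen:
            seen.append(comp[n])
    return seen


def ancestor_closure(parents: Dict[str, Set[str]], term: str) -> Set[str]:
    """All ancestors of a term by plain DFS over a child->parents map."""
    out: Set[str] = set()
    stack = list(parents.get(term, ()))
    while stack:
        cur = stack.pop()
        if cur in out:
            continue
        out.add(cur)
        stack.extend(parents.get(cur, ()))
    return out
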