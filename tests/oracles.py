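"""Independent brute-force oracles shared across test modules.

Each oracle solves its problem by explicit enumeration and never calls the
implementation path it is used to check.
"""

import itertools
import math

import numpy as np

from breakscape.core import Anchor


def chain_ok(prev: Anchor, nxt: Anchor, max_gap: int) -> bool:
    if (prev.chrom_a, prev.chrom_b, prev.orientation) != \
            (nxt.chrom_a, nxt.chrom_b, nxt.orientation):
        return False
    if nxt.start_a < prev.end_a or nxt.start_a - prev.end_a > max_gap:
        return False
    if prev.orientation == "+":
        gap = nxt.start_b - prev.end_b
    else:
        gap = prev.start_b - nxt.end_b
    return 0 <= gap <= max_gap


def enumerate_best_chain_score(anchors: list[Anchor], max_gap: int) -> float:
    """Best total weight over all valid chains, by explicit path enumeration."""
    srt = sorted(anchors, key=lambda a: (a.start_a, a.end_a))
    best = 0.0

    def extend(i: int, score: float) -> None:
        nonlocal best
        best = max(best, score)
        for j in range(i + 1, len(srt)):
            if chain_ok(srt[i], srt[j], max_gap):
                extend(j, score + srt[j].weight)

    for i in range(len(srt)):
        extend(i, srt[i].weight)
    return best


def mwu_exact_two_sided_p(x, y) -> float:
    """Full enumeration of the Mann-Whitney permutation null (tie-free)."""
    pooled = sorted(x) + sorted(y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    return min(1.0, 2 * min(cdf, sf))


def hypergeom_upper_tail(n_universe: int, term: int, query: int, overlap: int) -> float:
    """P(X >= overlap) by counting draws of size ``query`` from the universe."""
    total = math.comb(n_universe, query)
    favorable = sum(
        math.comb(term, k) * math.comb(n_universe - term, query - k)
        for k in range(overlap, min(term, query) + 1))
    return favorable / total
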