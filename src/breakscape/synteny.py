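"""Chaining anchors into large-scale homologous synteny blocks (HSBs).

Anchors are stratified by (chromosome A, chromosome B, orientation) and
chained by weighted collinear dynamic programming: a chain is a sequence of
anchors monotone on both genomes under the chain orientation, with
inter-anchor gaps bounded by ``max_gap`` on both sides, maximizing the sum
of anchor weights. Chains are extracted greedily by score; small leftover
anchors that fall inside an accepted block's footprint are absorbed as
micro-rearrangements up to a total-span tolerance, so an HSB tolerates
short internal inversions or transpositions without splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Anchor, AnchorSet

__all__ = ["HSB", "chain_anchors", "hsb_table", "trim_hsb_overlaps"]


@dataclass
class HSB:
    """A large-scale homologous synteny block between two genomes."""

    id: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str
    anchor_ids: list[str]
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_ids)

    @property
    def span_a(self) -> int:
        return self.end_a - self.start_a

    @property
    def span_b(self) -> int:
        return self.end_b - self.start_b

    def flipped(self) -> "HSB":
        return replace(
            self,
            chrom_a=self.chrom_b, start_a=self.start_b, end_a=self.end_b,
            chrom_b=self.chrom_a, start_b=self.start_a, end_b=self.end_a,
        )


def _compatible(prev: Anchor, nxt: Anchor, orientation: str, max_gap: int) -> bool:
    """May ``nxt`` follow ``prev`` in a chain of this orientation?"""
    if nxt.start_a < prev.end_a or nxt.start_a - prev.end_a > max_gap:
        return False
    if orientation == "+":
        gap_b = nxt.start_b - prev.end_b
    else:
        gap_b = prev.start_b - nxt.end_b
    return 0 <= gap_b <= max_gap


def _best_chain(anchors: list[Anchor], orientation: str, max_gap: int):
    """Highest-scoring chain among ``anchors`` (same stratum), by DP.

    Anchors are processed in genome-A order; score[i] is the best chain
    ending at anchor i. O(n^2), which is ample at the scale this package
    targets.
    """
    order = sorted(range(len(anchors)),
                   key=lambda i: (anchors[i].start_a, anchors[i].end_a, anchors[i].id))
    score = [anchors[i].weight for i in order]
    back = [-1] * len(order)
    for jj in range(len(order)):
        aj = anchors[order[jj]]
        for ii in range(jj):
            ai = anchors[order[ii]]
            if _compatible(ai, aj, orientation, max_gap):
                cand = score[ii] + aj.weight
                if cand > score[jj]:
                    score[jj] = cand
                    back[jj] = ii
    best = int(np.argmax(score))
    chain_idx = []
    k = best
    while k != -1:
        chain_idx.append(order[k])
        k = back[k]
    chain_idx.reverse()
    return [anchors[i] for i in chain_idx], score[best]


def chain_anchors(
    anchor_set: AnchorSet | list[Anchor],
    max_gap: int = 2_000_000,
    min_anchors: int = 3,
    min_span: int = 1_000_000,
    micro_tolerance: int = 200_000,
) -> list[HSB]:
    """Chain anchors into score-maximal HSBs.

    Parameters
    ----------
    max_gap
        Maximum gap between consecutive chained anchors, on both genomes.
    min_anchors, min_span
        Blocks with fewer anchors, or spanning less than this on either
        genome, are dropped ("large-scale" filter).
    micro_tolerance
        Total span of order/orientation-violating anchors that may be
        absorbed into a surrounding block as micro-rearrangements.

    Each anchor ends up in at most one block; conflicts are resolved by
    higher chain score, then longer genome-A span, then lexicographic id.
    Blocks are finally trimmed so they do not overlap on genome A.
    """
    anchors = anchor_set.anchors if isinstance(anchor_set, AnchorSet) else list(anchor_set)
    if max_gap <= 0 or min_anchors <= 0 or min_span < 0 or micro_tolerance < 0:
        raise ValueError("chaining parameters must be positive")
    for i, a in enumerate(anchors):
        if not a.id:
            a.id = f"a{i:06d}"

    strata: dict[tuple[str, str, str], list[Anchor]] = {}
    for a in anchors:
        strata.setdefault((a.chrom_a, a.chrom_b, a.orientation), []).append(a)

    candidates = []  # (score, span_a, chain anchors, orientation)
    for (ca, cb, orient), stratum in strata.items():
        pool = list(stratum)
        while pool:
            chain, score = _best_chain(pool, orient, max_gap)
            span_a = max(x.end_a for x in chain) - min(x.start_a for x in chain)
            candidates.append((score, span_a, chain, orient))
            used = {id(x) for x in chain}
            pool = [x for x in pool if id(x) not in used]

    candidates.sort(key=lambda c: (-c[0], -c[1], c[2][0].id))
    blocks: list[HSB] = []
    used_ids: set[str] = set()
    for score, _span, chain, orient in candidates:
        if len(chain) < min_anchors:
            continue
        sa = min(x.start_a for x in chain)
        ea = max(x.end_a for x in chain)
        sb = min(x.start_b for x in chain)
        eb = max(x.end_b for x in chain)
        if ea - sa < min_span or eb - sb < min_span:
            continue
        blocks.append(HSB("", chain[0].chrom_a, sa, ea, chain[0].chrom_b, sb, eb,
                          orient, [x.id for x in chain], score))
        used_ids.update(x.id for x in chain)

    # absorb small violating leftovers that sit inside an accepted block
    leftovers = [a for a in anchors if a.id not in used_ids]
    for blk in sorted(blocks, key=lambda b: -b.score):
        absorbed_span = 0
        for a in leftovers:
            if a.id in used_ids:
                continue
            if (a.chrom_a == blk.chrom_a and a.chrom_b == blk.chrom_b
                    and blk.start_a <= a.start_a and a.end_a <= blk.end_a
                    and blk.start_b <= a.start_b and a.end_b <= blk.end_b
                    and absorbed_span + a.span_a <= micro_tolerance):
                absorbed_span += a.span_a
                blk.anchor_ids.append(a.id)
                used_ids.add(a.id)

    blocks = trim_hsb_overlaps(blocks, target="A")
    blocks.sort(key=lambda b: (b.chrom_a, b.start_a, b.chrom_b, b.start_b))
    for i, b in enumerate(blocks, start=1):
        b.id = f"hsb{i:04d}"
    return blocks


def trim_hsb_overlaps(blocks: list[HSB], target: str = "A") -> list[HSB]:
    """Make blocks non-overlapping on the target genome.

    Blocks fully contained in a higher-scoring block are dropped; partial
    overlaps are trimmed at the midpoint of the overlapped stretch, which
    keeps the breakpoint definition ("the interval between two blocks")
    well posed.
    """
    view = blocks if target == "A" else [b.flipped() for b in blocks]
    order = sorted(range(len(view)), key=lambda i: -view[i].score)
    kept: list[int] = []
    for i in order:
        contained = any(
            view[j].chrom_a == view[i].chrom_a
            and view[j].start_a <= view[i].start_a and view[i].end_a <= view[j].end_a
            for j in kept)
        if not contained:
            kept.append(i)
    view = sorted((view[i] for i in kept), key=lambda b: (b.chrom_a, b.start_a))
    for prev, nxt in zip(view[:-1], view[1:]):
        if prev.chrom_a == nxt.chrom_a and nxt.start_a < prev.end_a:
            mid = (nxt.start_a + prev.end_a) // 2
            prev.end_a = mid
            nxt.start_a = max(mid, nxt.start_a)
            if nxt.start_a >= nxt.end_a:  # degenerate after trim
                nxt.start_a = nxt.end_a - 1
    out = view if target == "A" else [b.flipped() for b in view]
    return out


def hsb_table(blocks: list[HSB], genome_lengths_a: dict[str, int] | None = None,
              genome_lengths_b: dict[str, int] | None = None) -> dict:
    """Per-comparison summary: count, total spans and coverage fractions."""
    span_a = sum(b.span_a for b in blocks)
    span_b = sum(b.span_b for b in blocks)
    out = {
        "count": len(blocks),
        "span_a": span_a,
        "span_b": span_b,
        "coverage_a": None,
        "coverage_b": None,
    }
    if genome_lengths_a:
        out["coverage_a"] = span_a / sum(genome_lengths_a.values())
    if genome_lengths_b:
        out["coverage_b"] = span_b / sum(genome_lengths_b.values())
    return out
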