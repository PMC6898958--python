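"""Evolutionary breakpoint regions (EBRs) from HSB layouts.

An EBR is the interval on one genome between two adjacent large-scale
HSBs, demarcated exactly by the blocks' end coordinates. Adjacent blocks
whose partner chromosomes differ mark an interchromosomal rearrangement
(a fission, seen from the target genome); same-partner junctions mark
intrachromosomal events such as inversions. Chromosome-terminal gaps lie
beyond only one block and are therefore not EBRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .synteny import HSB

__all__ = [
    "EBR",
    "detect_ebrs",
    "count_fission_events",
    "merge_ebr_sets",
    "ebr_summary",
]


@dataclass
class EBR:
    genome_id: str
    chromosome: str
    start: int
    end: int
    flank_left: str = ""
    flank_right: str = ""
    partner_left: str = ""
    partner_right: str = ""
    kind: str = "interchromosomal"  # or "intrachromosomal"
    sources: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"EBR with empty interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "EBR") -> bool:
        return (self.chromosome == other.chromosome
                and self.start < other.end and other.start < self.end)


def _target_view(hsbs: list[HSB], target: str) -> list[HSB]:
    if target not in ("A", "B"):
        raise ValueError("target must be 'A' or 'B'")
    return list(hsbs) if target == "A" else [b.flipped() for b in hsbs]


def _sorted_nonoverlapping(hsbs: list[HSB]) -> dict[str, list[HSB]]:
    per_chrom: dict[str, list[HSB]] = {}
    for b in hsbs:
        per_chrom.setdefault(b.chrom_a, []).append(b)
    for chrom, blocks in per_chrom.items():
        blocks.sort(key=lambda b: (b.start_a, b.end_a))
        for prev, nxt in zip(blocks[:-1], blocks[1:]):
            if nxt.start_a < prev.end_a:
                raise ValueError(
                    f"HSBs {prev.id!r} and {nxt.id!r} overlap on {chrom} "
                    f"([{prev.start_a},{prev.end_a}) vs [{nxt.start_a},{nxt.end_a})); "
                    "trim blocks before EBR detection")
    return per_chrom


def detect_ebrs(
    hsbs: list[HSB],
    target: str = "A",
    fission_only: bool = False,
    *,
    genome_id: str = "",
    source: str = "",
) -> list[EBR]:
    """Every gap between adjacent HSBs on the target genome becomes an EBR.

    Abutting blocks with different partner chromosomes emit a 1-bp EBR at
    the junction, so a fission with no intervening sequence still
    surfaces. With ``fission_only``, only interchromosomal EBRs are
    returned.
    """
    view = _target_view(hsbs, target)
    per_chrom = _sorted_nonoverlapping(view)
    out: list[EBR] = []
    for chrom in sorted(per_chrom):
        blocks = per_chrom[chrom]
        for prev, nxt in zip(blocks[:-1], blocks[1:]):
            kind = ("interchromosomal" if prev.chrom_b != nxt.chrom_b
                    else "intrachromosomal")
            start, end = prev.end_a, nxt.start_a
            if start >= end:  # abutting blocks: keep a 1-bp junction record
                start, end = prev.end_a - 1, prev.end_a
            out.append(EBR(
                genome_id, chrom, start, end,
                flank_left=prev.id, flank_right=nxt.id,
                partner_left=prev.chrom_b, partner_right=nxt.chrom_b,
                kind=kind, sources={source} if source else set(),
            ))
    if fission_only:
        out = [e for e in out if e.kind == "interchromosomal"]
    return out


def count_fission_events(hsbs: list[HSB], target: str = "A") -> int:
    """Number of partner-chromosome changes between adjacent HSBs.

    Summed over target chromosomes; equals, per chromosome, the number of
    maximal same-partner runs minus one.
    """
    view = _target_view(hsbs, target)
    per_chrom = _sorted_nonoverlapping(view)
    n = 0
    for blocks in per_chrom.values():
        for prev, nxt in zip(blocks[:-1], blocks[1:]):
            if prev.chrom_b != nxt.chrom_b:
                n += 1
    return n


def merge_ebr_sets(set_1: list[EBR], set_2: list[EBR]) -> tuple[list[EBR], int]:
    """Union two EBR sets on the same genome.

    EBRs sharing at least one base are collapsed (transitively) into a
    single record spanning the union interval with sources pooled. Returns
    the merged list and the number of merged groups that contain members
    of both input sets.
    """
    gids = {e.genome_id for e in set_1} | {e.genome_id for e in set_2}
    if len(gids) > 1:
        raise ValueError(f"cannot merge EBR sets from different genomes: {sorted(gids)}")
    tagged = [(e, 0) for e in set_1] + [(e, 1) for e in set_2]
    tagged.sort(key=lambda t: (t[0].chromosome, t[0].start, t[0].end, t[1]))
    merged: list[EBR] = []
    groups: list[list[tuple[int, str, int, int]]] = []
    for e, origin in tagged:
        if merged and merged[-1].chromosome == e.chromosome and e.start < merged[-1].end:
            last = merged[-1]
            last.end = max(last.end, e.end)
            last.sources |= e.sources
            last.kind = last.kind if last.kind == e.kind else "interchromosomal"
            groups[-1].append((origin, e.chromosome, e.start, e.end))
        else:
            merged.append(EBR(e.genome_id, e.chromosome, e.start, e.end,
                              e.flank_left, e.flank_right,
                              e.partner_left, e.partner_right,
                              e.kind, set(e.sources)))
            groups.append([(origin, e.chromosome, e.start, e.end)])

    def is_cross(group: list[tuple[int, str, int, int]]) -> bool:
        # identical-coordinate members in both sets are the same region seen
        # twice, not a cross-set overlap
        ivals_0 = {m[1:] for m in group if m[0] == 0}
        ivals_1 = {m[1:] for m in group if m[0] == 1}
        return bool(ivals_0) and bool(ivals_1) and ivals_0 != ivals_1

    cross = sum(1 for g in groups if is_cross(g))
    return merged, cross


def ebr_summary(ebrs: list[EBR]) -> dict:
    """Count, total/min/max/mean length and per-chromosome counts."""
    if not ebrs:
        return {"count": 0, "total_span": 0, "min_length": 0, "max_length": 0,
                "mean_length": 0.0, "per_chromosome": {}, "per_kind": {}}
    lengths = [e.length for e in ebrs]
    per_chrom: dict[str, int] = {}
    per_kind: dict[str, int] = {}
    for e in ebrs:
        per_chrom[e.chromosome] = per_chrom.get(e.chromosome, 0) + 1
        per_kind[e.kind] = per_kind.get(e.kind, 0) + 1
    return {
        "count": len(ebrs),
        "total_span": sum(lengths),
        "min_length": min(lengths),
        "max_length": max(lengths),
        "mean_length": sum(lengths) / len(lengths),
        "per_chromosome": dict(sorted(per_chrom.items())),
        "per_kind": per_kind,
    }
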