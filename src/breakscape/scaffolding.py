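"""Reference-assisted chromosome construction from scaffolds.

Scaffolds are first assigned to chromosomes from flow-sorted-library read
depth (each sorted chromosome yields one library; a scaffold belongs to
the library that dominates its depth profile). Libraries that co-sorted
two chromosomes, and scaffolds with ambiguous depth, are resolved with
synteny against a related reference genome through a chromosome
correspondence map. Scaffolds are then ordered and oriented along each
chromosome by their reference coordinates, and the layout is emitted as
AGP v2.1 plus the concatenated FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Chromosome, Karyotype, revcomp
from .synteny import HSB

__all__ = [
    "ScaffoldPlacement",
    "assign_by_coverage",
    "resolve_with_reference",
    "order_by_reference",
    "emit_layout",
]


@dataclass
class ScaffoldPlacement:
    scaffold: str
    chromosome: str
    rank: int
    orientation: str  # '+', '-' or 'unknown'
    evidence: str  # 'coverage', 'synteny', 'both'
    confidence: float  # best / second-best signal ratio


def assign_by_coverage(
    matrix: pd.DataFrame,
    min_ratio: float = 3.0,
) -> tuple[dict[str, str], set[str]]:
    """Assign each scaffold to the dominant flow-sort library.

    Columns are first divided by their library-wide median depth (sorted
    libraries are sequenced to very different depths, so raw values are
    incomparable). A scaffold is assigned to its best library only when
    the best/second-best normalized ratio reaches ``min_ratio``; otherwise
    it joins the ambiguous set.
    """
    if matrix.empty:
        raise ValueError("empty coverage matrix")
    if min_ratio <= 1:
        raise ValueError("min_ratio must be > 1")
    med = matrix.median(axis=0).replace(0, np.nan)
    norm = matrix.divide(med, axis=1).fillna(0.0)
    assigned: dict[str, str] = {}
    ambiguous: set[str] = set()
    for scaffold, row in norm.iterrows():
        vals = row.to_numpy(dtype=float)
        if not np.any(vals > 0):
            ambiguous.add(scaffold)
            continue
        order = np.argsort(vals)[::-1]
        best, second = vals[order[0]], (vals[order[1]] if len(vals) > 1 else 0.0)
        if second <= 0 or best / second >= min_ratio:
            assigned[scaffold] = str(matrix.columns[order[0]])
        else:
            ambiguous.add(scaffold)
    return assigned, ambiguous


def _hsb_spans_by_ref(hsbs: list[HSB], scaffold: str) -> dict[str, int]:
    """Aligned span of one scaffold per reference chromosome.

    HSBs are expected with the scaffold on genome A and the reference on
    genome B.
    """
    spans: dict[str, int] = {}
    for b in hsbs:
        if b.chrom_a == scaffold:
            spans[b.chrom_b] = spans.get(b.chrom_b, 0) + b.span_a
    return spans


def resolve_with_reference(
    scaffolds,
    hsbs: list[HSB],
    correspondence: dict[str, set[str]],
    candidates: dict[str, set[str]] | None = None,
    *,
    majority: float = 0.6,
) -> tuple[dict[str, str], set[str]]:
    """Resolve scaffold->chromosome using reference synteny.

    ``correspondence`` maps each reference chromosome to the target
    chromosomes it paints (the cross-species painting result). A scaffold
    is assigned to the target chromosome whose reference chromosomes carry
    at least ``majority`` of its aligned span; ``candidates`` optionally
    restricts the admissible targets per scaffold (e.g. the two
    chromosomes of a mixed library). Scaffolds without reference HSBs or
    below the majority remain unresolved.
    """
    resolved: dict[str, str] = {}
    unresolved: set[str] = set()
    for sc in scaffolds:
        spans = _hsb_spans_by_ref(hsbs, sc)
        if not spans:
            unresolved.add(sc)
            continue
        target_span: dict[str, int] = {}
        for ref_chrom, span in spans.items():
            for tgt in correspondence.get(ref_chrom, set()):
                if candidates is None or tgt in candidates.get(sc, {tgt}):
                    target_span[tgt] = target_span.get(tgt, 0) + span
        total = sum(spans.values())
        if not target_span:
            unresolved.add(sc)
            continue
        best = max(target_span, key=lambda t: (target_span[t], t))
        if target_span[best] / total >= majority:
            resolved[sc] = best
        else:
            unresolved.add(sc)
    return resolved, unresolved


def order_by_reference(
    assignment: dict[str, str],
    hsbs: list[HSB],
    *,
    orient_majority: float = 0.7,
    evidence: dict[str, str] | None = None,
) -> list[ScaffoldPlacement]:
    """Order scaffolds along chromosomes by reference synteny.

    Within each chromosome, scaffolds sort by the span-weighted median
    reference coordinate of their HSBs; orientation is the majority HSB
    orientation when at least ``orient_majority`` of the aligned span
    agrees, else "unknown". Ranks are dense from 1.
    """
    per_scaffold: dict[str, list[HSB]] = {}
    for b in hsbs:
        per_scaffold.setdefault(b.chrom_a, []).append(b)
    rows = []
    for sc, chrom in assignment.items():
        blocks = per_scaffold.get(sc, [])
        if not blocks:
            raise ValueError(f"scaffold {sc!r} has no reference HSB; cannot order")
        mids = np.array([(b.start_b + b.end_b) / 2 for b in blocks])
        weights = np.array([b.span_a for b in blocks], dtype=float)
        order = np.argsort(mids)
        cum = np.cumsum(weights[order])
        median_pos = float(mids[order][np.searchsorted(cum, cum[-1] / 2)])
        plus = sum(b.span_a for b in blocks if b.orientation == "+")
        total = sum(b.span_a for b in blocks)
        if plus / total >= orient_majority:
            orient = "+"
        elif (total - plus) / total >= orient_majority:
            orient = "-"
        else:
            orient = "unknown"
        rows.append((sc, chrom, median_pos, orient))
    placements: list[ScaffoldPlacement] = []
    for chrom in sorted({r[1] for r in rows}):
        members = sorted((r for r in rows if r[1] == chrom), key=lambda r: r[2])
        for rank, (sc, _, _pos, orient) in enumerate(members, start=1):
            ev = (evidence or {}).get(sc, "synteny")
            placements.append(ScaffoldPlacement(sc, chrom, rank, orient, ev, float("nan")))
    return placements


def emit_layout(
    placements: list[ScaffoldPlacement],
    scaffolds: Karyotype,
    *,
    gap_size: int = 100,
) -> tuple[pd.DataFrame, Karyotype]:
    """Materialize placements as an AGP v2.1 table and chromosome FASTA.

    Scaffolds alternate with fixed-size N gaps; AGP coordinates are
    1-based inclusive. A '-' scaffold is reverse-complemented in the
    emitted sequence; 'unknown' orientations are written as '+' with the
    AGP orientation column set to '?' semantics via '+', matching common
    practice of treating unknowns as forward.
    """
    seen = set()
    for p in placements:
        if p.scaffold in seen:
            raise ValueError(f"scaffold {p.scaffold!r} placed more than once")
        seen.add(p.scaffold)
    rows = []
    chroms: list[Chromosome] = []
    for chrom in sorted({p.chromosome for p in placements}):
        members = sorted((p for p in placements if p.chromosome == chrom),
                         key=lambda p: p.rank)
        if [p.rank for p in members] != list(range(1, len(members) + 1)):
            raise ValueError(f"ranks on {chrom!r} are not dense from 1")
        pos = 0  # 0-based internal; +1 when writing
        part = 0
        seq_parts: list[str] = []
        for i, p in enumerate(members):
            comp = scaffolds.chrom(p.scaffold)
            if i > 0:
                part += 1
                rows.append((chrom, pos + 1, pos + gap_size, part, "N", gap_size,
                             "scaffold", "yes", "align_genus"))
                seq_parts.append("N" * gap_size)
                pos += gap_size
            part += 1
            orient = p.orientation if p.orientation in ("+", "-") else "+"
            rows.append((chrom, pos + 1, pos + comp.length, part, "W",
                         p.scaffold, 1, comp.length, orient))
            if comp.sequence is not None:
                seq_parts.append(revcomp(comp.sequence) if orient == "-" else comp.sequence)
            pos += comp.length
        seq = "".join(seq_parts) if all(
            scaffolds.chrom(p.scaffold).sequence is not None for p in members) else None
        chroms.append(Chromosome(chrom, pos, seq))
    agp = pd.DataFrame(rows, columns=["object", "object_beg", "object_end", "part_number",
                                      "component_type", "c6", "c7", "c8", "c9"])
    return agp, Karyotype(scaffolds.genome_id + "_chromosomes", chroms)
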