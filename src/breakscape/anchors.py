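"""Anchor construction from exact sequence matches and ortholog gene pairs.

The pairwise comparison starts from raw local matches (maximal exact
matches of at least 20 bp, the classic MUM-style seed), which are then
clustered against orthologous protein-coding gene pairs to form the
anchors that the synteny chainer consumes. Orthologs alone can also be
turned into anchors directly, which is the usual desk-scale route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .core import Anchor, AnchorSet, Karyotype, revcomp

log = logging.getLogger(__name__)

__all__ = [
    "RawMatch",
    "find_exact_matches",
    "anchors_from_orthologs",
    "cluster_matches_to_anchors",
]


@dataclass(frozen=True)
class RawMatch:
    """A maximal exact match between two sequences (0-based, half-open)."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str  # '+' | '-'

    @property
    def length(self) -> int:
        return self.end_a - self.start_a


def _forward_matches(a: str, b: str, min_len: int, chrom_a: str, chrom_b: str,
                     orientation: str, b_len_for_flip: int | None = None):
    """All maximal exact matches of length >= min_len via k-mer seeding.

    Seeds with k = min_len, extends each seed outward, and deduplicates by
    the maximal extension. 'N' participates in no match.
    """
    k = min_len
    n, m = len(a), len(b)
    if n < k or m < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = a[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    seen: set[tuple[int, int, int]] = set()
    out = []
    for j in range(m - k + 1):
        kmer = b[j:j + k]
        if "N" in kmer:
            continue
        for i in index.get(kmer, ()):
            # extend left
            s_a, s_b = i, j
            while s_a > 0 and s_b > 0 and a[s_a - 1] == b[s_b - 1] and a[s_a - 1] != "N":
                s_a -= 1
                s_b -= 1
            # extend right
            e_a, e_b = i + k, j + k
            while e_a < n and e_b < m and a[e_a] == b[e_b] and a[e_a] != "N":
                e_a += 1
                e_b += 1
            key = (s_a, s_b, e_a - s_a)
            if key in seen:
                continue
            seen.add(key)
            if orientation == "+":
                out.append(RawMatch(chrom_a, s_a, e_a, chrom_b, s_b, e_b, "+"))
            else:
                # coordinates on the reverse strand of B -> forward frame
                fs = b_len_for_flip - e_b
                fe = b_len_for_flip - s_b
                out.append(RawMatch(chrom_a, s_a, e_a, chrom_b, fs, fe, "-"))
    return out


def find_exact_matches(
    seq_a: str,
    seq_b: str,
    min_len: int = 20,
    both_strands: bool = False,
    *,
    chrom_a: str = "A",
    chrom_b: str = "B",
) -> list[RawMatch]:
    """Report every maximal exact match of at least ``min_len`` bases.

    Maximality means the match cannot be extended by one base on both
    sequences simultaneously and remain exact. Reverse-strand matches (vs
    the reverse complement of ``seq_b``) carry orientation '-' with B
    coordinates reported on the forward strand. Overlapping maximal matches
    are reported independently; chaining is not done here.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    matches = _forward_matches(seq_a, seq_b, min_len, chrom_a, chrom_b, "+")
    if both_strands:
        matches += _forward_matches(seq_a, revcomp(seq_b), min_len, chrom_a,
                                    chrom_b, "-", b_len_for_flip=len(seq_b))
    matches.sort(key=lambda m: (m.start_a, m.start_b, m.orientation))
    return matches


def anchors_from_orthologs(
    pairs: pd.DataFrame,
    karyotype_a: Karyotype | None = None,
    karyotype_b: Karyotype | None = None,
    *,
    strict: bool = False,
    genome_a: str = "A",
    genome_b: str = "B",
) -> AnchorSet:
    """One anchor per ortholog gene pair.

    Orientation is '+' when the two genes share a strand, '-' otherwise;
    the weight is the smaller of the two gene spans. Malformed rows
    (unknown chromosome, inverted interval) are dropped with a warning, or
    abort when ``strict`` is set.
    """
    anchors = []
    names_a = set(karyotype_a.names) if karyotype_a is not None else None
    names_b = set(karyotype_b.names) if karyotype_b is not None else None
    for idx, row in pairs.iterrows():
        problems = []
        if names_a is not None and row.chrom_a not in names_a:
            problems.append(f"unknown chromosome {row.chrom_a!r} on genome A")
        if names_b is not None and row.chrom_b not in names_b:
            problems.append(f"unknown chromosome {row.chrom_b!r} on genome B")
        if row.start_a >= row.end_a or row.start_b >= row.end_b:
            problems.append("inverted or empty interval")
        if problems:
            msg = f"ortholog row {idx} ({row.gene_a}/{row.gene_b}): " + "; ".join(problems)
            if strict:
                raise ValueError(msg)
            log.warning("%s -- row skipped", msg)
            continue
        span_a = int(row.end_a - row.start_a)
        span_b = int(row.end_b - row.start_b)
        anchors.append(Anchor(
            row.chrom_a, int(row.start_a), int(row.end_a),
            row.chrom_b, int(row.start_b), int(row.end_b),
            "+" if row.strand_a == row.strand_b else "-",
            weight=float(min(span_a, span_b)),
            source="ortholog", id=f"{row.gene_a}|{row.gene_b}",
        ))
    if karyotype_a is not None:
        genome_a = karyotype_a.genome_id
    if karyotype_b is not None:
        genome_b = karyotype_b.genome_id
    return AnchorSet(genome_a, genome_b, anchors)


def cluster_matches_to_anchors(
    matches: list[RawMatch],
    pairs: pd.DataFrame,
    window: int = 10_000,
) -> list[Anchor]:
    """Cluster raw matches against ortholog pairs to form merged anchors.

    A match supports a pair when its intervals on both genomes fall inside
    the pair's gene intervals expanded by ``window``; the supporting
    matches of each pair are merged into one anchor spanning their joint
    extent. Matches supporting no pair are discarded. The output does not
    depend on the input match order.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    out: dict[tuple, Anchor] = {}
    for _, row in pairs.iterrows():
        lo_a, hi_a = row.start_a - window, row.end_a + window
        lo_b, hi_b = row.start_b - window, row.end_b + window
        support = [
            m for m in matches
            if m.chrom_a == row.chrom_a and m.chrom_b == row.chrom_b
            and lo_a <= m.start_a and m.end_a <= hi_a
            and lo_b <= m.start_b and m.end_b <= hi_b
        ]
        if not support:
            continue
        sa = min(m.start_a for m in support)
        ea = max(m.end_a for m in support)
        sb = min(m.start_b for m in support)
        eb = max(m.end_b for m in support)
        plus = sum(m.length for m in support if m.orientation == "+")
        minus = sum(m.length for m in support if m.orientation == "-")
        orient = "+" if plus >= minus else "-"
        key = (row.chrom_a, sa, ea, row.chrom_b, sb, eb, orient)
        if key not in out:
            out[key] = Anchor(row.chrom_a, sa, ea, row.chrom_b, sb, eb, orient,
                              weight=float(ea - sa), source="merged",
                              id=f"{row.gene_a}|{row.gene_b}")
    return sorted(out.values(), key=lambda a: (a.chrom_a, a.start_a, a.chrom_b, a.start_b))
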