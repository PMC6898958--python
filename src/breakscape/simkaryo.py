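"""Karyotype simulator: ancestral genomes, chromosome rearrangements, anchors.

The simulator produces multi-chromosome genomes related by fission, fusion,
inversion and translocation events, together with gene/repeat annotation
tracks and an exact record of every applied breakpoint (the truth set used
to score breakpoint-detection recovery).

Sequence realism is deliberately minimal: i.i.d. nucleotides at a target GC
with repeat intervals overwritten by family-specific repetitive text. That
is sufficient for GC/repeat-coverage statistics; there is no indel or
substitution process.

A "fragile site" model is available: the ancestor can carry designated
hotspot regions with elevated gene and repeat-family placement intensity,
and rearrangement breakpoints can be drawn from those regions. This mirrors
the empirical association between evolutionary breakpoints and repeat-dense,
gene-rich chromatin.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import Anchor, AnchorSet, Chromosome, Feature, FeatureTrack, Karyotype, revcomp

__all__ = [
    "RearrangementEvent",
    "BreakpointInterval",
    "TruthSet",
    "SimulatedGenome",
    "simulate_ancestor",
    "sample_plan",
    "apply_rearrangements",
    "emit_anchors",
    "cross_ortholog_map",
    "simulate_flow_sort_coverage",
    "shred_karyotype",
]

ORTHOLOG_COLUMNS = [
    "gene_a", "gene_b",
    "chrom_a", "start_a", "end_a", "strand_a",
    "chrom_b", "start_b", "end_b", "strand_b",
]

# element length ranges (bp) used when a family has no explicit range
_FAMILY_LENGTHS = {
    "LINE-L1": (1000, 6000),
    "LINE-RTE": (800, 4000),
    "SINE": (100, 400),
    "LTR-ERV1": (300, 1000),
}
_DEFAULT_ELEMENT_RANGE = (300, 3000)

_EVENT_KINDS = ("fission", "fusion", "inversion", "translocation")


@dataclass
class RearrangementEvent:
    kind: str
    generation: int
    breakpoints: list[tuple[str, int]]
    sources: list[str]
    products: list[str]

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        n_bp = {"fission": 1, "fusion": 0, "inversion": 2, "translocation": 2}[self.kind]
        if len(self.breakpoints) != n_bp:
            raise ValueError(f"{self.kind}: expected {n_bp} breakpoints, got {len(self.breakpoints)}")
        n_prod = {"fission": 2, "fusion": 1, "inversion": 1, "translocation": 2}[self.kind]
        if len(self.products) != n_prod:
            raise ValueError(f"{self.kind}: expected {n_prod} products, got {len(self.products)}")


@dataclass
class BreakpointInterval:
    """A true breakpoint, represented as a 2-bp interval centred on the cut."""

    chrom: str
    start: int
    end: int
    kind: str
    event_index: int


@dataclass
class TruthSet:
    events: list[RearrangementEvent]
    #: genome_id -> list of true breakpoints in that genome's coordinates.
    #: Cuts are recorded in the source (ancestor) frame; junctions created by
    #: fusion/inversion/translocation are additionally recorded in the
    #: derived frame.
    breakpoint_intervals: dict[str, list[BreakpointInterval]]
    ortholog_map: pd.DataFrame

    def breakpoints(self, genome_id: str, kind: str | None = None) -> list[BreakpointInterval]:
        bps = self.breakpoint_intervals.get(genome_id, [])
        if kind is not None:
            bps = [b for b in bps if b.kind == kind]
        return bps

    def to_json(self, path) -> None:
        payload = {
            "events": [asdict(e) for e in self.events],
            "breakpoint_intervals": {
                g: [asdict(b) for b in bps]
                for g, bps in self.breakpoint_intervals.items()
            },
            "ortholog_map": self.ortholog_map.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedGenome:
    """A karyotype plus its annotation track and optional hotspot regions."""

    karyotype: Karyotype
    track: FeatureTrack
    hotspots: list[tuple[str, int, int]] = field(default_factory=list)
    truth: TruthSet | None = None

    @property
    def genome_id(self) -> str:
        return self.karyotype.genome_id


# ---------------------------------------------------------------------------
# weighted position sampling over piecewise-constant intensities


class _PiecewiseWeights:
    """Piecewise-constant positional weights on [0, length)."""

    def __init__(self, length: int, hot: list[tuple[int, int]], boost: float):
        bounds = {0, length}
        for s, e in hot:
            bounds.add(max(0, min(s, length)))
            bounds.add(max(0, min(e, length)))
        self.edges = sorted(bounds)
        hot_sorted = sorted((max(0, s), min(e, length)) for s, e in hot)
        self.weights = []
        for lo, hi in zip(self.edges[:-1], self.edges[1:]):
            w = boost if any(s <= lo and hi <= e for s, e in hot_sorted) else 1.0
            self.weights.append(w)
        self.cum = np.concatenate(
            [[0.0], np.cumsum([w * (hi - lo) for lo, hi, w in
                               zip(self.edges[:-1], self.edges[1:], self.weights)])]
        )

    @property
    def total(self) -> float:
        return float(self.cum[-1])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.uniform(0.0, self.total, size=n)
        idx = np.searchsorted(self.cum, u, side="right") - 1
        idx = np.clip(idx, 0, len(self.weights) - 1)
        lo = np.asarray(self.edges[:-1])[idx]
        w = np.asarray(self.weights)[idx]
        return (lo + (u - self.cum[idx]) / w).astype(np.int64)


class _OccupancyIndex:
    """Sorted non-overlapping intervals with O(log n) overlap checks."""

    def __init__(self):
        self.starts: list[int] = []
        self.ends: list[int] = []

    def overlaps(self, start: int, end: int) -> bool:
        i = bisect.bisect_right(self.starts, start)
        if i > 0 and self.ends[i - 1] > start:
            return True
        if i < len(self.starts) and self.starts[i] < end:
            return True
        return False

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_right(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


# ---------------------------------------------------------------------------
# ancestor simulation


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=probs)
    return np.frombuffer(b"AGCT", dtype="S1")[idx]


def _family_consensus(rng: np.random.Generator, gc: float, length: int = 600) -> np.ndarray:
    return _random_sequence(rng, length, gc)


def simulate_ancestor(
    n_chromosomes: int,
    mean_length: int = 10_000_000,
    length_dispersion: float = 0.15,
    gene_rate: float = 8.0,
    repeat_mix: dict[str, float] | None = None,
    gc_target: float = 0.42,
    seed: int = 0,
    *,
    genome_id: str = "ancestor",
    with_sequence: bool = True,
    gene_length_range: tuple[int, int] = (2_000, 10_000),
    n_hotspots: int = 0,
    hotspot_width: int = 200_000,
    hotspot_gene_boost: float = 1.0,
    hotspot_repeat_boost: dict[str, float] | None = None,
) -> SimulatedGenome:
    """Simulate an ancestral karyotype with gene and repeat tracks.

    Parameters
    ----------
    n_chromosomes
        Number of chromosomes (>= 1).
    mean_length, length_dispersion
        Chromosome lengths are drawn from a gamma distribution with this
        mean and coefficient of variation.
    gene_rate
        Expected genes per Mb (Poisson placement, non-overlapping).
    repeat_mix
        Map repeat family -> target genome coverage fraction; fractions must
        sum to < 1. Default: a mammal-like mix dominated by LINE-L1.
    gc_target
        Genome-wide GC fraction of the emitted sequence (within +/- 0.02).
    n_hotspots, hotspot_width, hotspot_gene_boost, hotspot_repeat_boost
        Optional fragile-site regions (``n_hotspots`` per chromosome) where
        gene placement intensity is multiplied by ``hotspot_gene_boost`` and
        the listed repeat families by their boost factors.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if not 0.0 < gc_target < 1.0:
        raise ValueError("gc_target must lie in (0, 1)")
    if gene_rate < 0:
        raise ValueError("gene_rate must be >= 0")
    if repeat_mix is None:
        repeat_mix = {"LINE-L1": 0.12, "SINE": 0.06, "LTR-ERV1": 0.04}
    if any(f < 0 for f in repeat_mix.values()):
        raise ValueError("repeat fractions must be >= 0")
    if sum(repeat_mix.values()) >= 1.0:
        raise ValueError("repeat fractions must sum to < 1")
    hotspot_repeat_boost = hotspot_repeat_boost or {}

    rng = np.random.default_rng(seed)
    cv = max(length_dispersion, 1e-9)
    shape = 1.0 / cv**2
    lengths = rng.gamma(shape, mean_length / shape, size=n_chromosomes)
    lengths = np.maximum(lengths.astype(np.int64), max(1, int(0.2 * mean_length)))

    chroms: list[Chromosome] = []
    feats: list[Feature] = []
    hotspots: list[tuple[str, int, int]] = []
    consensus = {fam: _family_consensus(rng, gc_target) for fam in repeat_mix}
    gene_no = 0

    for ci, L in enumerate(lengths):
        name = f"chr{ci + 1}"
        L = int(L)

        # Hotspots are kept >= hotspot_spacing apart and >= hotspot_margin
        # from chromosome ends, so each one sits inside its own Mb-scale
        # block of conserved flanking sequence (fragile sites are sparse
        # relative to synteny-block scale).
        hot: list[tuple[int, int]] = []
        hotspot_margin = max(hotspot_width, 1_500_000)
        hotspot_spacing = max(2 * hotspot_width, 2_000_000)
        if n_hotspots > 0 and L > 2 * hotspot_margin + hotspot_width:
            centers: list[int] = []
            for _ in range(40 * n_hotspots):
                if len(centers) == n_hotspots:
                    break
                c = int(rng.uniform(hotspot_margin, L - hotspot_margin))
                if all(abs(c - o) >= hotspot_spacing for o in centers):
                    centers.append(c)
            for c in sorted(centers):
                s = c - hotspot_width // 2
                hot.append((s, s + hotspot_width))
        hotspots.extend((name, s, e) for s, e in hot)

        # --- genes ----------------------------------------------------
        gene_occ = _OccupancyIndex()
        pw_gene = _PiecewiseWeights(L, hot, hotspot_gene_boost)
        n_genes = rng.poisson(gene_rate * pw_gene.total / 1e6)
        chrom_genes: list[Feature] = []
        for _ in range(n_genes):
            glen = int(rng.integers(*gene_length_range))
            for _attempt in range(60):
                pos = int(pw_gene.sample(rng, 1)[0])
                if pos + glen > L:
                    continue
                if not gene_occ.overlaps(pos, pos + glen):
                    gene_occ.add(pos, pos + glen)
                    gene_no += 1
                    strand = "+" if rng.random() < 0.5 else "-"
                    chrom_genes.append(Feature(name, pos, pos + glen,
                                               f"g{gene_no:05d}", "gene", strand))
                    break
        feats.extend(sorted(chrom_genes, key=lambda f: f.start))

        # --- repeats --------------------------------------------------
        rep_occ = _OccupancyIndex()
        chrom_reps: list[Feature] = []
        rep_no = 0
        for fam, frac in repeat_mix.items():
            boost = hotspot_repeat_boost.get(fam, 1.0)
            pw = _PiecewiseWeights(L, hot, boost)
            target = frac * pw.total  # boosted bases count extra
            lo, hi = _FAMILY_LENGTHS.get(fam, _DEFAULT_ELEMENT_RANGE)
            covered = 0
            attempts = 0
            max_attempts = int(20 * target / ((lo + hi) / 2) + 100)
            while covered < target and attempts < max_attempts:
                attempts += 1
                elen = int(rng.integers(lo, hi + 1))
                pos = int(pw.sample(rng, 1)[0])
                if pos + elen > L or rep_occ.overlaps(pos, pos + elen):
                    continue
                rep_occ.add(pos, pos + elen)
                rep_no += 1
                chrom_reps.append(Feature(name, pos, pos + elen,
                                          f"family:{fam}", "repeat", "+", family=fam))
                covered += elen
        feats.extend(sorted(chrom_reps, key=lambda f: f.start))

        # --- sequence -------------------------------------------------
        seq = None
        if with_sequence:
            arr = _random_sequence(rng, L, gc_target)
            for f in chrom_reps:
                cons = consensus[f.family]
                reps = int(np.ceil(f.length / len(cons)))
                arr[f.start:f.end] = np.tile(cons, reps)[: f.length]
            seq = arr.tobytes().decode("ascii")
        chroms.append(Chromosome(name, L, seq))

    kt = Karyotype(genome_id, chroms)
    track = FeatureTrack(genome_id, feats)
    track.validate(kt)
    return SimulatedGenome(kt, track, hotspots)


# ---------------------------------------------------------------------------
# rearrangement machinery


@dataclass
class _WChrom:
    """Working chromosome during event application."""

    name: str
    length: int
    seq: str | None
    feats: list[Feature]
    #: (ancestor_chrom, anc_start, anc_end, strand +1/-1) tiles in order
    segments: list[tuple[str, int, int, int]]
    #: derived-frame junction markers carried through later events
    markers: list[tuple[int, str, int]]  # (pos, kind, event_index)


def _wrap(kt: Karyotype, track: FeatureTrack) -> list[_WChrom]:
    by_chrom: dict[str, list[Feature]] = {c.name: [] for c in kt.chromosomes}
    for f in track.records:
        by_chrom[f.chrom].append(
            Feature(f.chrom, f.start, f.end, f.name, f.category, f.strand, f.family))
    return [
        _WChrom(c.name, c.length, c.sequence, by_chrom[c.name],
                [(c.name, 0, c.length, +1)], [])
        for c in kt.chromosomes
    ]


def _split_segments(segs, pos):
    """Split a segment tiling at local position ``pos``; return (left, right)."""
    left, right, off = [], [], 0
    for chrom, s, e, strand in segs:
        seg_len = e - s
        if off + seg_len <= pos:
            left.append((chrom, s, e, strand))
        elif off >= pos:
            right.append((chrom, s, e, strand))
        else:
            d = pos - off
            if strand == +1:
                left.append((chrom, s, s + d, strand))
                right.append((chrom, s + d, e, strand))
            else:
                left.append((chrom, e - d, e, strand))
                right.append((chrom, s, e - d, strand))
        off += seg_len
    return left, right


def _anc_position(segs, pos):
    """Map a local position to (ancestor_chrom, ancestor_pos)."""
    off = 0
    for chrom, s, e, strand in segs:
        if off <= pos < off + (e - s) or (pos == off + (e - s) and (chrom, s, e, strand) == segs[-1]):
            d = pos - off
            return (chrom, s + d) if strand == +1 else (chrom, e - d)
        off += e - s
    raise ValueError(f"position {pos} outside segment tiling")


def _split_feats(feats, pos, allow_gene_split):
    left, right = [], []
    for f in feats:
        if f.end <= pos:
            left.append(f)
        elif f.start >= pos:
            right.append(Feature(f.chrom, f.start - pos, f.end - pos, f.name,
                                 f.category, f.strand, f.family))
        else:  # spans the cut
            if f.category == "gene" and not allow_gene_split:
                raise ValueError(f"cut at {pos} would disrupt gene {f.name!r}")
            left.append(Feature(f.chrom, f.start, pos, f.name, f.category, f.strand, f.family))
            right.append(Feature(f.chrom, 0, f.end - pos, f.name, f.category, f.strand, f.family))
    return left, right


def _rename(feats, name):
    return [Feature(name, f.start, f.end, f.name, f.category, f.strand, f.family)
            for f in feats]


def _do_fission(w: _WChrom, pos: int, names: tuple[str, str], allow_gene_split=False):
    if not 0 < pos < w.length:
        raise ValueError(f"fission position {pos} not strictly inside {w.name!r}")
    fl, fr = _split_feats(w.feats, pos, allow_gene_split)
    sl, sr = _split_segments(w.segments, pos)
    ml = [(p, k, i) for p, k, i in w.markers if p <= pos]
    mr = [(p - pos, k, i) for p, k, i in w.markers if p > pos]
    left = _WChrom(names[0], pos, w.seq[:pos] if w.seq else None,
                   _rename(fl, names[0]), sl, ml)
    right = _WChrom(names[1], w.length - pos, w.seq[pos:] if w.seq else None,
                    _rename(fr, names[1]), sr, mr)
    return left, right


def _do_fusion(w1: _WChrom, w2: _WChrom, name: str, event_index: int) -> _WChrom:
    off = w1.length
    feats = _rename(w1.feats, name) + [
        Feature(name, f.start + off, f.end + off, f.name, f.category, f.strand, f.family)
        for f in w2.feats
    ]
    markers = [(p, k, i) for p, k, i in w1.markers]
    markers += [(p + off, k, i) for p, k, i in w2.markers]
    markers.append((off, "fusion", event_index))
    seq = (w1.seq + w2.seq) if (w1.seq is not None and w2.seq is not None) else None
    return _WChrom(name, w1.length + w2.length, seq, feats,
                   w1.segments + w2.segments, markers)


def _do_inversion(w: _WChrom, p1: int, p2: int, event_index: int,
                  allow_gene_split=False) -> _WChrom:
    if not 0 <= p1 < p2 <= w.length:
        raise ValueError(f"invalid inversion [{p1},{p2}) on {w.name!r}")
    for f in w.feats:
        if f.category == "gene" and not allow_gene_split:
            if f.start < p1 < f.end or f.start < p2 < f.end:
                raise ValueError(f"inversion boundary inside gene {f.name!r}")
    feats = []
    for f in w.feats:
        if f.end <= p1 or f.start >= p2:
            feats.append(f)
        else:
            ns = p1 + (p2 - min(f.end, p2))
            ne = p1 + (p2 - max(f.start, p1))
            strand = {"+": "-", "-": "+"}.get(f.strand, f.strand)
            feats.append(Feature(f.chrom, ns, ne, f.name, f.category, strand, f.family))
    seq = None
    if w.seq is not None:
        seq = w.seq[:p1] + revcomp(w.seq[p1:p2]) + w.seq[p2:]
    mid_l, rest = _split_segments(w.segments, p1)
    mid, right = _split_segments(rest, p2 - p1)
    inverted = [(c, s, e, -strand) for c, s, e, strand in reversed(mid)]
    markers = []
    for p, k, i in w.markers:
        if p1 < p < p2:
            markers.append((p1 + (p2 - p), k, i))
        else:
            markers.append((p, k, i))
    markers += [(p1, "inversion", event_index), (p2, "inversion", event_index)]
    return _WChrom(w.name, w.length, seq, feats, mid_l + inverted + right, markers)


def _do_translocation(w1: _WChrom, p1: int, w2: _WChrom, p2: int,
                      event_index: int, allow_gene_split=False):
    a_l, a_r = _do_fission(w1, p1, (w1.name, "__tmpA"), allow_gene_split) \
        if 0 < p1 < w1.length else (None, None)
    if a_l is None:
        raise ValueError(f"translocation position {p1} not strictly inside {w1.name!r}")
    b_l, b_r = _do_fission(w2, p2, (w2.name, "__tmpB"), allow_gene_split) \
        if 0 < p2 < w2.length else (None, None)
    if b_l is None:
        raise ValueError(f"translocation position {p2} not strictly inside {w2.name!r}")
    new1 = _do_fusion(a_l, b_r, w1.name, event_index)
    new2 = _do_fusion(b_l, a_r, w2.name, event_index)
    # relabel the junction markers as translocation junctions
    new1.markers = [(p, "translocation" if (k == "fusion" and i == event_index) else k, i)
                    for p, k, i in new1.markers]
    new2.markers = [(p, "translocation" if (k == "fusion" and i == event_index) else k, i)
                    for p, k, i in new2.markers]
    return new1, new2


def _cut_weights(w: _WChrom, breakpoint_bias: float, bias_family: str | None):
    reps = [(f.start, f.end) for f in w.feats
            if f.category == "repeat" and (bias_family is None or f.family == bias_family)]
    return _PiecewiseWeights(w.length, reps, breakpoint_bias)


def _boundary_zones(w: _WChrom, radius: int) -> list[tuple[int, int]]:
    """Exclusion zones around internal segment boundaries (local coords)."""
    if radius <= 0:
        return []
    zones = []
    off = 0
    for chrom, s, e, strand in w.segments[:-1]:
        off += e - s
        zones.append((off - radius, off + radius))
    return zones


def _sample_cut(rng, w: _WChrom, margin: int, weights: _PiecewiseWeights | None,
                lo: int | None = None, hi: int | None = None,
                forbidden: list[tuple[int, int]] | None = None) -> int | None:
    lo = margin if lo is None else max(lo, 1)
    hi = (w.length - margin) if hi is None else min(hi, w.length - 1)
    if hi <= lo:
        return None
    genes = sorted((f.start, f.end) for f in w.feats if f.category == "gene")
    starts = [g[0] for g in genes]
    for _ in range(200):
        if weights is None:
            pos = int(rng.integers(lo, hi))
        else:
            pos = int(weights.sample(rng, 1)[0])
            if not lo <= pos < hi:
                continue
        if forbidden and any(zl < pos < zh for zl, zh in forbidden):
            continue
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and genes[i][0] < pos < genes[i][1]:
            continue
        return pos
    return None


def sample_plan(
    genome: SimulatedGenome,
    n_events: int,
    rates: dict[str, float] | None = None,
    seed: int = 0,
    *,
    counts: dict[str, int] | None = None,
    breakpoint_bias: float = 1.0,
    bias_family: str | None = None,
    use_hotspots: bool = False,
    edge_margin: float = 0.1,
    min_fragment: int = 0,
    inversion_span: tuple[float, float] = (0.05, 0.3),
) -> list[dict]:
    """Draw a random, applicable event plan for ``apply_rearrangements``.

    Chromosomes are chosen with probability proportional to length and cut
    positions avoid gene bodies. ``edge_margin`` (fraction of the current
    chromosome length) keeps cuts away from chromosome ends so that both
    products remain full-sized chromosomes, as in observed karyotype
    changes; ``min_fragment`` enforces an absolute lower bound on every
    product, and ``inversion_span`` bounds inverted-segment lengths as
    fractions of the chromosome. With ``use_hotspots`` cuts are drawn from the ancestor's
    hotspot regions (one hotspot consumed per cut); otherwise positions
    inside repeat intervals (optionally of one family) have their sampling
    weight multiplied by ``breakpoint_bias``.

    The plan is expressed against evolving chromosome names, simulating the
    events on a scratch copy to keep every step applicable.
    """
    rng = np.random.default_rng(seed)
    if counts is not None:
        kind_sequence = [k for k, n in counts.items() for _ in range(n)]
        rng.shuffle(kind_sequence)
        n_events = len(kind_sequence)
    else:
        kind_sequence = None
        if rates is None:
            rates = {"fission": 0.6, "inversion": 0.3, "translocation": 0.1}
        kinds = [k for k in rates if rates[k] > 0]
        probs = np.array([rates[k] for k in kinds], dtype=float)
        probs /= probs.sum()

    work = _wrap(genome.karyotype, genome.track)
    hotspot_pool = list(genome.hotspots)
    rng.shuffle(hotspot_pool)
    plan: list[dict] = []
    n_fiss = 0

    def pick_chrom(exclude: str | None = None) -> _WChrom | None:
        cand = [w for w in work if w.name != exclude]
        if not cand:
            return None
        lens = np.array([w.length for w in cand], dtype=float)
        return cand[int(rng.choice(len(cand), p=lens / lens.sum()))]

    def hotspot_cut(kind_margin_frac: float):
        """Map the next unused hotspot centre into current coordinates."""
        while hotspot_pool:
            hchrom, hs, he = hotspot_pool.pop()
            for w in work:
                off = 0
                for chrom, s, e, strand in w.segments:
                    if chrom == hchrom and s <= (hs + he) // 2 < e:
                        centre = (hs + he) // 2
                        local = off + (centre - s if strand == +1 else e - centre)
                        margin = int(kind_margin_frac * w.length)
                        pos = _sample_cut(rng, w, 0, None,
                                          lo=max(local - (he - hs) // 2, margin),
                                          hi=min(local + (he - hs) // 2, w.length - margin))
                        if pos is not None:
                            return w, pos
                    off += e - s
        return None, None

    def cut_margin(w: _WChrom) -> int:
        return max(int(edge_margin * w.length), min_fragment)

    for gen in range(1, n_events + 1):
        if kind_sequence is not None:
            kind = kind_sequence[gen - 1]
        else:
            kind = kinds[int(rng.choice(len(kinds), p=probs))]
        if kind == "fusion" and len(work) < 2:
            kind = "fission"
        step: dict | None = None

        for _attempt in range(30):
            if kind == "fission":
                if use_hotspots:
                    w, pos = hotspot_cut(edge_margin)
                else:
                    w = pick_chrom()
                    pos = _sample_cut(
                        rng, w, cut_margin(w),
                        _cut_weights(w, breakpoint_bias, bias_family)
                        if breakpoint_bias != 1.0 else None,
                        forbidden=_boundary_zones(w, min_fragment)) if w else None
                if w is not None and pos is not None:
                    n_fiss += 1
                    names = (f"{w.name}a", f"{w.name}b")
                    step = {"kind": "fission", "chrom": w.name, "pos": pos}
                    l, r = _do_fission(w, pos, names)
                    work[work.index(w)] = l
                    work.insert(work.index(l) + 1, r)
            elif kind == "fusion":
                w1 = pick_chrom()
                w2 = pick_chrom(exclude=w1.name if w1 else None)
                if w1 is not None and w2 is not None:
                    step = {"kind": "fusion", "chrom_1": w1.name, "chrom_2": w2.name}
                    fused = _do_fusion(w1, w2, f"{w1.name}~{w2.name}", gen)
                    work.remove(w2)
                    work[work.index(w1)] = fused
            elif kind == "inversion":
                w = pick_chrom()
                if w is not None:
                    weights = (_cut_weights(w, breakpoint_bias, bias_family)
                               if breakpoint_bias != 1.0 else None)
                    margin = cut_margin(w)
                    zones = _boundary_zones(w, min_fragment)
                    p1 = _sample_cut(rng, w, margin, weights, forbidden=zones)
                    if p1 is not None:
                        span = int(rng.uniform(*inversion_span) * w.length)
                        span_lo = max(10_000, min_fragment)
                        p2 = _sample_cut(rng, w, margin, weights,
                                         lo=p1 + span_lo,
                                         hi=min(p1 + max(span, span_lo + 1),
                                                w.length - margin),
                                         forbidden=zones)
                        if p2 is not None:
                            step = {"kind": "inversion", "chrom": w.name,
                                    "start": p1, "end": p2}
                            work[work.index(w)] = _do_inversion(w, p1, p2, gen)
            elif kind == "translocation":
                w1 = pick_chrom()
                w2 = pick_chrom(exclude=w1.name if w1 else None)
                if w1 is not None and w2 is not None:
                    p1 = _sample_cut(rng, w1, cut_margin(w1), None,
                                     forbidden=_boundary_zones(w1, min_fragment))
                    p2 = _sample_cut(rng, w2, cut_margin(w2), None,
                                     forbidden=_boundary_zones(w2, min_fragment))
                    if p1 is not None and p2 is not None:
                        step = {"kind": "translocation",
                                "chrom_1": w1.name, "pos_1": p1,
                                "chrom_2": w2.name, "pos_2": p2}
                        n1, n2 = _do_translocation(w1, p1, w2, p2, gen)
                        work[work.index(w1)] = n1
                        work[work.index(w2)] = n2
            if step is not None:
                plan.append(step)
                break
    return plan


def apply_rearrangements(
    genome: SimulatedGenome,
    plan: list[dict],
    *,
    derived_id: str = "derived",
    allow_gene_split: bool = False,
    seed: int = 0,
) -> SimulatedGenome:
    """Apply an explicit event plan and record exact breakpoint truth.

    Each plan step is a dict: ``{"kind": "fission", "chrom", "pos"}``,
    ``{"kind": "fusion", "chrom_1", "chrom_2"}``, ``{"kind": "inversion",
    "chrom", "start", "end"}`` or ``{"kind": "translocation", "chrom_1",
    "pos_1", "chrom_2", "pos_2"}``, interpreted against the evolving
    karyotype in order. Use :func:`sample_plan` to draw random plans.

    Returns the derived genome; its ``truth`` carries the event list, the
    true breakpoints (as 2-bp intervals, in ancestor coordinates for every
    cut and in derived coordinates for fusion/inversion/translocation
    junctions) and the ancestor->derived ortholog map.
    """
    del seed  # plans are explicit; kept for a uniform call signature
    work = _wrap(genome.karyotype, genome.track)
    anc_id = genome.karyotype.genome_id
    total0 = genome.karyotype.total_length

    events: list[RearrangementEvent] = []
    anc_bps: list[BreakpointInterval] = []
    anc_lengths = genome.karyotype.lengths

    def record_anc(segs, pos, kind, idx):
        chrom, apos = _anc_position(segs, pos)
        lo = max(0, apos - 1)
        hi = min(anc_lengths[chrom], apos + 1)
        anc_bps.append(BreakpointInterval(chrom, lo, hi, kind, idx))

    def get(name: str) -> _WChrom:
        for w in work:
            if w.name == name:
                return w
        raise ValueError(f"plan references unknown chromosome {name!r}")

    for gen, step in enumerate(plan, start=1):
        kind = step["kind"]
        if kind == "fission":
            w = get(step["chrom"])
            pos = int(step["pos"])
            record_anc(w.segments, pos, "fission", gen)
            names = (f"{w.name}a", f"{w.name}b")
            l, r = _do_fission(w, pos, names, allow_gene_split)
            i = work.index(w)
            work[i:i + 1] = [l, r]
            events.append(RearrangementEvent("fission", gen, [(w.name, pos)],
                                             [w.name], list(names)))
        elif kind == "fusion":
            w1, w2 = get(step["chrom_1"]), get(step["chrom_2"])
            name = f"{w1.name}~{w2.name}"
            fused = _do_fusion(w1, w2, name, gen)
            work[work.index(w1)] = fused
            work.remove(w2)
            events.append(RearrangementEvent("fusion", gen, [], [w1.name, w2.name], [name]))
        elif kind == "inversion":
            w = get(step["chrom"])
            p1, p2 = int(step["start"]), int(step["end"])
            record_anc(w.segments, p1, "inversion", gen)
            record_anc(w.segments, p2, "inversion", gen)
            work[work.index(w)] = _do_inversion(w, p1, p2, gen, allow_gene_split)
            events.append(RearrangementEvent("inversion", gen, [(w.name, p1), (w.name, p2)],
                                             [w.name], [w.name]))
        elif kind == "translocation":
            w1, w2 = get(step["chrom_1"]), get(step["chrom_2"])
            p1, p2 = int(step["pos_1"]), int(step["pos_2"])
            record_anc(w1.segments, p1, "translocation", gen)
            record_anc(w2.segments, p2, "translocation", gen)
            n1, n2 = _do_translocation(w1, p1, w2, p2, gen, allow_gene_split)
            work[work.index(w1)] = n1
            work[work.index(w2)] = n2
            events.append(RearrangementEvent(
                "translocation", gen,
                [(w1.name, p1), (w2.name, p2)], [w1.name, w2.name], [w1.name, w2.name]))
        else:
            raise ValueError(f"unknown event kind {kind!r}")

    chroms = [Chromosome(w.name, w.length, w.seq) for w in work]
    kt = Karyotype(derived_id, chroms)
    if kt.total_length != total0:
        raise AssertionError("event application failed to conserve genome length")
    feats = [f for w in work for f in w.feats]
    track = FeatureTrack(derived_id, feats)
    track.validate(kt)

    der_bps = [
        BreakpointInterval(w.name, max(0, p - 1), min(w.length, p + 1), k, i)
        for w in work for p, k, i in w.markers if 0 < p < w.length
    ]

    genes_anc = {f.name: f for f in genome.track.genes()}
    rows = []
    for f in track.genes():
        g = genes_anc[f.name]
        rows.append((g.name, f.name, g.chrom, g.start, g.end, g.strand,
                     f.chrom, f.start, f.end, f.strand))
    omap = pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)

    truth = TruthSet(events, {anc_id: anc_bps, derived_id: der_bps}, omap)
    return SimulatedGenome(kt, track, [], truth)


# ---------------------------------------------------------------------------
# anchors and ortholog-map utilities


def emit_anchors(
    ortholog_map: pd.DataFrame,
    dropout: float = 0.0,
    jitter_sd: float = 0.0,
    micro_inversion_rate: float = 0.0,
    seed: int = 0,
    *,
    lengths_a: dict[str, int] | None = None,
    lengths_b: dict[str, int] | None = None,
    genome_a: str = "A",
    genome_b: str = "B",
) -> AnchorSet:
    """Turn an ortholog map into a noisy anchor set.

    ``dropout`` removes each pair independently; ``jitter_sd`` shifts both
    intervals by independent Gaussian offsets (clamped to the chromosome
    when lengths are given); ``micro_inversion_rate`` flips the anchor
    orientation without touching coordinates.
    """
    if ortholog_map.empty:
        raise ValueError("ortholog map is empty")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    anchors: list[Anchor] = []
    for _, row in ortholog_map.iterrows():
        if dropout > 0 and rng.random() < dropout:
            continue
        sa, ea = int(row.start_a), int(row.end_a)
        sb, eb = int(row.start_b), int(row.end_b)
        if jitter_sd > 0:
            for which in ("a", "b"):
                shift = int(round(rng.normal(0.0, jitter_sd)))
                if which == "a":
                    lim = lengths_a.get(row.chrom_a) if lengths_a else None
                    lo = max(0, sa + shift)
                    if lim is not None:
                        lo = min(lo, lim - (ea - sa))
                    sa, ea = lo, lo + (ea - sa)
                else:
                    lim = lengths_b.get(row.chrom_b) if lengths_b else None
                    lo = max(0, sb + shift)
                    if lim is not None:
                        lo = min(lo, lim - (eb - sb))
                    sb, eb = lo, lo + (eb - sb)
        orient = "+" if row.strand_a == row.strand_b else "-"
        if micro_inversion_rate > 0 and rng.random() < micro_inversion_rate:
            orient = "-" if orient == "+" else "+"
        anchors.append(Anchor(
            row.chrom_a, sa, ea, row.chrom_b, sb, eb, orient,
            weight=float(min(ea - sa, eb - sb)),
            source="ortholog", id=f"{row.gene_a}|{row.gene_b}",
        ))
    return AnchorSet(genome_a, genome_b, anchors)


def cross_ortholog_map(map_1: pd.DataFrame, map_2: pd.DataFrame) -> pd.DataFrame:
    """Compose two ancestor->derived maps into a derived-1 vs derived-2 map.

    Rows are joined on the shared ancestor gene id (``gene_a``); the result
    has derived genome 1 on the A side and derived genome 2 on the B side.
    """
    m1 = map_1.rename(columns={
        "gene_b": "g1", "chrom_b": "c1", "start_b": "s1", "end_b": "e1", "strand_b": "t1"})
    m2 = map_2.rename(columns={
        "gene_b": "g2", "chrom_b": "c2", "start_b": "s2", "end_b": "e2", "strand_b": "t2"})
    j = m1.merge(m2[["gene_a", "g2", "c2", "s2", "e2", "t2"]], on="gene_a")
    out = pd.DataFrame({
        "gene_a": j["g1"], "gene_b": j["g2"],
        "chrom_a": j["c1"], "start_a": j["s1"], "end_a": j["e1"], "strand_a": j["t1"],
        "chrom_b": j["c2"], "start_b": j["s2"], "end_b": j["e2"], "strand_b": j["t2"],
    })
    return out


# ---------------------------------------------------------------------------
# scaffold-level emulation (flow-sorting and shredding)


def shred_karyotype(
    genome: SimulatedGenome,
    n_pieces_per_chrom: int,
    seed: int = 0,
    *,
    shuffle: bool = True,
    scaffold_prefix: str = "scaf",
) -> tuple[SimulatedGenome, pd.DataFrame]:
    """Cut each chromosome into scaffolds at random gene-free positions.

    Returns the scaffold-level genome (chromosome per scaffold, features
    remapped, gene ids preserved) and a truth table with columns
    ``scaffold, chrom, order, offset, length`` giving the correct layout.
    """
    rng = np.random.default_rng(seed)
    pieces: list[_WChrom] = []
    rows = []
    counter = 0
    for w in _wrap(genome.karyotype, genome.track):
        cuts: list[int] = []
        lo = 1
        for _ in range(n_pieces_per_chrom - 1):
            pos = _sample_cut(rng, w, max(1, w.length // (4 * n_pieces_per_chrom)), None)
            if pos is not None:
                cuts.append(pos)
        cuts = sorted(set(cuts))
        del lo
        rest = w
        offset = 0
        order = 0
        for pos in cuts:
            counter += 1
            left, rest = _do_fission(rest, pos - offset, (f"{scaffold_prefix}{counter}", rest.name))
            rows.append((left.name, w.name, order, offset, left.length))
            pieces.append(left)
            order += 1
            offset = pos
        counter += 1
        rest = _WChrom(f"{scaffold_prefix}{counter}", rest.length, rest.seq,
                       _rename(rest.feats, f"{scaffold_prefix}{counter}"),
                       rest.segments, rest.markers)
        rows.append((rest.name, w.name, order, offset, rest.length))
        pieces.append(rest)
    if shuffle:
        perm = rng.permutation(len(pieces))
        pieces = [pieces[i] for i in perm]
    kt = Karyotype(genome.genome_id + "_scaffolds",
                   [Chromosome(p.name, p.length, p.seq) for p in pieces])
    track = FeatureTrack(kt.genome_id, [f for p in pieces for f in p.feats])
    truth = pd.DataFrame(rows, columns=["scaffold", "chrom", "order", "offset", "length"])
    return SimulatedGenome(kt, track), truth


def simulate_flow_sort_coverage(
    scaffold_truth: pd.DataFrame,
    chrom_names: list[str],
    seed: int = 0,
    *,
    depth_range: tuple[float, float] = (60.0, 270.0),
    background: float = 0.5,
    noise_cv: float = 0.05,
    mixed_libraries: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Emulate per-chromosome flow-sorted sequencing depth over scaffolds.

    Each chromosome yields one library with a depth drawn from
    ``depth_range`` (libraries are deliberately unequal, as real sorted
    libraries are); scaffolds from that chromosome receive the library
    depth with multiplicative noise, all others a small background.
    ``mixed_libraries`` lists chromosome pairs co-sorted into a single
    library (both pairs' scaffolds then share that library's signal), with
    the second chromosome of each pair contributing no library of its own.
    """
    rng = np.random.default_rng(seed)
    mixed_libraries = mixed_libraries or []
    merged_into = {b: a for a, b in mixed_libraries}
    libs = [c for c in chrom_names if c not in merged_into]
    lib_depth = {lib: rng.uniform(*depth_range) for lib in libs}
    lib_members = {lib: {lib} for lib in libs}
    for a, b in mixed_libraries:
        lib_members[a].add(b)

    scaffolds = scaffold_truth["scaffold"].tolist()
    true_chrom = dict(zip(scaffold_truth["scaffold"], scaffold_truth["chrom"]))
    mat = np.zeros((len(scaffolds), len(libs)))
    for i, sc in enumerate(scaffolds):
        for j, lib in enumerate(libs):
            base = lib_depth[lib] if true_chrom[sc] in lib_members[lib] else background
            mat[i, j] = max(0.0, base * (1.0 + rng.normal(0.0, noise_cv)))
    df = pd.DataFrame(mat, index=scaffolds, columns=[f"lib_{lib}" for lib in libs])
    df.index.name = "scaffold"
    return df
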