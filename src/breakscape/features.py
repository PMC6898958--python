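"""Genomic features of region sets and enrichment statistics.

EBRs are profiled against the rest of the genome in fixed windows: gene
density (genes/Mb, counted by midpoint), GC fraction (N excluded from the
denominator) and repeat coverage fraction. The EBR-overlapping windows are
compared against all windows of the chromosome (or genome) with the
Mann-Whitney U test, mirroring the usual "EBR versus whole chromosome"
contrast. Repeat families are additionally ranked by coverage fold change
with a permutation p value from random length-matched region placements,
and genes found in EBRs can be tested for gene-set overrepresentation with
a hypergeometric test and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .breakpoints import EBR
from .core import FeatureTrack, Karyotype

__all__ = [
    "RegionFeatureStats",
    "EnrichmentResult",
    "gc_content",
    "region_density",
    "mann_whitney_u",
    "MannWhitneyResult",
    "window_feature_table",
    "compare_ebr_features",
    "repeat_family_enrichment",
    "geneset_overrepresentation",
    "genes_in_regions",
]


# ---------------------------------------------------------------------------
# elementary per-region measures


def gc_content(sequence: str, regions: list[tuple[int, int]] | None = None):
    """GC fraction of a sequence or of each listed region.

    (G+C)/(A+C+G+T); N bases are excluded from the denominator. A region
    of only Ns yields NaN. Returns a float for the whole sequence, or a
    list of floats for ``regions``.
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    is_gc = (arr == b"G") | (arr == b"C")
    is_acgt = is_gc | (arr == b"A") | (arr == b"T")
    if regions is None:
        denom = int(is_acgt.sum())
        return float(is_gc.sum() / denom) if denom else float("nan")
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_n = np.concatenate([[0], np.cumsum(is_acgt)])
    out = []
    for s, e in regions:
        if not (0 <= s < e <= len(arr)):
            raise ValueError(f"region [{s},{e}) outside sequence of length {len(arr)}")
        denom = cum_n[e] - cum_n[s]
        out.append(float((cum_gc[e] - cum_gc[s]) / denom) if denom else float("nan"))
    return out


def region_density(
    track: FeatureTrack,
    regions: list[tuple[str, int, int]],
    mode: str = "count_per_mb",
    *,
    category: str | None = None,
    family: str | None = None,
) -> list[float]:
    """Feature density per region.

    ``count_per_mb`` counts features whose midpoint falls in the region,
    scaled to features/Mb; ``coverage_fraction`` sums clipped overlap
    lengths divided by the region length.
    """
    if mode not in ("count_per_mb", "coverage_fraction"):
        raise ValueError(f"unknown mode {mode!r}")
    feats = track.records
    if category is not None:
        feats = [f for f in feats if f.category == category]
    if family is not None:
        feats = [f for f in feats if f.family == family]
    by_chrom: dict[str, list] = {}
    for f in feats:
        by_chrom.setdefault(f.chrom, []).append(f)
    out = []
    for chrom, s, e in regions:
        if e <= s:
            raise ValueError(f"zero-length region [{s},{e}) on {chrom}")
        sel = by_chrom.get(chrom, [])
        if mode == "count_per_mb":
            n = sum(1 for f in sel if s <= f.midpoint < e)
            out.append(n / ((e - s) / 1e6))
        else:
            cov = sum(max(0, min(e, f.end) - max(s, f.start)) for f in sel)
            out.append(cov / (e - s))
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    z: float | None
    method: str
    n1: int
    n2: int

    def __iter__(self):  # allow ``u, p = mann_whitney_u(...)``
        return iter((self.u, self.p))


def mann_whitney_u(
    x,
    y,
    alternative: str = "two-sided",
    method: str = "auto",
) -> MannWhitneyResult:
    """Mann-Whitney U test of two independent samples.

    U counts pairs with x > y (ties counted half). ``method='exact'``
    enumerates the permutation null (requires n1*n2 <= 10000 and no ties,
    otherwise it falls back to the normal approximation); ``'normal'``
    uses the tie-corrected variance with continuity correction; ``'auto'``
    picks exact for small tie-free samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = False
    if method in ("exact", "auto"):
        use_exact = (n1 * n2 <= 10_000) and not has_ties
    scipy_method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=scipy_method,
                             use_continuity=True)
    z = None
    if scipy_method == "asymptotic":
        mu = n1 * n2 / 2.0
        tie_term = 0.0
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
        sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
        z = float((res.statistic - mu) / sigma) if sigma > 0 else 0.0
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), z,
                             scipy_method, n1, n2)


# ---------------------------------------------------------------------------
# window-based EBR feature comparison


@dataclass
class RegionFeatureStats:
    """Mann-Whitney comparison of one feature in EBR windows vs all windows."""

    label: str  # chromosome name or "genome"
    feature: str  # "gene_density" | "gc" | "repeat_coverage"
    n_ebr_windows: int
    n_all_windows: int
    u: float | None
    z: float | None
    p: float | None
    direction: str  # "higher in EBRs" | "lower in EBRs" | "none" | "NA"


def window_feature_table(
    karyotype: Karyotype,
    track: FeatureTrack,
    window: int = 100_000,
) -> pd.DataFrame:
    """Tile each chromosome into fixed windows and profile each window.

    Columns: chrom, start, end, gene_density (genes/Mb by midpoint), gc
    (NaN without sequence), repeat_coverage. The terminal window of a
    chromosome may be shorter than ``window``.
    """
    if window < 1_000:
        raise ValueError("window must be >= 1 kb")
    rows = []
    for c in karyotype.chromosomes:
        starts = np.arange(0, c.length, window)
        ends = np.minimum(starts + window, c.length)
        regions = [(c.name, int(s), int(e)) for s, e in zip(starts, ends)]
        dens = region_density(track, regions, "count_per_mb", category="gene")
        cov = region_density(track, regions, "coverage_fraction", category="repeat")
        if c.sequence is not None:
            gc = gc_content(c.sequence, [(int(s), int(e)) for s, e in zip(starts, ends)])
        else:
            gc = [float("nan")] * len(regions)
        for (chrom, s, e), d, g, r in zip(regions, dens, gc, cov):
            rows.append((chrom, s, e, d, g, r))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "gene_density", "gc", "repeat_coverage"])


_FEATURES = ["gene_density", "gc", "repeat_coverage"]


def compare_ebr_features(
    karyotype: Karyotype,
    track: FeatureTrack,
    ebrs: list[EBR],
    window: int = 100_000,
    *,
    y_mode: str = "all",
    alternative: str = "two-sided",
    table: pd.DataFrame | None = None,
) -> list[RegionFeatureStats]:
    """Compare gene density, GC and repeat coverage in EBR windows vs the genome.

    x = windows overlapping any EBR; y = all windows of the chromosome
    (``y_mode='all'``, the literal "EBRs versus the whole chromosome"
    contrast) or the non-EBR windows (``y_mode='complement'``). One result
    per chromosome and feature, plus pooled genome-wide results labelled
    "genome". Pass a precomputed ``table`` from
    :func:`window_feature_table` to amortize window profiling.
    """
    if y_mode not in ("all", "complement"):
        raise ValueError(f"unknown y_mode {y_mode!r}")
    if table is None:
        table = window_feature_table(karyotype, track, window)
    in_ebr = np.zeros(len(table), dtype=bool)
    starts = table["start"].to_numpy()
    ends = table["end"].to_numpy()
    chroms = table["chrom"].to_numpy()
    for e in ebrs:
        in_ebr |= (chroms == e.chromosome) & (starts < e.end) & (ends > e.start)

    out: list[RegionFeatureStats] = []
    labels = list(dict.fromkeys(table["chrom"])) + ["genome"]
    for label in labels:
        mask = np.ones(len(table), dtype=bool) if label == "genome" else (chroms == label)
        x_mask = mask & in_ebr
        y_mask = mask if y_mode == "all" else (mask & ~in_ebr)
        for feat in _FEATURES:
            vals = table[feat].to_numpy()
            x = vals[x_mask]
            y = vals[y_mask]
            x = x[~np.isnan(x)]
            y = y[~np.isnan(y)]
            if x.size == 0 or y.size == 0:
                out.append(RegionFeatureStats(label, feat, int(x_mask.sum()),
                                              int(y_mask.sum()), None, None, None, "NA"))
                continue
            if np.ptp(np.concatenate([x, y])) == 0:
                out.append(RegionFeatureStats(label, feat, x.size, y.size,
                                              x.size * y.size / 2.0, 0.0, 1.0, "none"))
                continue
            res = mann_whitney_u(x, y, alternative=alternative, method="normal")
            direction = ("higher in EBRs" if res.u > res.n1 * res.n2 / 2.0
                         else "lower in EBRs" if res.u < res.n1 * res.n2 / 2.0
                         else "none")
            out.append(RegionFeatureStats(label, feat, x.size, y.size,
                                          res.u, res.z, res.p, direction))
    return out


def stats_frame(results: list[RegionFeatureStats]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# repeat-family enrichment


class _CoverageIndex:
    """Per-family prefix-sum coverage over one chromosome."""

    def __init__(self, intervals: list[tuple[int, int]]):
        ivals = sorted(intervals)
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self.starts = np.array([m[0] for m in merged], dtype=np.int64)
        self.ends = np.array([m[1] for m in merged], dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(self.ends - self.starts)])

    def covered(self, s, e):
        """Vectorized covered bases of [s,e) (arrays ok)."""
        s = np.asarray(s, dtype=np.int64)
        e = np.asarray(e, dtype=np.int64)

        def prefix(x):
            i = np.searchsorted(self.ends, x, side="right")
            base = self.cum[i]
            partial = np.where(
                (i < len(self.starts)) & (x > self.starts[np.minimum(i, len(self.starts) - 1)]),
                x - self.starts[np.minimum(i, len(self.starts) - 1)], 0)
            return base + np.maximum(partial, 0)

        return prefix(e) - prefix(s)


def repeat_family_enrichment(
    track: FeatureTrack,
    ebrs: list[EBR],
    karyotype: Karyotype,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Coverage fold change of each repeat family in EBRs vs genome-wide.

    fold = (family coverage fraction in EBRs) / (genome-wide fraction);
    the permutation p value places ``n_permutations`` random
    length-matched region sets on the same karyotype and counts folds at
    least as large. Families are returned ranked by fold (descending).
    """
    rng = np.random.default_rng(seed)
    lengths = karyotype.lengths
    total = karyotype.total_length
    families = sorted({f.family for f in track.repeats() if f.family})
    ebr_len = sum(e.length for e in ebrs)
    if ebr_len == 0:
        raise ValueError("empty EBR set")

    idx: dict[str, dict[str, _CoverageIndex]] = {}
    for fam in families:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for f in track.repeats(fam):
            per_chrom.setdefault(f.chrom, []).append((f.start, f.end))
        idx[fam] = {c: _CoverageIndex(iv) for c, iv in per_chrom.items()}

    chrom_names = karyotype.names
    chrom_lens = np.array([lengths[c] for c in chrom_names], dtype=np.int64)
    chrom_p = chrom_lens / chrom_lens.sum()

    # random length-matched placements, shared across families
    ebr_sizes = np.array([e.length for e in ebrs], dtype=np.int64)
    perm_regions = []  # list of (chrom_idx array, start array)
    for _ in range(n_permutations):
        ci = rng.choice(len(chrom_names), size=len(ebr_sizes), p=chrom_p)
        # redraw chromosomes too short for the region
        for k in range(len(ebr_sizes)):
            tries = 0
            while chrom_lens[ci[k]] <= ebr_sizes[k] and tries < 50:
                ci[k] = rng.choice(len(chrom_names), p=chrom_p)
                tries += 1
        maxs = np.maximum(chrom_lens[ci] - ebr_sizes, 1)
        ss = (rng.random(len(ebr_sizes)) * maxs).astype(np.int64)
        perm_regions.append((ci, ss))

    rows = []
    for fam in families:
        fam_idx = idx[fam]
        genome_cov = sum(float(ix.cum[-1]) for ix in fam_idx.values())
        genome_frac = genome_cov / total
        obs_cov = 0
        for e in ebrs:
            ix = fam_idx.get(e.chromosome)
            if ix is not None:
                obs_cov += int(ix.covered(e.start, e.end))
        obs_frac = obs_cov / ebr_len
        if genome_frac == 0:
            rows.append((fam, obs_frac, genome_frac, float("nan"), float("nan")))
            continue
        fold = obs_frac / genome_frac
        hits = 0
        for ci, ss in perm_regions:
            cov = 0
            for k in range(len(ebr_sizes)):
                ix = fam_idx.get(chrom_names[ci[k]])
                if ix is not None:
                    cov += int(ix.covered(ss[k], ss[k] + ebr_sizes[k]))
            if cov / ebr_len >= obs_frac:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
        rows.append((fam, obs_frac, genome_frac, fold, p))
    df = pd.DataFrame(rows, columns=["family", "ebr_fraction", "genome_fraction",
                                     "fold", "perm_p"])
    return df.sort_values("fold", ascending=False, na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene lists and gene-set overrepresentation


def genes_in_regions(track: FeatureTrack, regions) -> list[str]:
    """Ids of genes overlapping any region by >= 1 bp, deduplicated, sorted.

    ``regions`` may be (chrom, start, end) tuples or EBR records.
    """
    triples = [(r.chromosome, r.start, r.end) if isinstance(r, EBR) else tuple(r)
               for r in regions]
    hits = set()
    for g in track.genes():
        for chrom, s, e in triples:
            if g.chrom == chrom and g.start < e and s < g.end:
                hits.add(g.name)
                break
    return sorted(hits)


@dataclass
class EnrichmentResult:
    term: str
    term_size: int
    overlap: int
    p: float
    q: float


def geneset_overrepresentation(
    query_genes,
    annotation: dict[str, set[str]],
    universe,
) -> list[EnrichmentResult]:
    """Hypergeometric overrepresentation of each term in the query set.

    Terms are intersected with the universe first; p is the upper-tail
    hypergeometric probability P(overlap >= observed) and q the
    Benjamini-Hochberg adjusted value across the tested terms. Terms with
    zero overlap are reported with p = 1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes) & universe
    n_u = len(universe)
    n_q = len(query)
    results = []
    for term, genes in sorted(annotation.items()):
        in_u = set(genes) & universe
        k = len(in_u & query)
        # P(X >= k), X ~ Hypergeom(N=n_u, K=|term|, n=n_q)
        p = float(stats.hypergeom.sf(k - 1, n_u, len(in_u), n_q)) if in_u else 1.0
        p = min(1.0, p)
        results.append([term, len(in_u), k, p])
    ps = np.array([r[3] for r in results])
    qs = _benjamini_hochberg(ps)
    return [EnrichmentResult(term, size, k, p, float(q))
            for (term, size, k, p), q in zip(results, qs)]


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return np.maximum(out, p)  # q >= p elementwise
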