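"""Feature statistics: GC, densities, Mann-Whitney U, enrichment oracles."""


import math

import numpy as np
import pytest

from breakscape.breakpoints import EBR
from breakscape.core import Chromosome, Feature, FeatureTrack, Karyotype
from breakscape.features import (
    compare_ebr_features,
    gc_content,
    genes_in_regions,
    geneset_overrepresentation,
    mann_whitney_u,
    region_density,
    repeat_family_enrichment,
    window_feature_table,
)


# ---------------------------------------------------------------------------
# GC and densities


@pytest.mark.parametrize("seq,expect", [("ATGC", 0.5), ("AAAA", 0.0), ("ATGN", 1 / 3)])
def test_gc_content_counts_gc_over_non_n(seq, expect):
    assert gc_content(seq) == pytest.approx(expect)


def test_gc_of_all_n_region_is_nan_and_bad_region_rejected():
    assert math.isnan(gc_content("NNNN"))
    with pytest.raises(ValueError):
        gc_content("ACGT", regions=[(2, 8)])


def test_region_gc_matches_whole_string_slices():
    rng = np.random.default_rng(1)
    seq = "".join(rng.choice(list("ACGTN"), size=500, p=[0.3, 0.25, 0.2, 0.2, 0.05]))
    regions = [(0, 100), (100, 350), (42, 43), (0, 500)]
    per_region = gc_content(seq, regions)
    for (s, e), got in zip(regions, per_region):
        expect = gc_content(seq[s:e])
        assert got == pytest.approx(expect, nan_ok=True)


def _toy_track():
    feats = [
        Feature("chr1", 100, 300, "g1", "gene"),
        Feature("chr1", 400, 600, "g2", "gene"),
        Feature("chr1", 900, 980, "g3", "gene"),
        Feature("chr1", 0, 500, "family:LINE-L1", "repeat", family="LINE-L1"),
    ]
    return FeatureTrack("g", feats)


def test_count_density_uses_midpoints():
    track = _toy_track()
    # midpoints at 200, 500, 940
    (d,) = region_density(track, [("chr1", 0, 1_000_000)], "count_per_mb",
                          category="gene")
    assert d == 3.0
    (d2,) = region_density(track, [("chr1", 450, 1_000_000)], "count_per_mb",
                           category="gene")
    assert d2 == pytest.approx(2 / ((1_000_000 - 450) / 1e6))


def test_coverage_density_clips_overlap():
    track = _toy_track()
    (c,) = region_density(track, [("chr1", 0, 1000)], "coverage_fraction",
                          category="repeat")
    assert c == 0.5
    with pytest.raises(ValueError):
        region_density(track, [("chr1", 5, 5)], "coverage_fraction")


def test_densities_match_per_base_oracle_on_random_toy():
    rng = np.random.default_rng(7)
    feats = []
    pos = 0
    i = 0
    while pos < 9_500:  # non-overlapping, as repeat tracks are by contract
        pos += int(rng.integers(10, 300))
        length = int(rng.integers(10, 400))
        if pos + length > 10_000:
            break
        feats.append(Feature("c", pos, pos + length, f"r{i}", "repeat", family="F"))
        pos += length
        i += 1
    track = FeatureTrack("g", feats)
    regions = [("c", int(s), int(s) + 1_000) for s in rng.integers(0, 9_000, size=5)]
    got = region_density(track, regions, "coverage_fraction", category="repeat")
    for (chrom, s, e), val in zip(regions, got):
        base = np.zeros(10_000, dtype=bool)
        for f in feats:
            base[f.start:f.end] = True
        assert val == pytest.approx(base[s:e].mean())


# ---------------------------------------------------------------------------
# Mann-Whitney U


from oracles import mwu_exact_two_sided_p as exact_two_sided_p


def test_worked_example_exact_p():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
    assert res.u == 0 and res.p == pytest.approx(0.1)


def test_identical_samples_give_central_u():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.u == 4.5  # n1*n2/2


def test_u_complementarity():
    rng = np.random.default_rng(0)
    x = rng.normal(size=8)
    y = rng.normal(size=5)
    assert mann_whitney_u(x, y).u + mann_whitney_u(y, x).u == pytest.approx(40)


@pytest.mark.parametrize("seed", range(8))
def test_exact_method_equals_full_enumeration(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(2, 6, size=2)
    vals = rng.permutation(100)[: n1 + n2].astype(float)  # tie-free
    x, y = vals[:n1], vals[n1:]
    res = mann_whitney_u(x, y, method="exact")
    assert res.p == pytest.approx(exact_two_sided_p(list(x), list(y)))


def test_normal_approximation_close_to_exact_for_n7():
    rng = np.random.default_rng(2)
    worst = 0.0
    for _ in range(25):
        x = rng.permutation(1000)[:7].astype(float)
        y = rng.permutation(1000)[700:707].astype(float)
        pe = mann_whitney_u(x, y, method="exact").p
        pn = mann_whitney_u(x, y, method="normal").p
        worst = max(worst, abs(pe - pn))
    assert worst <= 0.02


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# window comparison


def _flat_genome():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=200_000))
    kt = Karyotype("g", [Chromosome("chr1", 200_000, seq)])
    feats = [Feature("chr1", i * 10_000 + 1_000, i * 10_000 + 3_000, f"g{i}", "gene")
             for i in range(20)]
    return kt, FeatureTrack("g", feats)


def test_identical_windows_give_p_one():
    kt, track = _flat_genome()
    ebrs = [EBR("g", "chr1", 50_000, 60_000)]
    res = compare_ebr_features(kt, track, ebrs, window=10_000)
    gene_rows = [r for r in res if r.feature == "gene_density"]
    assert all(r.p == 1.0 and r.direction == "none" for r in gene_rows)


def test_no_overlapping_windows_yields_na():
    kt, track = _flat_genome()
    res = compare_ebr_features(kt, track, [], window=10_000)
    assert all(r.direction == "NA" and r.p is None for r in res)


def test_elevated_ebr_windows_detected_as_higher():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
    kt = Karyotype("g", [Chromosome("chr1", 1_000_000, seq)])
    feats = []
    gi = 0
    for i in range(100):  # baseline one gene per 10 kb window
        feats.append(Feature("chr1", i * 10_000 + 100, i * 10_000 + 600, f"g{gi}", "gene"))
        gi += 1
    for i in range(90, 100):  # 5x denser in the tail, which we call the EBR
        for k in range(4):
            s = i * 10_000 + 1_000 + k * 2_000
            feats.append(Feature("chr1", s, s + 500, f"g{gi}", "gene"))
            gi += 1
    track = FeatureTrack("g", feats)
    ebrs = [EBR("g", "chr1", 900_000, 1_000_000)]
    res = compare_ebr_features(kt, track, ebrs, window=10_000)
    (r,) = [r for r in res if r.label == "genome" and r.feature == "gene_density"]
    assert r.direction == "higher in EBRs" and r.p < 0.01


# ---------------------------------------------------------------------------
# repeat family enrichment


def _repeat_genome():
    kt = Karyotype("g", [Chromosome("chr1", 1_000_000)])
    feats = []
    # family A: 10% of the EBR [0,100k), 5% genome-wide overall
    for i in range(10):
        feats.append(Feature("chr1", i * 10_000, i * 10_000 + 1_000,
                             "family:A", "repeat", family="A"))
    for i in range(10, 90):
        if i % 2 == 0:
            feats.append(Feature("chr1", i * 10_000, i * 10_000 + 1_000,
                                 "family:A", "repeat", family="A"))
    return kt, FeatureTrack("g", feats)


def test_fold_change_is_coverage_ratio():
    kt, track = _repeat_genome()
    ebrs = [EBR("g", "chr1", 0, 100_000)]
    df = repeat_family_enrichment(track, ebrs, kt, n_permutations=10, seed=0)
    row = df[df.family == "A"].iloc[0]
    assert row.ebr_fraction == pytest.approx(0.1)
    assert row.fold == pytest.approx(row.ebr_fraction / row.genome_fraction)


def test_whole_genome_as_ebr_gives_fold_one():
    kt, track = _repeat_genome()
    ebrs = [EBR("g", "chr1", 0, 1_000_000)]
    df = repeat_family_enrichment(track, ebrs, kt, n_permutations=10, seed=0)
    assert df.iloc[0].fold == pytest.approx(1.0)


def test_absent_family_flagged_not_ranked():
    kt = Karyotype("g", [Chromosome("chr1", 100_000)])
    track = FeatureTrack("g", [Feature("chr1", 0, 1_000, "family:B", "repeat", family="B")])
    ebrs = [EBR("g", "chr1", 0, 10_000)]
    df = repeat_family_enrichment(track, ebrs, kt, n_permutations=10, seed=0)
    assert set(df.family) == {"B"}  # only families present genome-wide are testable


# ---------------------------------------------------------------------------
# gene lists and overrepresentation


def test_gene_region_overlap_uses_one_bp_half_open_rule():
    track = FeatureTrack("g", [Feature("c", 5, 10, "in", "gene"),
                               Feature("c", 5, 9, "out", "gene")])
    assert genes_in_regions(track, [("c", 9, 20)]) == ["in"]


def test_genes_in_regions_matches_per_base_oracle():
    rng = np.random.default_rng(11)
    feats = [Feature("c", int(s), int(s) + int(rng.integers(5, 50)), f"g{i}", "gene")
             for i, s in enumerate(rng.integers(0, 9_900, size=60))]
    track = FeatureTrack("g", feats)
    regions = [("c", int(s), int(s) + 500) for s in rng.integers(0, 9_400, size=4)]
    expected = set()
    for f in feats:
        base = set(range(f.start, f.end))
        for _, s, e in regions:
            if base & set(range(s, e)):
                expected.add(f.name)
    assert genes_in_regions(track, regions) == sorted(expected)


from oracles import hypergeom_upper_tail as brute_force_upper_tail


def test_worked_hypergeometric_example():
    universe = [f"u{i}" for i in range(20)]
    term = set(universe[:5])
    query = universe[1:5] + [universe[10]]  # overlap 4
    (res,) = geneset_overrepresentation(query, {"T": term}, universe)
    assert res.overlap == 4
    assert res.p == pytest.approx(76 / 15504)
    assert res.p == pytest.approx(brute_force_upper_tail(20, 5, 5, 4))


@pytest.mark.parametrize("seed", range(6))
def test_hypergeometric_p_matches_enumeration(seed):
    rng = np.random.default_rng(seed)
    n_u = int(rng.integers(8, 16))
    universe = [f"u{i}" for i in range(n_u)]
    term = set(rng.choice(universe, size=int(rng.integers(2, n_u // 2)), replace=False))
    query = list(rng.choice(universe, size=int(rng.integers(2, n_u // 2)), replace=False))
    (res,) = geneset_overrepresentation(query, {"T": term}, universe)
    expect = brute_force_upper_tail(n_u, len(term), len(query), res.overlap)
    assert res.p == pytest.approx(expect)


def test_zero_overlap_reports_p_one():
    universe = [f"u{i}" for i in range(10)]
    (res,) = geneset_overrepresentation(universe[:3], {"T": set(universe[5:])}, universe)
    assert res.overlap == 0 and res.p == pytest.approx(1.0)


def test_query_equal_universe_saturates():
    universe = [f"u{i}" for i in range(10)]
    ann = {"T1": set(universe[:4]), "T2": set(universe[2:9])}
    results = geneset_overrepresentation(universe, ann, universe)
    assert all(r.overlap == r.term_size and r.p == pytest.approx(1.0) for r in results)


def test_bh_q_values_monotone_and_bounded():
    universe = [f"u{i}" for i in range(40)]
    rng = np.random.default_rng(4)
    ann = {f"T{i}": set(rng.choice(universe, size=8, replace=False)) for i in range(12)}
    query = list(rng.choice(universe, size=10, replace=False))
    results = geneset_overrepresentation(query, ann, universe)
    results.sort(key=lambda r: r.p)
    qs = [r.q for r in results]
    assert all(q1 <= q2 for q1, q2 in zip(qs[:-1], qs[1:]))
    assert all(r.q >= r.p for r in results)
    with pytest.raises(ValueError):
        geneset_overrepresentation(query, ann, [])
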