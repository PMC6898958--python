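"""Scaffold assignment, reference-assisted ordering and AGP layout."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from breakscape.core import Chromosome, Karyotype, revcomp
from breakscape.scaffolding import (
    assign_by_coverage,
    emit_layout,
    order_by_reference,
    resolve_with_reference,
)
from breakscape.simkaryo import (
    emit_anchors,
    shred_karyotype,
    simulate_ancestor,
    simulate_flow_sort_coverage,
)
from breakscape.synteny import HSB, chain_anchors


def test_dominant_library_signal_assigns_scaffold():
    # library medians reflect the off-target background, as they do when
    # each library holds a small fraction of the scaffolds
    m = pd.DataFrame({"lib1": [2.0, 1.0, 1.1, 0.9, 1.0],
                      "lib2": [1.5, 1.2, 0.8, 1.0, 1.1],
                      "lib3": [100.0, 1.1, 0.9, 1.2, 1.0]},
                     index=[f"s{i}" for i in range(1, 6)])
    assigned, ambiguous = assign_by_coverage(m, min_ratio=3)
    assert assigned["s1"] == "lib3"


def test_close_depths_are_ambiguous():
    m = pd.DataFrame({"lib1": [50.0], "lib2": [45.0]}, index=["s1"])
    assigned, ambiguous = assign_by_coverage(m, min_ratio=3)
    assert ambiguous == {"s1"} and not assigned


def test_all_zero_row_is_ambiguous_and_bad_inputs_rejected():
    m = pd.DataFrame({"lib1": [0.0, 5.0], "lib2": [0.0, 1.0]}, index=["s0", "s1"])
    _, ambiguous = assign_by_coverage(m, min_ratio=2)
    assert "s0" in ambiguous
    with pytest.raises(ValueError):
        assign_by_coverage(m, min_ratio=1.0)
    with pytest.raises(ValueError):
        assign_by_coverage(pd.DataFrame(), min_ratio=3)


def test_assignment_invariant_to_column_scaling():
    rng = np.random.default_rng(0)
    m = pd.DataFrame(rng.uniform(0.1, 1.0, size=(20, 4)),
                     index=[f"s{i}" for i in range(20)],
                     columns=[f"lib{j}" for j in range(4)])
    for i in range(20):
        m.iloc[i, i % 4] = rng.uniform(50, 200)
    a1, _ = assign_by_coverage(m, min_ratio=3)
    scaled = m.copy()
    scaled["lib2"] *= 7.5
    a2, _ = assign_by_coverage(scaled, min_ratio=3)
    assert a1 == a2


def _hsb(i, scaf, s, e, ref, sb, eb, orient="+"):
    return HSB(f"h{i}", scaf, s, e, ref, sb, eb, orient, ["a"] * 3, float(e - s))


def test_majority_reference_span_resolves_mixed_library():
    hsbs = [_hsb(1, "s1", 0, 95_000, "refC", 0, 95_000),
            _hsb(2, "s1", 95_000, 100_000, "refD", 0, 5_000)]
    resolved, unresolved = resolve_with_reference(
        ["s1"], hsbs, {"refC": {"chr10"}, "refD": {"chr11"}},
        candidates={"s1": {"chr10", "chr11"}})
    assert resolved == {"s1": "chr10"}


def test_even_split_stays_unresolved():
    hsbs = [_hsb(1, "s1", 0, 50_000, "refC", 0, 50_000),
            _hsb(2, "s1", 50_000, 100_000, "refD", 0, 50_000)]
    resolved, unresolved = resolve_with_reference(
        ["s1"], hsbs, {"refC": {"chr10"}, "refD": {"chr11"}})
    assert unresolved == {"s1"}
    _, unres2 = resolve_with_reference(["s_nohsb"], hsbs, {"refC": {"chr10"}})
    assert unres2 == {"s_nohsb"}


def test_ordering_by_median_reference_position_and_orientation_majority():
    mb = 1_000_000
    hsbs = [
        _hsb(1, "s1", 0, mb, "ref", 30 * mb, 31 * mb),
        _hsb(2, "s2", 0, mb, "ref", 10 * mb, 11 * mb),
        _hsb(3, "s3", 0, mb, "ref", 50 * mb, 51 * mb),
        # s3: 80% of aligned span on '-'
        _hsb(4, "s3", mb, 5 * mb, "ref", 51 * mb, 55 * mb, orient="-"),
    ]
    placements = order_by_reference({"s1": "chr1", "s2": "chr1", "s3": "chr1"}, hsbs)
    assert [p.scaffold for p in sorted(placements, key=lambda p: p.rank)] == ["s2", "s1", "s3"]
    s3 = next(p for p in placements if p.scaffold == "s3")
    assert s3.orientation == "-"
    s1 = next(p for p in placements if p.scaffold == "s1")
    assert s1.orientation == "+"


def test_layout_arithmetic_and_reverse_complement():
    mb = 1_000_000
    rng = np.random.default_rng(1)
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=mb)) for i in (1, 2)}
    scaffolds = Karyotype("x", [Chromosome(n, mb, s) for n, s in seqs.items()])
    from breakscape.scaffolding import ScaffoldPlacement
    placements = [ScaffoldPlacement("s1", "chr1", 1, "+", "both", 10.0),
                  ScaffoldPlacement("s2", "chr1", 2, "-", "both", 10.0)]
    agp, kt = emit_layout(placements, scaffolds, gap_size=100)
    (chrom,) = kt.chromosomes
    assert chrom.length == 2 * mb + 100
    assert chrom.sequence[:mb] == seqs["s1"]
    assert chrom.sequence[mb:mb + 100] == "N" * 100
    assert chrom.sequence[mb + 100:] == revcomp(seqs["s2"])
    w_rows = agp[agp.component_type == "W"]
    assert list(w_rows["c9"]) == ["+", "-"]
    with pytest.raises(ValueError):
        emit_layout(placements + [placements[0]], scaffolds)


def test_agp_round_trip_is_identity(tmp_path):
    from breakscape import io
    from breakscape.scaffolding import ScaffoldPlacement
    scaffolds = Karyotype("x", [Chromosome("s1", 1000, "A" * 1000),
                                Chromosome("s2", 500, "C" * 500)])
    placements = [ScaffoldPlacement("s1", "chr1", 1, "+", "both", 1.0),
                  ScaffoldPlacement("s2", "chr1", 2, "-", "both", 1.0)]
    agp, _ = emit_layout(placements, scaffolds)
    path = tmp_path / "layout.agp"
    io.write_agp(agp, path)
    back = io.read_agp(path)
    pd.testing.assert_frame_equal(agp, back)
    recovered = io.layout_from_agp(back)
    agp2, _ = emit_layout(recovered, scaffolds)
    pd.testing.assert_frame_equal(agp, agp2)


def test_shred_and_recover_reconstructs_layout_exactly():
    genome = simulate_ancestor(8, mean_length=2_000_000, length_dispersion=0.05,
                               gene_rate=25, with_sequence=False, seed=31)
    scaffolds, truth = shred_karyotype(genome, n_pieces_per_chrom=5, seed=7)
    # coverage: chr2 and chr3 co-sorted into one mixed library
    cov = simulate_flow_sort_coverage(truth, genome.karyotype.names, seed=8,
                                      mixed_libraries=[("chr2", "chr3")])
    assert cov.shape[1] == 7  # chr3 folded into the chr2 library
    assigned, ambiguous = assign_by_coverage(cov, min_ratio=3)
    # reference synteny: scaffold-vs-ancestor anchors from the gene map
    rows = []
    anc_genes = {g.name: g for g in genome.track.genes()}
    for f in scaffolds.track.genes():
        g = anc_genes[f.name]
        rows.append((f.name, g.name, f.chrom, f.start, f.end, f.strand,
                     g.chrom, g.start, g.end, g.strand))
    import pandas as pd
    from breakscape.simkaryo import ORTHOLOG_COLUMNS
    omap = pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)
    aset = emit_anchors(omap, genome_a="scafs", genome_b="ancestor")
    hsbs = chain_anchors(aset, max_gap=1_500_000, min_anchors=1, min_span=0,
                         micro_tolerance=0)

    true_chrom = dict(zip(truth["scaffold"], truth["chrom"]))
    chrom_of = {}
    evidence = {}
    correspondence = {c: {c} for c in genome.karyotype.names}  # reference = ancestor
    for sc, lib in assigned.items():
        libchrom = lib.removeprefix("lib_")
        if libchrom == "chr2":  # mixed library: resolve by synteny
            resolved, _ = resolve_with_reference([sc], hsbs, correspondence,
                                                 candidates={sc: {"chr2", "chr3"}})
            chrom_of.update(resolved)
            evidence[sc] = "both"
        else:
            chrom_of[sc] = libchrom
            evidence[sc] = "coverage"
    # every unambiguous scaffold correctly assigned
    assert all(chrom_of[sc] == true_chrom[sc] for sc in chrom_of)
    assert not ambiguous

    # a gene-free scaffold has no synteny evidence and stays unplaced,
    # like the paper's unanchored scaffolds
    with_synteny = {b.chrom_a for b in hsbs}
    orderable = {sc: c for sc, c in chrom_of.items() if sc in with_synteny}
    placements = order_by_reference(orderable, hsbs, evidence=evidence)
    for chrom in genome.karyotype.names:
        placed = [p for p in sorted(placements, key=lambda p: p.rank)
                  if p.chromosome == chrom]
        truth_order = truth[truth["chrom"] == chrom].sort_values("order")
        got = [p.scaffold for p in placed]
        expect = [s for s in truth_order["scaffold"] if s in orderable]
        assert set(got) == set(expect)
        tau = kendalltau([expect.index(s) for s in got], range(len(got))).statistic
        assert tau == pytest.approx(1.0)
        assert got == expect
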