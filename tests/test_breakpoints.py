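"""EBR detection, fission counting, set union and the tiling invariant."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breakscape.breakpoints import (
    EBR,
    count_fission_events,
    detect_ebrs,
    ebr_summary,
    merge_ebr_sets,
)
from breakscape.simkaryo import apply_rearrangements, emit_anchors, sample_plan, simulate_ancestor
from breakscape.synteny import HSB, chain_anchors

MB = 1_000_000


def _hsb(i, chrom, s, e, partner, sb=0, eb=None, orient="+"):
    eb = eb if eb is not None else sb + (e - s)
    return HSB(f"h{i}", chrom, s, e, partner, sb, eb, orient, ["a"] * 3, float(e - s))


def test_gap_between_blocks_with_different_partners_is_interchromosomal_ebr():
    hsbs = [_hsb(1, "chr1", 0, 10 * MB, "dogX"), _hsb(2, "chr1", 12 * MB, 20 * MB, "dogY")]
    (e,) = detect_ebrs(hsbs, genome_id="panda")
    assert (e.chromosome, e.start, e.end, e.kind) == ("chr1", 10 * MB, 12 * MB,
                                                      "interchromosomal")
    assert (e.partner_left, e.partner_right) == ("dogX", "dogY")
    assert (e.flank_left, e.flank_right) == ("h1", "h2")


def test_single_block_and_terminal_gaps_yield_no_ebr():
    assert detect_ebrs([_hsb(1, "chr1", 2 * MB, 8 * MB, "dogX")]) == []


def test_same_partner_gap_is_intrachromosomal_and_filterable():
    hsbs = [_hsb(1, "chr1", 0, 5 * MB, "dogX"),
            _hsb(2, "chr1", 6 * MB, 10 * MB, "dogX", orient="-")]
    (e,) = detect_ebrs(hsbs)
    assert e.kind == "intrachromosomal"
    assert detect_ebrs(hsbs, fission_only=True) == []


def test_abutting_blocks_with_partner_change_emit_one_bp_junction_ebr():
    hsbs = [_hsb(1, "chr1", 0, 5 * MB, "dogX"), _hsb(2, "chr1", 5 * MB, 9 * MB, "dogY")]
    (e,) = detect_ebrs(hsbs)
    assert (e.start, e.end) == (5 * MB - 1, 5 * MB)
    assert e.kind == "interchromosomal"


def test_overlapping_blocks_rejected_with_pair_named():
    hsbs = [_hsb(1, "chr1", 0, 5 * MB, "dogX"), _hsb(2, "chr1", 4 * MB, 9 * MB, "dogY")]
    with pytest.raises(ValueError, match="h1.*h2"):
        detect_ebrs(hsbs)


def test_detection_on_genome_b_uses_flipped_frame():
    hsbs = [_hsb(1, "chr1", 0, 5 * MB, "dogX", sb=0),
            _hsb(2, "chr2", 0, 5 * MB, "dogX", sb=7 * MB)]
    (e,) = detect_ebrs(hsbs, target="B")
    assert e.chromosome == "dogX" and (e.start, e.end) == (5 * MB, 7 * MB)
    assert (e.partner_left, e.partner_right) == ("chr1", "chr2")


def test_fission_count_is_number_of_partner_transitions():
    hsbs = [_hsb(1, "chr1", 0, 2 * MB, "X"), _hsb(2, "chr1", 3 * MB, 5 * MB, "Y"),
            _hsb(3, "chr1", 6 * MB, 8 * MB, "X")]
    assert count_fission_events(hsbs) == 2
    same = [_hsb(1, "chr1", 0, 2 * MB, "X"), _hsb(2, "chr1", 3 * MB, 5 * MB, "X")]
    assert count_fission_events(same) == 0


def test_fission_count_equals_interchromosomal_ebr_count_with_nonzero_gaps():
    rng = np.random.default_rng(3)
    hsbs = []
    pos = 0
    for i in range(8):
        length = int(rng.integers(1, 4)) * MB
        hsbs.append(_hsb(i, "chr1", pos, pos + length, str(rng.choice(["X", "Y", "Z"]))))
        pos += length + int(rng.integers(1, 3)) * MB
    inter = [e for e in detect_ebrs(hsbs) if e.kind == "interchromosomal"]
    assert count_fission_events(hsbs) == len(inter)


# ---------------------------------------------------------------------------
# merging


def _ebr(chrom, s, e, genome="g", src="s1"):
    return EBR(genome, chrom, s, e, sources={src})


def test_overlapping_pair_merges_to_union_interval():
    merged, cross = merge_ebr_sets([_ebr("chr1", 10 * MB, 12 * MB)],
                                   [_ebr("chr1", 11 * MB, 13 * MB, src="s2")])
    assert len(merged) == 1 and cross == 1
    assert (merged[0].start, merged[0].end) == (10 * MB, 13 * MB)
    assert merged[0].sources == {"s1", "s2"}


def test_disjoint_sets_concatenate_without_cross_overlaps():
    s1 = [_ebr("chr1", i * MB, i * MB + 100_000) for i in (1, 3, 5)]
    s2 = [_ebr("chr2", i * MB, i * MB + 100_000, src="s2") for i in (1, 3)]
    merged, cross = merge_ebr_sets(s1, s2)
    assert len(merged) == 5 and cross == 0


def test_paper_style_union_counts():
    """58- and 15-member sets with 14 one-to-one overlaps union to 59."""
    rng = np.random.default_rng(0)
    set_a = [_ebr("chr1", i * MB, i * MB + 300_000) for i in range(58)]
    overlap_idx = rng.choice(58, size=14, replace=False)
    set_b = [_ebr("chr1", int(i) * MB + 200_000, int(i) * MB + 500_000, src="s2")
             for i in overlap_idx]
    set_b += [_ebr("chr1", (100 + i) * MB, (100 + i) * MB + 300_000, src="s2")
              for i in range(1)]
    assert len(set_a) == 58 and len(set_b) == 15
    merged, cross = merge_ebr_sets(set_a, set_b)
    assert len(merged) == 59 and cross == 14


def test_merge_is_commutative():
    s1 = [_ebr("chr1", 1 * MB, 2 * MB), _ebr("chr2", 0, MB)]
    s2 = [_ebr("chr1", int(1.5 * MB), 3 * MB, src="s2")]
    m12, c12 = merge_ebr_sets(s1, s2)
    m21, c21 = merge_ebr_sets(s2, s1)
    key = lambda e: (e.chromosome, e.start, e.end)
    assert sorted(map(key, m12)) == sorted(map(key, m21)) and c12 == c21


def test_self_merge_is_idempotent_with_zero_cross_pairs():
    s = [_ebr("chr1", 1 * MB, 2 * MB), _ebr("chr1", 5 * MB, 6 * MB)]
    merged, cross = merge_ebr_sets(s, s)
    assert [(e.start, e.end) for e in merged] == [(1 * MB, 2 * MB), (5 * MB, 6 * MB)]
    assert cross == 0


def test_transitive_overlaps_collapse_into_one_record():
    s1 = [_ebr("chr1", 0, 2 * MB), _ebr("chr1", 3 * MB, 5 * MB)]
    s2 = [_ebr("chr1", 1 * MB, 4 * MB, src="s2")]
    merged, cross = merge_ebr_sets(s1, s2)
    assert len(merged) == 1 and (merged[0].start, merged[0].end) == (0, 5 * MB)
    assert cross == 1


@st.composite
def _ebr_sets(draw):
    def one_set(src):
        n = draw(st.integers(0, 8))
        out = []
        for _ in range(n):
            chrom = draw(st.sampled_from(["chr1", "chr2"]))
            s = draw(st.integers(0, 50)) * 100_000
            length = draw(st.integers(1, 5)) * 100_000
            out.append(_ebr(chrom, s, s + length, src=src))
        return out
    return one_set("s1"), one_set("s2")


@settings(max_examples=60, deadline=None, derandomize=True)
@given(_ebr_sets())
def test_union_properties_on_generated_interval_sets(sets):
    """The union is commutative, never larger than the input, and disjoint."""
    s1, s2 = sets
    m12, c12 = merge_ebr_sets(s1, s2)
    m21, c21 = merge_ebr_sets(s2, s1)
    key = lambda e: (e.chromosome, e.start, e.end)
    assert sorted(map(key, m12)) == sorted(map(key, m21)) and c12 == c21
    assert len(m12) <= len(s1) + len(s2)
    by_chrom = {}
    for e in m12:
        by_chrom.setdefault(e.chromosome, []).append(e)
    for ebrs in by_chrom.values():
        ebrs.sort(key=lambda e: e.start)
        for a, b in zip(ebrs[:-1], ebrs[1:]):
            assert a.end <= b.start  # merged output is disjoint
    # merging the result with itself changes nothing
    m_again, c_again = merge_ebr_sets(m12, m12)
    assert sorted(map(key, m_again)) == sorted(map(key, m12)) and c_again == 0


def test_mixed_genome_ids_rejected():
    with pytest.raises(ValueError):
        merge_ebr_sets([_ebr("chr1", 0, MB, genome="g1")],
                       [_ebr("chr1", 0, MB, genome="g2")])


def test_summary_arithmetic():
    s = ebr_summary([_ebr("chr1", 0, 1 * MB), _ebr("chr1", 2 * MB, 4 * MB),
                     _ebr("chr2", 0, 3 * MB)])
    assert s["count"] == 3 and s["total_span"] == 6 * MB
    assert s["mean_length"] == 2 * MB and s["min_length"] == MB and s["max_length"] == 3 * MB
    assert s["per_chromosome"] == {"chr1": 2, "chr2": 1}
    assert s["mean_length"] * s["count"] == s["total_span"]
    assert ebr_summary([])["count"] == 0


# ---------------------------------------------------------------------------
# the tiling invariant on simulated layouts


def test_hsbs_ebrs_and_terminal_gaps_tile_each_chromosome(fissioned):
    anc, der = fissioned
    aset = emit_anchors(der.truth.ortholog_map, genome_a=anc.genome_id,
                        genome_b=der.genome_id)
    hsbs = chain_anchors(aset, max_gap=1 * MB, min_anchors=2, min_span=100_000)
    ebrs = detect_ebrs(hsbs, genome_id=anc.genome_id)
    for chrom in anc.karyotype.chromosomes:
        blocks = sorted([b for b in hsbs if b.chrom_a == chrom.name],
                        key=lambda b: b.start_a)
        gaps = [e for e in ebrs if e.chromosome == chrom.name]
        if not blocks:
            continue
        covered = sum(b.span_a for b in blocks) + sum(e.length for e in gaps)
        terminal = blocks[0].start_a + (chrom.length - blocks[-1].end_a)
        assert covered + terminal == chrom.length
        # no overlap, no hole between consecutive pieces
        pieces = sorted([(b.start_a, b.end_a) for b in blocks]
                        + [(e.start, e.end) for e in gaps])
        for (s1, e1), (s2, e2) in zip(pieces[:-1], pieces[1:]):
            assert e1 == s2


def test_planted_fissions_recovered_as_interchromosomal_ebrs(fissioned):
    anc, der = fissioned
    aset = emit_anchors(der.truth.ortholog_map, genome_a=anc.genome_id,
                        genome_b=der.genome_id)
    hsbs = chain_anchors(aset, max_gap=1 * MB, min_anchors=2, min_span=100_000)
    ebrs = detect_ebrs(hsbs, genome_id=anc.genome_id, fission_only=True)
    truth = der.truth.breakpoints(anc.genome_id, kind="fission")
    assert count_fission_events(hsbs) == len(truth)
    for bp in truth:
        containing = [e for e in ebrs
                      if e.chromosome == bp.chrom and e.start <= bp.start and bp.end <= e.end]
        assert len(containing) == 1
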