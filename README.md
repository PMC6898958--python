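# breakscape

Synteny blocks, evolutionary breakpoints, and what lives inside them.

When two chromosome-level genomes are compared, orthologous markers
("anchors") fall into long collinear runs — **homologous synteny blocks
(HSBs)** — separated by the places where chromosome rearrangements broke
the ancestral order: **evolutionary breakpoint regions (EBRs)**. A change
of partner chromosome between two adjacent blocks on the target genome
marks an interchromosomal event (a fission, seen from that genome); the
interval between the block ends is the breakpoint region. EBRs are of
interest in comparative genomics because they are repeatedly found to be
gene-dense, GC-rich and repeat-rich — classically enriched for LINE-L1
elements — and because the genes inside them cluster in particular
functional categories.

`breakscape` implements that analysis end to end for desk-scale data,
for people studying karyotype evolution who want a transparent,
testable pipeline rather than a black-box aligner:

- **simkaryo** — a karyotype simulator: ancestral genomes with gene and
  repeat tracks, rearranged by fission / fusion / inversion /
  translocation with exact breakpoint ground truth, plus noisy ortholog
  anchor emission (dropout, jitter, micro-inversion) and flow-sort
  coverage emulation.
- **anchors** — maximal exact matches (≥ 20 bp) and ortholog-pair
  anchors, with match-to-ortholog clustering.
- **synteny** — weighted collinear chaining into large-scale HSBs
  (score-maximal per chromosome pair and orientation, gap-bounded,
  micro-rearrangements absorbed up to a tolerance).
- **breakpoints** — EBR detection between adjacent blocks, fission-event
  counting, and per-genome union of EBR sets across comparisons.
- **features** — gene density / GC / repeat coverage of EBR windows
  versus the whole genome (Mann-Whitney U), repeat-family fold change
  with permutation p values, and hypergeometric gene-set
  overrepresentation with Benjamini-Hochberg FDR.
- **scaffolding** — scaffold-to-chromosome assignment from flow-sorted
  library depth, reference-assisted resolution and ordering, AGP v2.1 +
  FASTA output.
- **CLI / pipeline** — `breakscape run` drives simulate → anchors →
  chain → ebr → merge → features → enrich from one config + seed and
  writes a reproducible run report.

## The statistics at the core

For two adjacent blocks B₁, B₂ on target chromosome c with partner
chromosomes p₁, p₂, the EBR is the interval [end(B₁), start(B₂)), and it
is interchromosomal iff p₁ ≠ p₂. The fission count of a comparison is
Σ_c (number of maximal same-partner runs − 1). Feature contrasts use the
Mann-Whitney statistic U = Σᵢⱼ [xᵢ > yⱼ] + ½[xᵢ = yⱼ] over EBR windows x
versus all windows y, exact for small tie-free samples, tie-corrected
normal otherwise. Gene-set overrepresentation is the hypergeometric
upper tail P(X ≥ k) for overlap k between a term and the EBR gene list
within an explicit gene universe.

## Worked example

Simulate a six-chromosome ancestor, derive a genome by five fissions
and two inversions, and recover the events:

```python
from breakscape import (simulate_ancestor, sample_plan, apply_rearrangements,
                        emit_anchors, chain_anchors, detect_ebrs,
                        count_fission_events, ebr_summary)

ancestor = simulate_ancestor(6, mean_length=8_000_000, gene_rate=12, seed=4)
plan = sample_plan(ancestor, 0, counts={"fission": 5, "inversion": 2},
                   seed=4, min_fragment=1_500_000)
derived = apply_rearrangements(ancestor, plan, derived_id="derived")

anchors = emit_anchors(derived.truth.ortholog_map,
                       genome_a="ancestor", genome_b="derived")
hsbs = chain_anchors(anchors)          # max_gap 2 Mb, >=3 anchors, >=1 Mb span
ebrs = detect_ebrs(hsbs, genome_id="ancestor")

print(f"{len(anchors)} anchors -> {len(hsbs)} HSBs")
print(f"fission events: {count_fission_events(hsbs)}")
s = ebr_summary(ebrs)
print(f"EBRs: {s['count']} ({s['per_kind']}), mean length {s['mean_length']/1e3:.1f} kb")
for e in ebrs[:3]:
    print(f"  {e.chromosome}:{e.start}-{e.end}  {e.kind}  "
          f"{e.partner_left} | {e.partner_right}")
```

Output:

```
528 anchors -> 11 HSBs
fission events: 5
EBRs: 5 ({'interchromosomal': 5}), mean length 158.4 kb
  chr2:3815095-3998229  interchromosomal  chr2aa | chr2ab
  chr2:5761805-6016767  interchromosomal  chr2ab | chr2b
  chr3:4307804-4412474  interchromosomal  chr3a | chr3b
```

All five planted fissions are recovered as interchromosomal EBRs whose
intervals bracket the true cut sites (the two inversions here fall below
the 1 Mb "large-scale" block threshold and are absorbed or skipped —
exactly the behaviour the `micro_tolerance` and `min_span` parameters
control). The full three-genome analysis, including the per-genome EBR
unions and feature tests, runs with:

```bash
breakscape run --outdir run1 --seed 1
```

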