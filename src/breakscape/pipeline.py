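"""End-to-end driver: simulate -> anchors -> chain -> ebr -> features -> enrich.

A run is described by a single declarative config (YAML or dict). Three
genomes are simulated from one ancestor, all six ordered pairwise
comparisons are chained, EBR sets are merged per target genome, EBR
windows are profiled against the genome, and EBR genes are tested for
gene-set overrepresentation against a simulated annotation. All
randomness flows from one global seed through named per-stage substreams,
so a config + seed pair is fully reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from .breakpoints import detect_ebrs, count_fission_events, ebr_summary, merge_ebr_sets
from .features import (
    compare_ebr_features,
    geneset_overrepresentation,
    genes_in_regions,
    repeat_family_enrichment,
    stats_frame,
    window_feature_table,
)
from .simkaryo import apply_rearrangements, cross_ortholog_map, emit_anchors, sample_plan, simulate_ancestor
from .synteny import chain_anchors, hsb_table, trim_hsb_overlaps

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "config_hash", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "breakscape_run",
    "log_level": "INFO",
    "simulate": {
        "n_chromosomes": 6,
        "mean_length": 10_000_000,
        "length_dispersion": 0.15,
        "gene_rate": 8.0,
        "gc_target": 0.42,
        "repeat_mix": {"LINE-L1": 0.12, "SINE": 0.06, "LTR-ERV1": 0.04},
        "with_sequence": True,
        "n_hotspots": 0,
        "hotspot_width": 200_000,
        "hotspot_gene_boost": 1.0,
        "hotspot_repeat_boost": {},
        # per-genome rearrangement plans (drawn at run time)
        "genomes": [
            {"id": "gpanda", "n_events": 3},
            {"id": "gdog", "n_events": 10},
            {"id": "gcat", "n_events": 2},
        ],
        "rates": {"fission": 0.7, "inversion": 0.3},
        "edge_margin": 0.1,
        "use_hotspots": False,
        "breakpoint_bias": 1.0,
        "bias_family": None,
    },
    "anchors": {"dropout": 0.0, "jitter_sd": 0.0, "micro_inversion_rate": 0.0},
    "chain": {"max_gap": 2_000_000, "min_anchors": 3, "min_span": 1_000_000,
              "micro_tolerance": 200_000},
    "ebr": {"fission_only": False},
    "features": {"window": 100_000, "y_mode": "all", "repeat_permutations": 200},
    "enrich": {"gmt": None, "n_random_terms": 20, "term_size": 30, "alpha": 0.05},
}


def _merge_config(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and key not in ("repeat_mix", "hotspot_repeat_boost", "rates"):
            if not isinstance(val, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge_config(defaults[key], val, path + key + ".")
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(source: dict | str | Path | None = None, **overrides) -> dict:
    """Build a validated run config from defaults, a YAML file and overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if source is not None:
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                source = yaml.safe_load(fh) or {}
        cfg = _merge_config(cfg, source)
    if overrides:
        cfg = _merge_config(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _substream(seed: int, label: str) -> int:
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: dict | None = None, **overrides) -> dict:
    """Run the full simulated comparison; returns the run report dict.

    Outputs are written under ``config['outdir']``; per-stage outputs
    carry the tool version and config hash in their headers, and stages
    already on disk with a matching config hash are reused.
    """
    cfg = load_config(config, **overrides)
    logging.basicConfig(level=getattr(logging, cfg["log_level"].upper(), logging.INFO))
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    header = f"breakscape v{__version__} config={chash}"
    seed = int(cfg["seed"])

    report_path = outdir / "run_report.json"
    if report_path.exists():
        try:
            old = json.loads(report_path.read_text())
            if old.get("config_hash") == chash:
                log.info("config unchanged (%s); reusing cached run", chash)
                return old
        except (json.JSONDecodeError, OSError):
            pass

    sim = cfg["simulate"]
    ancestor = simulate_ancestor(
        sim["n_chromosomes"], sim["mean_length"], sim["length_dispersion"],
        sim["gene_rate"], dict(sim["repeat_mix"]), sim["gc_target"],
        seed=_substream(seed, "ancestor"), genome_id="ancestor",
        with_sequence=sim["with_sequence"], n_hotspots=sim["n_hotspots"],
        hotspot_width=sim["hotspot_width"], hotspot_gene_boost=sim["hotspot_gene_boost"],
        hotspot_repeat_boost=dict(sim["hotspot_repeat_boost"]),
    )

    genomes = {}
    for spec_g in sim["genomes"]:
        gid = spec_g["id"]
        plan = sample_plan(
            ancestor, spec_g["n_events"], dict(sim["rates"]),
            seed=_substream(seed, f"plan:{gid}"),
            breakpoint_bias=sim["breakpoint_bias"], bias_family=sim["bias_family"],
            use_hotspots=sim["use_hotspots"], edge_margin=sim["edge_margin"],
        )
        derived = apply_rearrangements(ancestor, plan, derived_id=gid)
        genomes[gid] = derived
        if sim["with_sequence"]:
            io.write_fasta(derived.karyotype, outdir / f"{gid}.fasta")
        io.write_intervals(derived.track, outdir / f"{gid}.features.bed")
        derived.truth.to_json(outdir / f"{gid}.truth.json")
    gids = list(genomes)

    anc_cfg = cfg["anchors"]
    chain_cfg = cfg["chain"]
    comparisons = {}
    for target in gids:
        for other in gids:
            if target == other:
                continue
            label = f"{target}_vs_{other}"
            omap = cross_ortholog_map(genomes[target].truth.ortholog_map,
                                      genomes[other].truth.ortholog_map)
            aset = emit_anchors(
                omap, anc_cfg["dropout"], anc_cfg["jitter_sd"],
                anc_cfg["micro_inversion_rate"],
                seed=_substream(seed, f"anchors:{label}"),
                lengths_a=genomes[target].karyotype.lengths,
                lengths_b=genomes[other].karyotype.lengths,
                genome_a=target, genome_b=other,
            )
            io.write_anchors(aset, outdir / f"anchors.{label}.tsv", header=header)
            hsbs = chain_anchors(aset, chain_cfg["max_gap"], chain_cfg["min_anchors"],
                                 chain_cfg["min_span"], chain_cfg["micro_tolerance"])
            io.write_hsbs(hsbs, outdir / f"hsbs.{label}.tsv", header=header)
            ebrs = detect_ebrs(hsbs, target="A", fission_only=cfg["ebr"]["fission_only"],
                               genome_id=target, source=label)
            io.write_ebrs(ebrs, outdir / f"ebrs.{label}.bed", header=header)
            comparisons[label] = {
                "target": target,
                "other": other,
                "n_anchors": len(aset),
                "hsb": hsb_table(hsbs, genomes[target].karyotype.lengths,
                                 genomes[other].karyotype.lengths),
                "n_ebrs": len(ebrs),
                "n_fission_events": count_fission_events(hsbs),
                "_ebrs": ebrs,
            }

    feat_cfg = cfg["features"]
    enr_cfg = cfg["enrich"]
    per_genome = {}
    rng_terms = np.random.default_rng(_substream(seed, "annotation"))
    universe = sorted({g.name for sg in genomes.values() for g in sg.track.genes()})
    if enr_cfg["gmt"]:
        annotation = io.read_gmt(enr_cfg["gmt"])
    else:
        annotation = {
            f"TERM{i:03d}": set(rng_terms.choice(universe,
                                                 size=min(enr_cfg["term_size"], len(universe)),
                                                 replace=False))
            for i in range(enr_cfg["n_random_terms"])
        }
        io.write_gmt(annotation, outdir / "annotation.synthetic.gmt")

    for gid in gids:
        own = [c for c in comparisons.values() if c["target"] == gid]
        merged, cross = list(own[0]["_ebrs"]), 0
        for other in own[1:]:
            merged, c = merge_ebr_sets(merged, other["_ebrs"])
            cross += c
        io.write_ebrs(merged, outdir / f"ebrs.{gid}.merged.bed", header=header)
        summary = ebr_summary(merged)
        genome = genomes[gid]
        table = window_feature_table(genome.karyotype, genome.track, feat_cfg["window"])
        results = compare_ebr_features(genome.karyotype, genome.track, merged,
                                       feat_cfg["window"], y_mode=feat_cfg["y_mode"],
                                       table=table)
        frame = stats_frame(results)
        with open(outdir / f"features.{gid}.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            frame.to_csv(fh, sep="\t", index=False)
        fam = None
        if merged and genome.track.repeats():
            fam = repeat_family_enrichment(
                genome.track, merged, genome.karyotype,
                n_permutations=feat_cfg["repeat_permutations"],
                seed=_substream(seed, f"perm:{gid}"))
            with open(outdir / f"repeat_enrichment.{gid}.tsv", "w") as fh:
                fh.write(f"# {header}\n")
                fam.to_csv(fh, sep="\t", index=False)
        ebr_genes = genes_in_regions(genome.track, merged)
        enr = geneset_overrepresentation(ebr_genes, annotation, universe)
        with open(outdir / f"enrichment.{gid}.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            fh.write("term\tterm_size\toverlap\tp\tq\n")
            for r in sorted(enr, key=lambda r: r.p):
                fh.write(f"{r.term}\t{r.term_size}\t{r.overlap}\t{r.p:.6g}\t{r.q:.6g}\n")
        genome_stats = {f"{r.feature}": {"p": r.p, "direction": r.direction}
                        for r in results if r.label == "genome"}
        per_genome[gid] = {
            "n_chromosomes": len(genome.karyotype),
            "genome_length": genome.karyotype.total_length,
            "merged_ebrs": summary,
            "cross_set_overlaps": cross,
            "n_ebr_genes": len(ebr_genes),
            "feature_tests": genome_stats,
            "top_repeat_family": (fam.iloc[0]["family"] if fam is not None and len(fam) else None),
            "n_significant_terms": sum(1 for r in enr if r.q < enr_cfg["alpha"]),
        }

    for c in comparisons.values():
        del c["_ebrs"]
    report = {
        "tool": "breakscape",
        "version": __version__,
        "config_hash": chash,
        "config": cfg,
        "comparisons": comparisons,
        "genomes": per_genome,
    }
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True, default=str))
    return report
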