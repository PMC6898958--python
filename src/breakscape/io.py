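"""Format I/O.

Internal coordinates are 0-based half-open everywhere; BED shares that
convention, while GFF3 and AGP are converted from/to 1-based closed at
this boundary. FASTA goes through Biopython.
"""

from __future__ import annotations

import re

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .breakpoints import EBR
from .core import Anchor, AnchorSet, Chromosome, Feature, FeatureTrack, Karyotype
from .scaffolding import ScaffoldPlacement
from .simkaryo import ORTHOLOG_COLUMNS
from .synteny import HSB

_IUPAC = set("ACGTNRYSWKMBDHV")

ANCHOR_COLUMNS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
                  "orientation", "weight", "source", "id"]
HSB_COLUMNS = ["id", "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
               "orientation", "n_anchors", "score"]
EBR_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
               "kind", "partner_left", "partner_right", "sources"]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, genome_id: str | None = None) -> Karyotype:
    """Read a FASTA file into a karyotype (sequences uppercased)."""
    chroms = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters {sorted(bad)} in record {rec.id!r}")
        chroms.append(Chromosome(rec.id, len(seq), seq))
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    if genome_id is None:
        genome_id = str(path)
    return Karyotype(genome_id, chroms)


def write_fasta(karyotype: Karyotype, path, width: int = 80) -> None:
    records = []
    for c in karyotype.chromosomes:
        if c.sequence is None:
            raise ValueError(f"chromosome {c.name!r} has no sequence to write")
        records.append(SeqRecord(Seq(c.sequence), id=c.name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# intervals (BED / GFF3)

_FAMILY_RE = re.compile(r"^family:(.+)$")


def read_intervals(path, dialect: str = "BED", *, genome_id: str = "",
                   category: str | None = None) -> FeatureTrack:
    """Read BED6 (0-based half-open) or GFF3 (1-based closed) into a track.

    For BED, a name of the form ``family:LINE-L1`` marks a repeat record of
    that family; other records take ``category`` (default "gene"). For
    GFF3, the type column is the category and a ``family=`` attribute is
    honoured.
    """
    if dialect not in ("BED", "GFF3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "BED":
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"feat{lineno}"
                    strand = parts[5] if len(parts) > 5 else "+"
                    m = _FAMILY_RE.match(name)
                    if m:
                        cat, family = "repeat", m.group(1)
                    else:
                        cat, family = (category or "gene"), None
                else:
                    chrom, cat = parts[0], parts[2]
                    start, end = int(parts[3]) - 1, int(parts[4])
                    strand = parts[6]
                    attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
                    name = attrs.get("ID", f"feat{lineno}")
                    family = attrs.get("family")
                if start >= end:
                    raise ValueError("start >= end after conversion")
                records.append(Feature(chrom, start, end, name, cat, strand, family))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed {dialect} line: {exc}") from exc
    return FeatureTrack(genome_id or str(path), records)


def write_intervals(track: FeatureTrack, path, dialect: str = "BED") -> None:
    with open(path, "w") as fh:
        if dialect == "BED":
            for f in track.records:
                name = f"family:{f.family}" if f.category == "repeat" and f.family else f.name
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")
        elif dialect == "GFF3":
            fh.write("##gff-version 3\n")
            for f in track.records:
                attrs = f"ID={f.name}"
                if f.family:
                    attrs += f";family={f.family}"
                fh.write(f"{f.chrom}\tbreakscape\t{f.category}\t{f.start + 1}\t{f.end}"
                         f"\t.\t{f.strand}\t.\t{attrs}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# tabular formats


def read_orthologs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ORTHOLOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ortholog TSV {path} lacks columns {sorted(missing)}")
    return df


def write_orthologs(df: pd.DataFrame, path) -> None:
    df[ORTHOLOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_anchors(path, genome_a: str = "A", genome_b: str = "B") -> AnchorSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    anchors = [
        Anchor(r.chrom_a, int(r.start_a), int(r.end_a),
               r.chrom_b, int(r.start_b), int(r.end_b),
               r.orientation, float(r.weight), r.source, str(r.id))
        for r in df.itertuples()
    ]
    return AnchorSet(genome_a, genome_b, anchors)


def write_anchors(anchor_set: AnchorSet, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("\t".join(ANCHOR_COLUMNS) + "\n")
        for a in anchor_set.anchors:
            fh.write(f"{a.chrom_a}\t{a.start_a}\t{a.end_a}\t{a.chrom_b}\t{a.start_b}"
                     f"\t{a.end_b}\t{a.orientation}\t{a.weight}\t{a.source}\t{a.id}\n")


def read_hsbs(path) -> list[HSB]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        HSB(str(r.id), r.chrom_a, int(r.start_a), int(r.end_a),
            r.chrom_b, int(r.start_b), int(r.end_b), r.orientation,
            anchor_ids=[f"_{i}" for i in range(int(r.n_anchors))], score=float(r.score))
        for r in df.itertuples()
    ]


def write_hsbs(hsbs: list[HSB], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("\t".join(HSB_COLUMNS) + "\n")
        for b in hsbs:
            fh.write(f"{b.id}\t{b.chrom_a}\t{b.start_a}\t{b.end_a}\t{b.chrom_b}"
                     f"\t{b.start_b}\t{b.end_b}\t{b.orientation}\t{b.n_anchors}\t{b.score}\n")


def write_ebrs(ebrs: list[EBR], path, header: str | None = None) -> None:
    """EBRs as BED6+4 (kind, partner_left, partner_right, sources)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for i, e in enumerate(ebrs, start=1):
            srcs = ",".join(sorted(e.sources)) or "."
            fh.write(f"{e.chromosome}\t{e.start}\t{e.end}\tebr{i:04d}\t0\t.\t"
                     f"{e.kind}\t{e.partner_left or '.'}\t{e.partner_right or '.'}\t{srcs}\n")


def read_ebrs(path, genome_id: str = "") -> list[EBR]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            sources = set() if p[9] == "." else set(p[9].split(","))
            out.append(EBR(genome_id, p[0], int(p[1]), int(p[2]),
                           partner_left="" if p[7] == "." else p[7],
                           partner_right="" if p[8] == "." else p[8],
                           kind=p[6], sources=sources))
    return out


def read_coverage_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ValueError(f"negative depths in coverage matrix {path}")
    return df


def read_correspondence(path) -> dict[str, set[str]]:
    """TSV with columns reference_chrom, target_chrom -> mapping dict."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r[0]), set()).add(str(r[1]))
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: term <tab> description <tab> gene ids."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            out[p[0]] = set(p[2:])
    return out


def write_gmt(annotation: dict[str, set[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation):
            desc = (descriptions or {}).get(term, term)
            fh.write("\t".join([term, desc, *sorted(annotation[term])]) + "\n")


# ---------------------------------------------------------------------------
# AGP v2.1


def write_agp(agp: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        if header:
            fh.write(f"# {header}\n")
        for r in agp.itertuples(index=False):
            fh.write("\t".join(str(v) for v in r) + "\n")


def read_agp(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) != 9:
                raise ValueError(f"AGP line with {len(p)} columns in {path}")
            if p[4] == "W":
                rows.append((p[0], int(p[1]), int(p[2]), int(p[3]), "W",
                             p[5], int(p[6]), int(p[7]), p[8]))
            else:
                rows.append((p[0], int(p[1]), int(p[2]), int(p[3]), p[4],
                             int(p[5]), p[6], p[7], p[8]))
    return pd.DataFrame(rows, columns=["object", "object_beg", "object_end",
                                       "part_number", "component_type",
                                       "c6", "c7", "c8", "c9"])


def layout_from_agp(agp: pd.DataFrame) -> list[ScaffoldPlacement]:
    """Recover scaffold placements from an AGP table."""
    placements = []
    for chrom, group in agp.groupby("object", sort=True):
        rank = 0
        for r in group.sort_values("part_number").itertuples(index=False):
            if r.component_type != "W":
                continue
            rank += 1
            placements.append(ScaffoldPlacement(str(r.c6), str(chrom), rank,
                                                r.c9, "agp", float("nan")))
    return placements
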