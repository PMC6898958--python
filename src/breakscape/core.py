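"""Shared domain containers.

All coordinates are 0-based, half-open throughout the package; converters
to/from 1-based closed conventions (GFF3, AGP) live at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Chromosome",
    "Karyotype",
    "Feature",
    "FeatureTrack",
    "Anchor",
    "AnchorSet",
]

_COMPLEMENT = str.maketrans("ACGTNacgtnRYSWKMBDHVryswkmbdhv",
                            "TGCANtgcanYRSWMKVHDByrswmkvhdb")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Chromosome:
    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"chromosome {self.name!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"chromosome {self.name!r}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )


@dataclass
class Karyotype:
    """A genome as an ordered set of named chromosomes."""

    genome_id: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate chromosome names in {self.genome_id!r}")

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def chrom(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome {name!r} in genome {self.genome_id!r}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)


@dataclass
class Feature:
    """One annotated interval (gene or repeat element)."""

    chrom: str
    start: int
    end: int
    name: str
    category: str  # "gene" | "repeat"
    strand: str = "+"
    family: str | None = None  # repeat family label, e.g. "LINE-L1"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name!r}: invalid interval [{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FeatureTrack:
    """Gene and repeat annotations for one genome."""

    genome_id: str
    records: list[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> list[Feature]:
        return [f for f in self.records if f.category == "gene"]

    def repeats(self, family: str | None = None) -> list[Feature]:
        reps = [f for f in self.records if f.category == "repeat"]
        if family is not None:
            reps = [f for f in reps if f.family == family]
        return reps

    def by_chrom(self, chrom: str) -> list[Feature]:
        return [f for f in self.records if f.chrom == chrom]

    def validate(self, karyotype: Karyotype) -> None:
        lengths = karyotype.lengths
        for f in self.records:
            if f.chrom not in lengths:
                raise ValueError(f"feature {f.name!r}: unknown chromosome {f.chrom!r}")
            if f.end > lengths[f.chrom]:
                raise ValueError(
                    f"feature {f.name!r}: end {f.end} beyond chromosome "
                    f"{f.chrom!r} length {lengths[f.chrom]}"
                )


@dataclass
class Anchor:
    """An orthologous correspondence between intervals on two genomes.

    ``orientation`` is '+' when the two members lie on the same strand and
    '-' otherwise; ``weight`` scores the anchor for chaining (defaults to
    its span in bases).
    """

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str = "+"
    weight: float = 0.0
    source: str = "ortholog"  # "ortholog" | "match" | "merged"
    id: str = ""

    def __post_init__(self) -> None:
        if self.start_a >= self.end_a or self.start_b >= self.end_b:
            raise ValueError(f"anchor {self.id!r}: inverted or empty interval")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"anchor {self.id!r}: bad orientation {self.orientation!r}")
        if self.weight == 0.0:
            self.weight = float(self.end_a - self.start_a)

    @property
    def span_a(self) -> int:
        return self.end_a - self.start_a

    @property
    def span_b(self) -> int:
        return self.end_b - self.start_b

    def flipped(self) -> "Anchor":
        """The same anchor viewed from genome B."""
        return replace(
            self,
            chrom_a=self.chrom_b, start_a=self.start_b, end_a=self.end_b,
            chrom_b=self.chrom_a, start_b=self.start_a, end_b=self.end_a,
        )


@dataclass
class AnchorSet:
    """Anchors for one ordered pairwise comparison (A = target frame)."""

    genome_a: str
    genome_b: str
    anchors: list[Anchor] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.anchors)

    def flipped(self) -> "AnchorSet":
        return AnchorSet(
            genome_a=self.genome_b,
            genome_b=self.genome_a,
            anchors=[a.flipped() for a in self.anchors],
        )
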