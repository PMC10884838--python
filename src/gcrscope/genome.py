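"""Genome and feature containers plus FASTA/BED round-tripping.

A :class:`Genome` is an ordered mapping of chromosome name to an uppercase
A/C/G/T sequence, together with a flat list of :class:`Feature` annotations
(genes, telomeric tracts, rDNA-like arrays, identical regions shared by
homologous gene pairs, and essential genes). All internal coordinates are
0-based, half-open; SAM output and human-facing reports are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

ALPHABET = frozenset("ACGT")

FEATURE_KINDS = frozenset(
    {"gene", "telomere_tract", "rdna_array", "identical_region", "essential_gene"}
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """An annotated interval on one chromosome.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``+`` or ``-``;
    ``kind`` is one of :data:`FEATURE_KINDS`.
    """

    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"feature {self.name}: need 0 <= start < end, got [{self.start},{self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.name}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.name}: unknown kind {self.kind!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass
class Genome:
    """Named chromosome sequences plus feature annotations."""

    chroms: dict[str, str]
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.chroms:
            raise ValueError("genome has no chromosomes")
        for name, seq in self.chroms.items():
            if not seq:
                raise ValueError(f"chromosome {name} is empty")
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"chromosome {name} has non-ACGT characters: {sorted(bad)}")
        for f in self.features:
            if f.chrom not in self.chroms:
                raise ValueError(f"feature {f.name} on unknown chromosome {f.chrom}")
            if f.end > len(self.chroms[f.chrom]):
                raise ValueError(f"feature {f.name} exceeds bounds of {f.chrom}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def get_features(self, kind: str | None = None, chrom: str | None = None,
                     name: str | None = None) -> list[Feature]:
        out = self.features
        if kind is not None:
            out = [f for f in out if f.kind == kind]
        if chrom is not None:
            out = [f for f in out if f.chrom == chrom]
        if name is not None:
            out = [f for f in out if f.name == name]
        return list(out)

    def feature(self, name: str) -> Feature:
        hits = self.get_features(name=name)
        if len(hits) != 1:
            raise KeyError(f"expected exactly one feature named {name!r}, found {len(hits)}")
        return hits[0]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.chroms[chrom][start:end]

    def fetch_feature(self, name: str, oriented: bool = False) -> str:
        """Sequence of a named feature; ``oriented=True`` returns the
        5'->3' sequence on the feature's own strand."""
        f = self.feature(name)
        seq = self.fetch(f.chrom, f.start, f.end)
        return revcomp(seq) if (oriented and f.strand == "-") else seq

    # ---------------------------------------------------------------- I/O

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chroms.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def features_to_bed(self, path) -> None:
        """BED6 with the feature kind carried in column 7."""
        with open(path, "w") as fh:
            for f in self.features:
                fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\t{f.kind}\n")

    @classmethod
    def from_fasta(cls, fasta_path, bed_path=None) -> "Genome":
        chroms: dict[str, str] = {}
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            chroms[rec.id] = str(rec.seq).upper()
        features = read_feature_bed(bed_path) if bed_path else []
        return cls(chroms=chroms, features=features)

    def with_features(self, features: list[Feature]) -> "Genome":
        return Genome(chroms=dict(self.chroms), features=list(features))


def read_feature_bed(path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
            kind = parts[6] if len(parts) > 6 else "gene"
            feats.append(Feature(chrom, start, end, strand, kind, name))
    return feats
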