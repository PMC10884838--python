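"""Synthetic genomes, rearrangements and paired-end reads with exact truth.

The toy genome carries the structural motifs that terminal-deletion calling
must handle: degenerate telomeric tracts (tandem GGTTAC cores with occasional
1-2 nt spacers) at every chromosome end, tandem rDNA-like arrays at both ends
of the last chromosome, a same-orientation homologous gene pair on two
chromosomes sharing a perfectly identical internal region, an
inverted-orientation homologous pair flanking a middle gene, and an essential
gene centromeric of everything a viable terminal deletion may remove.

Rearrangements are applied as segment edits, so every mutant chromosome keeps
an exact map back to reference coordinates. The read simulator uses that map
to emit truth alignments against the *reference*: junction-spanning reads are
assigned to the side with the longer reference-contiguous match (extending
through sequence that is locally identical between mutant and reference, as a
real aligner would), ties going to the lower coordinate; the non-contiguous
remainder is soft-clipped. Coordinates are 0-based half-open internally and
1-based in SAM/reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import Genome, Feature, revcomp

TELOMERE_CORE = "GGTTAC"

EVENT_TYPES = frozenset(
    {"homology_translocation", "chromosome_fusion", "telomere_addition",
     "inversion_plus_deletion"}
)

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# --------------------------------------------------------------------------
# configs and truth records
# --------------------------------------------------------------------------

@dataclass
class ToyGenomeConfig:
    """Layout of the synthetic three-chromosome genome.

    Sizes default to a ~500 kb genome; positions of the engineered motifs are
    fixed offsets validated against the chromosome sizes, so smaller genomes
    for fast tests remain self-consistent or are rejected.
    """

    seed: int = 0
    chrom_names: tuple[str, ...] = ("chrI", "chrII", "chrIII")
    chrom_sizes: tuple[int, ...] = (150_000, 250_000, 100_000)
    telomere_len: int = 300
    spacer_prob: float = 0.3
    rdna_unit_len: int = 1500
    rdna_copies: int = 3
    gene_len: int = 1500
    p1_identical_len: int = 240   # shared block of the same-orientation pair
    p2_identical_len: int = 12    # shared window of the inverted pair
    p1_gene_a_start: int = 20_000   # on chrI
    p1_gene_b_start: int = 30_000   # on chrII
    p2_gene_a_start: int = 45_000   # telomere-proximal inverted homolog, chrII
    mid_gene_gap: int = 1_600       # gap between inverted homolog and middle gene
    cen_gene_gap: int = 3_200       # gap between middle gene and the other homolog
    essential_gap: int = 40_000     # distance from the inverted pair to the essential gene
    homolog_divergence: float = 0.12

    def validate(self) -> None:
        if len(self.chrom_names) != 3 or len(self.chrom_sizes) != 3:
            raise ValueError("toy genome needs exactly three chromosomes")
        if any(s <= 2 * self.telomere_len for s in self.chrom_sizes):
            raise ValueError("chromosomes must exceed two telomere tracts")
        if self.p1_identical_len > self.gene_len - 4:
            raise ValueError("identical region does not fit inside the gene")
        if self.p2_identical_len > self.gene_len - 4:
            raise ValueError("identical window does not fit inside the gene")
        if not (0 <= self.spacer_prob <= 1):
            raise ValueError("spacer_prob must be in [0,1]")
        s1, s2, s3 = self.chrom_sizes
        rdna_len = self.rdna_unit_len * self.rdna_copies
        if 2 * (self.telomere_len + rdna_len) >= s3:
            raise ValueError("rDNA arrays overlap on the last chromosome")
        if self.p1_gene_a_start < self.telomere_len or self.p1_gene_a_start + self.gene_len > s1 - self.telomere_len:
            raise ValueError("chrI homolog out of bounds")
        aat_b_start = self._aat_b_start
        ess_end = aat_b_start + self.gene_len + self.essential_gap + 1000
        if ess_end > s2 - self.telomere_len:
            raise ValueError("chrII motifs exceed chromosome bounds")
        if self.p1_gene_b_start + self.gene_len >= self.p2_gene_a_start:
            raise ValueError("chrII gene layout overlaps")

    @property
    def _mid_gene_start(self) -> int:
        return self.p2_gene_a_start + self.gene_len + self.mid_gene_gap

    @property
    def _aat_b_start(self) -> int:
        return self._mid_gene_start + self.gene_len + self.cen_gene_gap


@dataclass
class ReadSimConfig:
    """Paired-end library parameters (2 x ``read_len`` bp)."""

    read_len: int = 150
    insert_mean: int = 400
    insert_sd: int = 50
    coverage: float = 30.0
    error_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")
        if not (0 <= self.error_rate < 0.05):
            raise ValueError("error_rate must be in [0, 0.05)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be non-negative")


@dataclass
class RearrangementEvent:
    """Truth (or called) record of one gross chromosomal rearrangement.

    ``first_retained`` is the 1-based reference coordinate of the first
    undeleted base on ``chrom``. ``homology_interval`` is 0-based half-open on
    the reference of ``chrom`` and present exactly for the homology-mediated
    event types; ``partner`` is (chrom, 1-based coord, strand), present for
    translocation and fusion.
    """

    event_type: str
    chrom: str
    first_retained: int
    partner: tuple[str, int, str] | None = None
    homology_interval: tuple[int, int] | None = None
    telomere_seq: str | None = None

    def validate(self, genome: Genome | None = None) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.first_retained < 1:
            raise ValueError("first_retained must be >= 1")
        if genome is not None and self.first_retained > len(genome.chroms[self.chrom]):
            raise ValueError("first_retained beyond chromosome end")
        needs_hom = self.event_type in {"homology_translocation", "inversion_plus_deletion"}
        if (self.homology_interval is not None) != needs_hom:
            raise ValueError("homology_interval present iff the event is homology-mediated")
        needs_partner = self.event_type in {"homology_translocation", "chromosome_fusion"}
        if (self.partner is not None) != needs_partner:
            raise ValueError("partner present iff the event joins two loci")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RearrangementEvent":
        d = dict(d)
        if d.get("partner") is not None:
            d["partner"] = tuple(d["partner"])
        if d.get("homology_interval") is not None:
            d["homology_interval"] = tuple(d["homology_interval"])
        return cls(**d)


@dataclass(frozen=True)
class Segment:
    """One mutant-chromosome block mapped back to the reference.

    Mutant interval [m0, m1). ``ref_chrom`` is None for inserted sequence
    (de novo telomere). For strand '-', mutant offset i maps to reference
    position ``ref_start + (m1 - 1 - i)``... i.e. the block is the reverse
    complement of reference [ref_start, ref_start + (m1 - m0)).
    """

    m0: int
    m1: int
    ref_chrom: str | None
    ref_start: int
    strand: str = "+"


@dataclass
class MutantGenome:
    """Mutant sequences plus the exact per-chromosome reference segment map."""

    reference: Genome
    chroms: dict[str, str]
    segments: dict[str, list[Segment]]
    events: list[RearrangementEvent] = field(default_factory=list)

    def as_genome(self) -> Genome:
        return Genome(chroms=dict(self.chroms), features=[])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    @classmethod
    def identity(cls, genome: Genome) -> "MutantGenome":
        segs = {
            name: [Segment(0, len(seq), name, 0, "+")]
            for name, seq in genome.chroms.items()
        }
        return cls(reference=genome, chroms=dict(genome.chroms), segments=segs)


# --------------------------------------------------------------------------
# toy genome construction
# --------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute each base independently with probability ``divergence``."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < divergence)[0]
    for i in hits:
        choices = [b for b in _BASES if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def _force_diff(seq_list: list[str], i: int, other: str) -> None:
    """Ensure seq_list[i] != other by a deterministic substitution."""
    if seq_list[i] == other:
        j = (_BASES.index(other) + 1) % 4
        seq_list[i] = _BASES[j]


def make_telomere_tract(rng: np.random.Generator, min_len: int,
                        spacer_prob: float = 0.3,
                        core: str = TELOMERE_CORE) -> str:
    """G-rich telomeric tract: tandem cores, each followed with probability
    ``spacer_prob`` by a 1-2 nt A/C spacer (degenerate fission-yeast-like
    grammar; the true telomerase grammar is unspecified, so this is a
    configurable stand-in)."""
    parts: list[str] = []
    total = 0
    while total < min_len:
        parts.append(core)
        total += len(core)
        if rng.random() < spacer_prob:
            n = int(rng.integers(1, 3))
            sp = "".join("AC"[int(rng.integers(0, 2))] for _ in range(n))
            parts.append(sp)
            total += n
    return "".join(parts)[:min_len]


def build_toy_genome(config: ToyGenomeConfig | None = None) -> Genome:
    """Assemble the synthetic genome described in the module docstring.

    Deterministic for a fixed config (same seed twice gives byte-identical
    FASTA). The bases immediately flanking each engineered identical
    region/window are forced to differ between the two homologs, so junctions
    formed through them have discriminating bases exactly at the edges.
    """
    cfg = config or ToyGenomeConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n1, n2, n3 = cfg.chrom_names
    s1, s2, s3 = cfg.chrom_sizes
    tl = cfg.telomere_len
    feats: list[Feature] = []

    # background sequence per chromosome
    seqs = {n1: list(_random_seq(rng, s1)),
            n2: list(_random_seq(rng, s2)),
            n3: list(_random_seq(rng, s3))}

    def plant(chrom: str, start: int, sub: str) -> None:
        seqs[chrom][start : start + len(sub)] = list(sub)

    # telomere tracts: left ends carry the reverse complement of a G-rich
    # tract on the forward strand (the G-rich strand runs 5'->3' toward each
    # chromosome end), right ends carry the G-rich tract directly.
    for name, size in zip(cfg.chrom_names, cfg.chrom_sizes):
        left = revcomp(make_telomere_tract(rng, tl, cfg.spacer_prob))
        right = make_telomere_tract(rng, tl, cfg.spacer_prob)
        plant(name, 0, left)
        plant(name, size - tl, right)
        feats.append(Feature(name, 0, tl, "+", "telomere_tract", f"tel_{name}_L"))
        feats.append(Feature(name, size - tl, size, "+", "telomere_tract", f"tel_{name}_R"))

    # rDNA-like arrays at both ends of the last chromosome (identical unit)
    unit = _random_seq(rng, cfg.rdna_unit_len)
    array = unit * cfg.rdna_copies
    plant(n3, tl, array)
    plant(n3, s3 - tl - len(array), array)
    feats.append(Feature(n3, tl, tl + len(array), "+", "rdna_array", "rdna_l"))
    feats.append(Feature(n3, s3 - tl - len(array), s3 - tl, "+", "rdna_array", "rdna_r"))

    # P1: same-orientation homologous pair sharing one exact internal block
    gl = cfg.gene_len
    ident_off = (gl - cfg.p1_identical_len) // 2
    gene_a = list(_random_seq(rng, gl))
    gene_b = list(_mutate(rng, "".join(gene_a), cfg.homolog_divergence))
    gene_b[ident_off : ident_off + cfg.p1_identical_len] = \
        gene_a[ident_off : ident_off + cfg.p1_identical_len]
    _force_diff(gene_b, ident_off - 1, gene_a[ident_off - 1])
    _force_diff(gene_b, ident_off + cfg.p1_identical_len,
                gene_a[ident_off + cfg.p1_identical_len])
    plant(n1, cfg.p1_gene_a_start, "".join(gene_a))
    plant(n2, cfg.p1_gene_b_start, "".join(gene_b))
    feats.append(Feature(n1, cfg.p1_gene_a_start, cfg.p1_gene_a_start + gl, "+", "gene", "hxtA"))
    feats.append(Feature(n2, cfg.p1_gene_b_start, cfg.p1_gene_b_start + gl, "+", "gene", "hxtB"))
    feats.append(Feature(n1, cfg.p1_gene_a_start + ident_off,
                         cfg.p1_gene_a_start + ident_off + cfg.p1_identical_len,
                         "+", "identical_region", "p1_ident_a"))
    feats.append(Feature(n2, cfg.p1_gene_b_start + ident_off,
                         cfg.p1_gene_b_start + ident_off + cfg.p1_identical_len,
                         "+", "identical_region", "p1_ident_b"))

    # P2: inverted homologous pair flanking a middle gene on the chrII arm,
    # sharing a short window that is identical in chimera-forming orientation
    w = gl // 2
    wlen = cfg.p2_identical_len
    cds_a = list(_random_seq(rng, gl))
    cds_b = list(_mutate(rng, "".join(cds_a), cfg.homolog_divergence))
    cds_b[w : w + wlen] = cds_a[w : w + wlen]
    _force_diff(cds_b, w - 1, cds_a[w - 1])
    _force_diff(cds_b, w + wlen, cds_a[w + wlen])
    aat_a_start = cfg.p2_gene_a_start
    mid_start = cfg._mid_gene_start
    aat_b_start = cfg._aat_b_start
    mid_gene = _random_seq(rng, gl)
    plant(n2, aat_a_start, "".join(cds_a))
    plant(n2, mid_start, mid_gene)
    plant(n2, aat_b_start, revcomp("".join(cds_b)))
    feats.append(Feature(n2, aat_a_start, aat_a_start + gl, "+", "gene", "aatA"))
    feats.append(Feature(n2, mid_start, mid_start + gl, "+", "gene", "alrM"))
    feats.append(Feature(n2, aat_b_start, aat_b_start + gl, "-", "gene", "aatB"))
    # genomic coordinates of the shared window on each homolog
    p2a_start = aat_a_start + w
    p2b_start = aat_b_start + gl - w - wlen   # revcomp placement
    feats.append(Feature(n2, p2a_start, p2a_start + wlen, "+", "identical_region", "p2_ident_a"))
    feats.append(Feature(n2, p2b_start, p2b_start + wlen, "-", "identical_region", "p2_ident_b"))

    # essential gene tens of kb centromeric of the inverted pair
    ess_start = aat_b_start + gl + cfg.essential_gap
    plant(n2, ess_start, _random_seq(rng, 1000))
    feats.append(Feature(n2, ess_start, ess_start + 1000, "+", "essential_gene", "ess1"))

    genome = Genome(chroms={k: "".join(v) for k, v in seqs.items()}, features=feats)
    _check_motif_overlap(genome)
    return genome


def _check_motif_overlap(genome: Genome) -> None:
    by_chrom: dict[str, list[Feature]] = {}
    for f in genome.features:
        if f.kind == "identical_region":
            continue  # nested inside genes by design
        by_chrom.setdefault(f.chrom, []).append(f)
    for chrom, fs in by_chrom.items():
        fs = sorted(fs, key=lambda f: f.start)
        for a, b in zip(fs, fs[1:]):
            if a.end > b.start:
                raise ValueError(f"motifs {a.name} and {b.name} overlap on {chrom}")


# --------------------------------------------------------------------------
# rearrangements
# --------------------------------------------------------------------------

def default_event(genome: Genome, event_type: str, seed: int = 0,
                  n_telomere_cores: int = 30) -> RearrangementEvent:
    """Canonical truth event for each mechanism on the toy genome layout."""
    rng = np.random.default_rng(seed)
    telo = make_telomere_tract(rng, n_telomere_cores * len(TELOMERE_CORE))
    if event_type == "homology_translocation":
        ia = genome.feature("p1_ident_a")
        ib = genome.feature("p1_ident_b")
        return RearrangementEvent(
            event_type, ib.chrom, first_retained=ib.start + 1,
            partner=(ia.chrom, ia.start + 1, "+"),
            homology_interval=(ib.start, ib.end))
    if event_type == "chromosome_fusion":
        hxt_b = genome.feature("hxtB")
        rdna = genome.feature("rdna_l")
        unit = (rdna.end - rdna.start) // 3
        pos = rdna.start + unit + unit // 2  # internal to the second unit
        return RearrangementEvent(
            event_type, hxt_b.chrom, first_retained=hxt_b.end + 5000,
            partner=(rdna.chrom, pos + 1, "+"))
    if event_type == "telomere_addition":
        hxt_b = genome.feature("hxtB")
        return RearrangementEvent(
            event_type, hxt_b.chrom, first_retained=hxt_b.end + 9000,
            telomere_seq=telo)
    if event_type == "inversion_plus_deletion":
        site1 = genome.feature("p2_ident_a")
        mid = genome.feature("alrM")
        return RearrangementEvent(
            event_type, site1.chrom, first_retained=mid.start + 700 + 1,
            homology_interval=(site1.start, site1.end),
            telomere_seq=telo)
    raise ValueError(f"unknown event type {event_type!r}")


def _phase_telomere(telo: str, forbidden_last: set[str]) -> str:
    """Rotate the G-rich tract so the last base of its reverse complement
    (the base that will abut the junction on the forward strand) is not in
    ``forbidden_last``; keeps the junction free of chance aligner extension."""
    for phase in range(len(TELOMERE_CORE)):
        t = telo[phase:] + telo[:phase]
        if revcomp(t)[-1] not in forbidden_last:
            return t
    raise RuntimeError("could not phase telomeric tract")  # pragma: no cover


def lost_intervals(genome: Genome, event: RearrangementEvent) -> list[tuple[int, int]]:
    """Reference intervals on event.chrom absent from the mutant."""
    f0 = event.first_retained - 1
    if event.event_type in {"chromosome_fusion", "telomere_addition"}:
        return [(0, f0)]
    if event.event_type == "homology_translocation":
        hs, _ = event.homology_interval
        return [(0, hs)]
    # inversion_plus_deletion: terminal loss up to site1 start, plus the
    # interior part of the inverted segment beyond the first retained base
    s1, _ = event.homology_interval
    site2 = genome.feature("p2_ident_b")
    return [(0, s1), (f0 + 1, site2.end)]


def apply_rearrangement(genome: Genome, event: RearrangementEvent,
                        ) -> tuple[MutantGenome, RearrangementEvent]:
    """Apply one rearrangement; returns the mutant genome (with its reference
    segment map) and the completed truth record.

    Junctions without engineered homology are made clean: the partner
    coordinate or telomere phase is adjusted so no chance base match lets an
    alignment extend across the junction, and so the two 20 bp junction
    flanks share no suffix/prefix overlap usable as microhomology.
    Fails if the truncation would remove the essential gene.
    """
    event.validate(genome)
    ref = genome.chroms
    chrom = event.chrom
    cseq = ref[chrom]
    f0 = event.first_retained - 1

    for (a, b) in lost_intervals(genome, event):
        for ess in genome.get_features(kind="essential_gene", chrom=chrom):
            if ess.start < b and a < ess.end:
                raise ValueError(
                    f"event would remove essential gene {ess.name}; not viable")

    chroms = dict(ref)
    segments = {n: [Segment(0, len(s), n, 0, "+")] for n, s in ref.items()}
    completed = RearrangementEvent(**{**event.to_dict()})
    if completed.partner is not None:
        completed.partner = tuple(completed.partner)
    if completed.homology_interval is not None:
        completed.homology_interval = tuple(completed.homology_interval)

    if event.event_type == "homology_translocation":
        hs, he = event.homology_interval
        if f0 != hs:
            raise ValueError("first_retained must sit at the homology interval start")
        pchrom, pcoord, _ = event.partner
        pa = pcoord - 1  # partner identical-region start (0-based)
        donor = ref[pchrom]
        if donor[pa : pa + (he - hs)] != cseq[hs:he]:
            raise ValueError("homology interval is not identical between the loci")
        mut = donor[:pa] + cseq[hs:]
        chroms[chrom] = mut
        segments[chrom] = [
            Segment(0, pa, pchrom, 0, "+"),
            Segment(pa, len(mut), chrom, hs, "+"),
        ]

    elif event.event_type == "chromosome_fusion":
        pchrom, pcoord, _ = event.partner
        pseq = ref[pchrom]
        pos = pcoord - 1
        # slide the rDNA-internal breakpoint until the junction is clean:
        # no chance aligner extension on either side and no suffix/prefix
        # overlap of any length usable as microhomology in the 20 bp flanks
        for _ in range(256):
            partner_flank = pseq[pos - 20 : pos]
            retained_flank = cseq[f0 : f0 + 20]
            ok = (pseq[pos - 1] != cseq[f0 - 1]      # no leftward extension
                  and cseq[f0] != pseq[pos]          # no rightward extension
                  and all(partner_flank[-L:] != retained_flank[:L]
                          for L in range(1, 21)))
            if ok:
                break
            pos += 1
        else:  # pragma: no cover
            raise RuntimeError("no clean fusion breakpoint found near partner")
        completed.partner = (pchrom, pos + 1, "+")
        mut = pseq[:pos] + cseq[f0:]
        chroms[chrom] = mut
        segments[chrom] = [
            Segment(0, pos, pchrom, 0, "+"),
            Segment(pos, len(mut), chrom, f0, "+"),
        ]

    elif event.event_type == "telomere_addition":
        telo = event.telomere_seq or TELOMERE_CORE * 4
        if telo.count(TELOMERE_CORE) < 4:
            raise ValueError("appended telomere needs >= 4 core repeats")
        # forbid: chance leftward extension (== cseq[f0-1]) and a 1 bp
        # suffix/prefix junction overlap (== cseq[f0])
        telo = _phase_telomere(telo, {cseq[f0 - 1], cseq[f0]})
        completed.telomere_seq = telo
        left = revcomp(telo)
        mut = left + cseq[f0:]
        chroms[chrom] = mut
        segments[chrom] = [
            Segment(0, len(left), None, 0, "+"),
            Segment(len(left), len(mut), chrom, f0, "+"),
        ]

    elif event.event_type == "inversion_plus_deletion":
        s1, s1e = event.homology_interval
        wlen = s1e - s1
        site2 = genome.feature("p2_ident_b")
        s2, s2e = site2.start, site2.end
        if cseq[s1:s1e] != revcomp(cseq[s2:s2e]):
            raise ValueError("inverted homology sites are not reverse-complement identical")
        if not (s1e <= f0 < s2):
            raise ValueError("first_retained must fall between the inverted homologs")
        telo = event.telomere_seq or TELOMERE_CORE * 4
        if telo.count(TELOMERE_CORE) < 4:
            raise ValueError("appended telomere needs >= 4 core repeats")
        # molecule after inversion + terminal deletion + healing:
        #   telo_rc + revcomp(ref[s1 : f0+1]) + ref[s2e:]
        # the retained piece aligns to the reference on the '-' strand ending
        # at ref f0; forbid revcomp(telo)[-1] == complement(ref[f0+1]) so the
        # reverse-strand alignment cannot extend one base past f0
        telo = _phase_telomere(telo, {_COMP[cseq[f0 + 1]]})
        completed.telomere_seq = telo
        left = revcomp(telo)
        inv = revcomp(cseq[s1 : f0 + 1])
        mut = left + inv + cseq[s2e:]
        chroms[chrom] = mut
        segments[chrom] = [
            Segment(0, len(left), None, 0, "+"),
            Segment(len(left), len(left) + len(inv), chrom, s1, "-"),
            Segment(len(left) + len(inv), len(mut), chrom, s2e, "+"),
        ]

    else:  # pragma: no cover
        raise ValueError(event.event_type)

    mutant = MutantGenome(reference=genome, chroms=chroms, segments=segments,
                          events=[completed])
    return mutant, completed


# --------------------------------------------------------------------------
# read simulation with truth alignments
# --------------------------------------------------------------------------

@dataclass
class SimulatedRead:
    name: str
    mate: int            # 1 or 2
    seq: str             # as sequenced
    # truth alignment against the reference (None fields when unmapped)
    ref_chrom: str | None
    ref_start: int       # 0-based leftmost aligned base
    sam_reverse: bool
    left_clip: int
    match_len: int
    right_clip: int
    stored_seq: str      # SEQ column (reference-forward orientation)
    mapq: int
    # provenance (mutant coordinates of the whole read)
    m_chrom: str = ""
    m0: int = 0
    m1: int = 0


@dataclass
class SimulatedReadSet:
    reads: list[SimulatedRead]          # R1,R2 interleaved per pair
    mutant: MutantGenome
    config: ReadSimConfig

    def write_fastq(self, r1_path, r2_path) -> None:
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for rd in self.reads:
                fh = f1 if rd.mate == 1 else f2
                fh.write(f"@{rd.name}/{rd.mate}\n{rd.seq}\n+\n{'I' * len(rd.seq)}\n")

    def write_sam(self, path) -> None:
        write_truth_sam(self.reads, self.mutant.reference, path, self.config)


_MULTICOPY_KINDS = {"identical_region", "rdna_array", "telomere_tract"}


def _multicopy_intervals(genome: Genome) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for f in genome.features:
        if f.kind in _MULTICOPY_KINDS:
            out.setdefault(f.chrom, []).append((f.start, f.end))
    return out


def _map_read(mutant: MutantGenome, chrom: str, r0: int, r1: int,
              min_match: int = 20):
    """Truth alignment of mutant interval [r0, r1): choose the segment giving
    the longest reference-contiguous match (extended through locally
    identical sequence), ties to the lower reference coordinate.

    Returns (ref_chrom, ref0, strand, a0, a1) with [a0, a1) the matched
    mutant sub-interval, or None when no match reaches ``min_match``.
    """
    segs = mutant.segments[chrom]
    mseq = mutant.chroms[chrom]
    ref = mutant.reference.chroms
    best = None
    for seg in segs:
        if seg.m1 <= r0 or seg.m0 >= r1 or seg.ref_chrom is None:
            continue
        rseq = ref[seg.ref_chrom]
        rlen = len(rseq)
        a0, a1 = max(r0, seg.m0), min(r1, seg.m1)
        if seg.strand == "+":
            off = seg.ref_start - seg.m0
            while a0 > r0 and 0 <= a0 - 1 + off and mseq[a0 - 1] == rseq[a0 - 1 + off]:
                a0 -= 1
            while a1 < r1 and a1 + off < rlen and mseq[a1] == rseq[a1 + off]:
                a1 += 1
            ref0 = a0 + off
        else:
            # mutant x <-> ref seg.ref_start + (seg.m1 - 1 - x), complemented
            base = seg.ref_start + seg.m1 - 1
            while a0 > r0 and base - (a0 - 1) < rlen and \
                    mseq[a0 - 1] == _COMP[rseq[base - (a0 - 1)]]:
                a0 -= 1
            while a1 < r1 and base - a1 >= 0 and mseq[a1] == _COMP[rseq[base - a1]]:
                a1 += 1
            ref0 = base - (a1 - 1)
        cand = (-(a1 - a0), seg.ref_chrom, ref0, seg.strand, a0, a1)
        if best is None or cand[:3] < best[:3]:
            best = cand
    if best is None or -best[0] < min_match:
        return None
    _, ref_chrom, ref0, strand, a0, a1 = best
    return ref_chrom, ref0, strand, a0, a1


def simulate_reads(source: MutantGenome | Genome, cfg: ReadSimConfig,
                   ) -> SimulatedReadSet:
    """Simulate a 2 x ``read_len`` paired-end library from the mutant genome.

    Fragments are drawn uniformly; lengths ~ Normal(insert_mean, insert_sd)
    truncated at read_len. R1 is the forward fragment start, R2 the reverse
    complement of the fragment end. Substitution errors are i.i.d. per base;
    no indel errors, so truth CIGARs stay exact (errors appear as mismatches
    inside the matched block and never move the truth alignment). Reads whose
    truth alignment lies entirely inside an annotated multi-copy feature
    (identical region, rDNA array, telomeric tract) get MAPQ 0.
    """
    cfg.validate()
    mutant = source if isinstance(source, MutantGenome) else MutantGenome.identity(source)
    rng = np.random.default_rng(cfg.seed)
    names = list(mutant.chroms)
    lens = np.array([len(mutant.chroms[n]) for n in names], dtype=np.int64)
    total = int(lens.sum())
    n_pairs = int(round(cfg.coverage * total / (2 * cfg.read_len)))

    which = rng.choice(len(names), size=n_pairs, p=lens / total)
    flen = np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, n_pairs)).astype(np.int64)
    flen = np.maximum(flen, cfg.read_len)
    flen = np.minimum(flen, lens[which])
    start = np.floor(rng.random(n_pairs) * (lens[which] - flen + 1)).astype(np.int64)

    # substitution errors, drawn in pair order for determinism
    nerr = rng.binomial(cfg.read_len, cfg.error_rate, size=2 * n_pairs)

    multicopy = _multicopy_intervals(mutant.reference)

    def inject_errors(seq: str, k: int) -> str:
        if k == 0:
            return seq
        out = list(seq)
        pos = rng.integers(0, len(seq), k)
        shift = rng.integers(1, 4, k)
        for p, s in zip(pos, shift):
            out[p] = _BASES[(_BASES.index(out[p]) + s) % 4]
        return "".join(out)

    def low_mapq(ref_chrom: str, ref0: int, ref1: int) -> bool:
        for (a, b) in multicopy.get(ref_chrom, ()):
            if a <= ref0 and ref1 <= b:
                return True
        return False

    reads: list[SimulatedRead] = []
    rl = cfg.read_len
    for i in range(n_pairs):
        chrom = names[which[i]]
        f0, fl = int(start[i]), int(flen[i])
        mseq = mutant.chroms[chrom]
        frag_r1 = (f0, f0 + rl)
        frag_r2 = (f0 + fl - rl, f0 + fl)
        name = f"sim{i:07d}"
        for mate, (m0, m1) in ((1, frag_r1), (2, frag_r2)):
            raw = mseq[m0:m1]
            read_seq = raw if mate == 1 else revcomp(raw)
            read_seq = inject_errors(read_seq, int(nerr[2 * i + (mate - 1)]))
            aln = _map_read(mutant, chrom, m0, m1)
            if aln is None:
                reads.append(SimulatedRead(name, mate, read_seq, None, 0, False,
                                           0, 0, 0, read_seq, 0, chrom, m0, m1))
                continue
            ref_chrom, ref0, strand, a0, a1 = aln
            read_is_fwd = mate == 1
            sam_reverse = (strand == "+") != read_is_fwd
            stored = revcomp(read_seq) if sam_reverse else read_seq
            if strand == "+":
                lclip, match, rclip = a0 - m0, a1 - a0, m1 - a1
            else:
                lclip, match, rclip = m1 - a1, a1 - a0, a0 - m0
            mapq = 0 if low_mapq(ref_chrom, ref0, ref0 + match) else 60
            reads.append(SimulatedRead(name, mate, read_seq, ref_chrom, ref0,
                                       sam_reverse, lclip, match, rclip,
                                       stored, mapq, chrom, m0, m1))
    return SimulatedReadSet(reads=reads, mutant=mutant, config=cfg)


def write_truth_sam(reads: list[SimulatedRead], reference: Genome, path,
                    cfg: ReadSimConfig) -> None:
    """Plain-text SAM of the truth alignments (valid @SQ header, soft-clip
    CIGARs; pairs on consecutive lines, R1 then R2)."""
    max_proper = cfg.insert_mean + 5 * cfg.insert_sd
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in reference.chroms.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        fh.write("@PG\tID:gcrscope\tPN:gcrscope\n")
        for j in range(0, len(reads), 2):
            r1, r2 = reads[j], reads[j + 1]
            for rd, other in ((r1, r2), (r2, r1)):
                flag = 0x1 | (0x40 if rd.mate == 1 else 0x80)
                mapped = rd.ref_chrom is not None
                omapped = other.ref_chrom is not None
                if not mapped:
                    flag |= 0x4
                if not omapped:
                    flag |= 0x8
                if mapped and rd.sam_reverse:
                    flag |= 0x10
                if omapped and other.sam_reverse:
                    flag |= 0x20
                tlen = 0
                proper = False
                if mapped and omapped and rd.ref_chrom == other.ref_chrom:
                    lo = min(rd.ref_start, other.ref_start)
                    hi = max(rd.ref_start + rd.match_len,
                             other.ref_start + other.match_len)
                    span = hi - lo
                    tlen = span if rd.ref_start <= other.ref_start else -span
                    fwd, rev = (rd, other) if not rd.sam_reverse else (other, rd)
                    proper = (rd.sam_reverse != other.sam_reverse
                              and not fwd.sam_reverse and rev.sam_reverse
                              and fwd.ref_start <= rev.ref_start
                              and span <= max_proper)
                if proper:
                    flag |= 0x2
                if mapped:
                    cig = ""
                    if rd.left_clip:
                        cig += f"{rd.left_clip}S"
                    cig += f"{rd.match_len}M"
                    if rd.right_clip:
                        cig += f"{rd.right_clip}S"
                    rname, pos = rd.ref_chrom, rd.ref_start + 1
                else:
                    cig, rname, pos = "*", "*", 0
                if omapped:
                    rnext = "=" if (mapped and other.ref_chrom == rd.ref_chrom) \
                        else other.ref_chrom
                    pnext = other.ref_start + 1
                else:
                    rnext, pnext = ("=" if mapped else "*"), (pos if mapped else 0)
                fh.write(
                    f"{rd.name}\t{flag}\t{rname}\t{pos}\t{rd.mapq if mapped else 0}"
                    f"\t{cig}\t{rnext}\t{pnext}\t{tlen}\t{rd.stored_seq}"
                    f"\t{'I' * len(rd.stored_seq)}\n")


def write_truth_json(events: list[RearrangementEvent], path) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in events], fh, indent=2)


def read_truth_json(path) -> list[RearrangementEvent]:
    with open(path) as fh:
        return [RearrangementEvent.from_dict(d) for d in json.load(fh)]
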