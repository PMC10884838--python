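"""Soft-clip junction calling and clipped-sequence characterisation.

Reads whose alignments end in a soft clip of at least ``min_clip`` bases are
grouped by (chromosome, clip coordinate, clip side); a cluster's junction is
the 1-based first retained (aligned) base adjacent to the clip. The cluster
consensus is the per-column majority over the clipped parts, oriented 5'->3'
away from the retained side (for left clips this is the reverse complement
of the clipped bases as stored), so a de novo telomere read off a left-arm
junction shows the G-rich GGTTAC core directly.

Junctions formed through sequence identical between two loci are not
point-resolvable; alignments extend through the shared block, so the cluster
lands on the outermost discriminating position, and interval-level
resolution is delegated to homology analysis.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pysam

from .genome import Genome, revcomp

logger = logging.getLogger(__name__)

TELOMERE_CORE = "GGTTAC"


@dataclass
class SoftClipCluster:
    chrom: str
    junction: int          # 1-based first retained (aligned) base
    side: str              # left_clip | right_clip
    support: int
    consensus_clip: str    # 5'->3' away from the retained side
    mean_clip_len: float


@dataclass
class PartnerHit:
    chrom: str
    start: int             # 0-based on the reference forward strand
    end: int
    strand: str            # '+': clip matches forward strand; '-': reverse
    identity: float        # percent
    length: int


@dataclass
class ClipCharacterization:
    telomere_score: int
    is_telomeric: bool
    partner_hits: list[PartnerHit] = field(default_factory=list)
    microhomology_len: int = 0
    flags: list[str] = field(default_factory=list)


# --------------------------------------------------------------------- clips

def cluster_soft_clips(alignments, min_clip: int = 10, min_support: int = 3,
                       min_mapq: int = 0) -> list[SoftClipCluster]:
    """Cluster soft-clipped read ends into candidate junctions.

    Member reads of a cluster clip at the identical coordinate; clusters with
    fewer than ``min_support`` reads are dropped. Malformed CIGARs are
    skipped with a warning rather than raising.
    """
    af = alignments if isinstance(alignments, pysam.AlignmentFile) \
        else pysam.AlignmentFile(str(alignments))
    groups: dict[tuple[str, int, str], list[str]] = defaultdict(list)
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            try:
                cig = read.cigartuples
                seq = read.query_sequence
                if not cig or seq is None:
                    continue
                op0, l0 = cig[0]
                opn, ln = cig[-1]
                if op0 == 4 and l0 >= min_clip:
                    junction = read.reference_start + 1
                    clip = revcomp(seq[:l0])  # outward orientation
                    groups[(read.reference_name, junction, "left_clip")].append(clip)
                if opn == 4 and ln >= min_clip:
                    junction = read.reference_end
                    clip = seq[-ln:]
                    groups[(read.reference_name, junction, "right_clip")].append(clip)
            except (ValueError, TypeError) as exc:
                logger.warning("skipping read %s: malformed CIGAR (%s)",
                               read.query_name, exc)
    finally:
        if not isinstance(alignments, pysam.AlignmentFile):
            af.close()

    clusters = []
    for (chrom, junction, side), clips in sorted(groups.items()):
        if len(clips) < min_support:
            continue
        clusters.append(SoftClipCluster(
            chrom=chrom, junction=junction, side=side, support=len(clips),
            consensus_clip=_consensus(clips),
            mean_clip_len=sum(map(len, clips)) / len(clips)))
    return clusters


def _consensus(clips: list[str]) -> str:
    """Per-column majority vote over junction-anchored clipped parts; ties
    become N (excluded from telomere scoring and realignment seeds)."""
    out = []
    for i in range(max(map(len, clips))):
        col = Counter(c[i] for c in clips if len(c) > i)
        best = col.most_common()
        if len(best) > 1 and best[0][1] == best[1][1]:
            out.append("N")
        else:
            out.append(best[0][0])
    return "".join(out)


# ------------------------------------------------------------- telomere score

def score_telomeric(seq: str, core: str = TELOMERE_CORE, max_spacer: int = 2,
                    min_copies: int = 2) -> tuple[int, bool]:
    """Count tandem copies of the telomeric core motif in ``seq``.

    A tandem chain is a series of exact core occurrences in which consecutive
    cores are separated by at most ``max_spacer`` non-core bases. The score
    is the size of the largest chain; the sequence is called telomeric when
    the score reaches ``min_copies`` and the chain spans at least half of the
    sequence. N bases never match the core.
    """
    if not seq:
        raise ValueError("empty sequence")
    occ = []
    i = seq.find(core)
    while i != -1:
        occ.append(i)
        i = seq.find(core, i + 1)
    if not occ:
        return 0, False
    cl = len(core)
    # chain DP over occurrence graph (equivalent to the greedy scan but
    # robust to overlapping occurrence layouts)
    best_len = [1] * len(occ)
    best_span_start = list(occ)
    for j in range(len(occ)):
        for p in range(j):
            gap = occ[j] - (occ[p] + cl)
            if 0 <= gap <= max_spacer and best_len[p] + 1 > best_len[j]:
                best_len[j] = best_len[p] + 1
                best_span_start[j] = best_span_start[p]
    score = 0
    covered = False
    for j in range(len(occ)):
        span = occ[j] + cl - best_span_start[j]
        if best_len[j] > score:
            score = best_len[j]
            covered = span >= 0.5 * len(seq)
        elif best_len[j] == score:
            covered = covered or span >= 0.5 * len(seq)
    return score, bool(score >= min_copies and covered)


# --------------------------------------------------------------- realignment

def realign_clip(consensus_clip: str, genome: Genome, min_hit_len: int = 15,
                 max_mismatches: int = 2) -> tuple[list[PartnerHit], list[str]]:
    """Seed-and-extend realignment of a clip consensus against both strands.

    Exact seeds of ``min_hit_len`` (skipping N) are located with substring
    search and extended without gaps, allowing up to ``max_mismatches``
    mismatches. Hits are reported with percent identity, sorted by alignment
    length then identity. Returns (hits, flags); a clip shorter than the
    seed length yields no hits and the flag ``too_short``.
    """
    clip = consensus_clip
    if len(clip) < min_hit_len:
        return [], ["too_short"]
    hits: dict[tuple[str, str, int], PartnerHit] = {}
    for strand in "+-":
        q = clip if strand == "+" else revcomp(clip)
        for chrom, seq in genome.chroms.items():
            for qpos in range(0, len(q) - min_hit_len + 1):
                seed = q[qpos : qpos + min_hit_len]
                if "N" in seed:
                    continue
                s = seq.find(seed)
                while s != -1:
                    diag = s - qpos
                    key = (chrom, strand, diag)
                    if key not in hits:
                        hit = _extend(q, seq, qpos, s, min_hit_len, max_mismatches)
                        if hit is not None:
                            g0, g1, ident = hit
                            hits[key] = PartnerHit(
                                chrom=chrom, start=g0, end=g1, strand=strand,
                                identity=ident, length=g1 - g0)
                        else:
                            hits[key] = None  # type: ignore[assignment]
                    s = seq.find(seed, s + 1)
    out = [h for h in hits.values() if h is not None]
    out.sort(key=lambda h: (-h.length, -h.identity, h.chrom, h.start))
    return out, []


def _extend(q: str, seq: str, qpos: int, s: int, seed_len: int,
            max_mm: int) -> tuple[int, int, float] | None:
    """Ungapped two-sided extension of an exact seed; returns genome
    interval and percent identity, or None for a degenerate hit."""
    mm = 0
    q0, g0 = qpos, s
    while q0 > 0 and g0 > 0:
        if q[q0 - 1] != seq[g0 - 1] or q[q0 - 1] == "N":
            if mm + 1 > max_mm or q[q0 - 1] == "N":
                break
            mm += 1
        q0 -= 1
        g0 -= 1
    q1, g1 = qpos + seed_len, s + seed_len
    while q1 < len(q) and g1 < len(seq):
        if q[q1] != seq[g1] or q[q1] == "N":
            if mm + 1 > max_mm or q[q1] == "N":
                break
            mm += 1
        q1 += 1
        g1 += 1
    # trim flanking mismatches
    while q1 - q0 > 0 and q[q1 - 1] != seq[g1 - 1]:
        q1 -= 1
        g1 -= 1
        mm -= 1
    while q1 - q0 > 0 and q[q0] != seq[g0]:
        q0 += 1
        g0 += 1
        mm -= 1
    length = g1 - g0
    if length < seed_len:
        return None
    ident = 100.0 * (length - mm) / length
    return g0, g1, ident


# ------------------------------------------------------------ microhomology

def measure_microhomology(retained_flank: str, partner_flank: str) -> int:
    """Length of the longest exact sequence shared across a junction.

    Convention: both flanks are written on the junction-forming strand in
    joined-molecule order — ``partner_flank`` ends at the junction and
    ``retained_flank`` starts at it. The value is the largest L for which the
    last L bases the partner contributes equal the first L bases the retained
    side contributes next (``partner_flank[-L:] == retained_flank[:L]``); the
    joined molecule is ambiguous over that many bases. Identical flanks of
    length w give w — full homology, which callers route to homology-driven
    logic rather than microhomology-mediated joining.
    """
    w = min(len(retained_flank), len(partner_flank))
    best = 0
    for L in range(1, w + 1):
        if partner_flank[-L:] == retained_flank[:L]:
            best = L
    return best


def write_cluster_tsv(rows: list[tuple[SoftClipCluster, ClipCharacterization]],
                      path) -> None:
    """One row per cluster: junction, support, clip stats, telomere score,
    top partner hit and microhomology."""
    with open(path, "w") as fh:
        fh.write("chrom\tjunction\tside\tsupport\tmean_clip_len\t"
                 "telomere_score\tis_telomeric\tpartner\tmicrohomology_len\n")
        for cl, ch in rows:
            top = ch.partner_hits[0] if ch.partner_hits else None
            partner = (f"{top.chrom}:{top.start + 1}-{top.end}({top.strand})"
                       f"@{top.identity:.1f}%" if top else ".")
            fh.write(f"{cl.chrom}\t{cl.junction}\t{cl.side}\t{cl.support}\t"
                     f"{cl.mean_clip_len:.1f}\t{ch.telomere_score}\t"
                     f"{int(ch.is_telomeric)}\t{partner}\t{ch.microhomology_len}\n")
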