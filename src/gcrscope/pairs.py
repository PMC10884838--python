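"""Discordant read-pair analysis and homology-interval breakpoint narrowing.

Read pairs violating the expected library geometry flag structural variants:
mates on the same strand (inversion), mates on different chromosomes
(translocation/fusion) or inserts far beyond the library distribution.
Chimera-supporting pairs — pairs consistent with a hybrid of two homologous
genes but with neither parental locus — pin down homology-driven junctions,
and alignment of the homologs narrows such junctions to the interval of
perfect identity containing the switch, which is the best obtainable
resolution for a recombination-mediated breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio import Align

from .genome import Feature, revcomp


@dataclass
class DiscordantGroup:
    kind: str                       # inversion_FF | inversion_RR | inter_chromosomal | long_insert
    locusA: tuple[str, int, int]    # chrom, start, end (0-based half-open)
    locusB: tuple[str, int, int]
    support: int
    pair_names: list[str] = field(default_factory=list)


@dataclass
class ChimeraSupport:
    geneA: str
    geneB: str
    pairs: list[str]
    informative: int

    @property
    def support(self) -> int:
        return len(self.pairs)


@dataclass
class HomologyInterval:
    """Interval of perfect identity between two homologs around a junction.

    ``seqA_range``/``seqB_range`` are 0-based half-open on the two (oriented)
    input sequences; the optional genomic fields locate the same interval on
    the reference for pipeline use.
    """

    seqA_range: tuple[int, int]
    seqB_range: tuple[int, int]
    length: int
    is_exact: bool
    genomic_a: tuple[str, int, int] | None = None
    genomic_b: tuple[str, int, int] | None = None
    inverted: bool = False


# ------------------------------------------------------------------- pairs

def _collect_pairs(alignments):
    """Primary mapped mate pairs keyed by name; raises on unpaired input."""
    af = alignments if isinstance(alignments, pysam.AlignmentFile) \
        else pysam.AlignmentFile(str(alignments))
    pairs: dict[str, list] = {}
    saw_paired = False
    try:
        for read in af.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired:
                saw_paired = True
            if read.is_unmapped:
                continue
            pairs.setdefault(read.query_name, []).append(read)
    finally:
        if not isinstance(alignments, pysam.AlignmentFile):
            af.close()
    if not saw_paired:
        raise ValueError("input contains no paired reads")
    return {k: v for k, v in pairs.items() if len(v) == 2}


def estimate_insert_stats(pairs: dict[str, list]) -> tuple[float, float]:
    """Median insert and MAD-based sd over concordantly oriented pairs."""
    inserts = []
    for a, b in pairs.values():
        if a.reference_name != b.reference_name or a.is_reverse == b.is_reverse:
            continue
        fwd, rev = (a, b) if not a.is_reverse else (b, a)
        if fwd.reference_start <= rev.reference_start:
            inserts.append(rev.reference_end - fwd.reference_start)
    if not inserts:
        raise ValueError("no proper pairs to estimate insert size from")
    arr = np.asarray(inserts)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return med, 1.4826 * mad


def find_discordant_pairs(alignments, insert_mean: float | None = None,
                          insert_sd: float | None = None,
                          min_pairs: int = 3,
                          min_mapq: int = 1) -> list[DiscordantGroup]:
    """Flag and cluster discordant pairs.

    Pairs are flagged when the mates share orientation (inversion_FF /
    inversion_RR), map to different chromosomes (inter_chromosomal), or span
    an insert larger than insert_mean + 5*insert_sd (long_insert). Flagged
    pairs are clustered per kind with a window of insert_mean + 3*insert_sd
    on both loci; clusters below ``min_pairs`` are dropped.
    """
    pairs = _collect_pairs(alignments)
    if insert_mean is None or insert_sd is None:
        insert_mean, insert_sd = estimate_insert_stats(pairs)
    max_insert = insert_mean + 5 * insert_sd
    window = insert_mean + 3 * insert_sd

    flagged: dict[str, list] = {}
    for name, (a, b) in sorted(pairs.items()):
        if min(a.mapping_quality, b.mapping_quality) < min_mapq:
            continue
        # order by (chrom, position)
        if (a.reference_name, a.reference_start) > (b.reference_name, b.reference_start):
            a, b = b, a
        kind = None
        if a.reference_name != b.reference_name:
            kind = "inter_chromosomal"
        elif a.is_reverse == b.is_reverse:
            kind = "inversion_RR" if a.is_reverse else "inversion_FF"
        elif not a.is_reverse and b.is_reverse:
            if b.reference_end - a.reference_start > max_insert:
                kind = "long_insert"
        if kind is not None:
            flagged.setdefault(kind, []).append((name, a, b))

    groups: list[DiscordantGroup] = []
    for kind, items in sorted(flagged.items()):
        items.sort(key=lambda t: (t[1].reference_name, t[1].reference_start,
                                  t[2].reference_name, t[2].reference_start))
        current: list = []
        for item in items:
            if current and _compatible(current[-1], item, window):
                current.append(item)
            else:
                groups.extend(_finish_group(kind, current, min_pairs))
                current = [item]
        groups.extend(_finish_group(kind, current, min_pairs))
    return groups


def _compatible(prev, item, window) -> bool:
    _, pa, pb = prev
    _, a, b = item
    return (a.reference_name == pa.reference_name
            and b.reference_name == pb.reference_name
            and abs(a.reference_start - pa.reference_start) <= window
            and abs(b.reference_start - pb.reference_start) <= window)


def _finish_group(kind, items, min_pairs) -> list[DiscordantGroup]:
    if len(items) < min_pairs:
        return []
    a_chrom = items[0][1].reference_name
    b_chrom = items[0][2].reference_name
    a0 = min(t[1].reference_start for t in items)
    a1 = max(t[1].reference_end for t in items)
    b0 = min(t[2].reference_start for t in items)
    b1 = max(t[2].reference_end for t in items)
    return [DiscordantGroup(kind=kind, locusA=(a_chrom, a0, a1),
                            locusB=(b_chrom, b0, b1), support=len(items),
                            pair_names=[t[0] for t in items])]


# ----------------------------------------------------------------- chimeras

def _specific_intervals(gene: Feature, ident: tuple[str, int, int]) -> list[tuple[int, int]]:
    _, s, e = ident
    out = []
    if gene.start < s:
        out.append((gene.start, s))
    if e < gene.end:
        out.append((e, gene.end))
    return out


def _overlap(a0, a1, b0, b1) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def collect_chimera_support(alignments, geneA: Feature, geneB: Feature,
                            identical: HomologyInterval,
                            insert_mean: float | None = None,
                            insert_sd: float | None = None) -> ChimeraSupport:
    """Read pairs supporting a chimera of two homologous genes.

    A pair supports the chimera when one mate anchors (MAPQ > 0, at least one
    base outside the shared identical region) in gene A and the other in
    gene B, the pair as mapped is inconsistent with both parental loci, and
    the insert implied on the chimeric molecule is within insert_mean +/-
    3*insert_sd. Pairs with both mates entirely inside the identical region
    carry no information and are never counted. ``informative`` counts pairs
    meeting the one-discriminating-base rule on both sides (for anchored
    pairs this is implied by anchoring).
    """
    if identical is None or identical.genomic_a is None or identical.genomic_b is None:
        raise ValueError("chimera support requires the genomic identical interval")
    pairs = _collect_pairs(alignments)
    if insert_mean is None or insert_sd is None:
        insert_mean, insert_sd = estimate_insert_stats(pairs)
    lo, hi = insert_mean - 3 * insert_sd, insert_mean + 3 * insert_sd

    ga, gb = identical.genomic_a, identical.genomic_b
    a_spec = _specific_intervals(geneA, ga)
    b_spec = _specific_intervals(geneB, gb)

    supporting: list[str] = []
    informative = 0
    for name, (r1, r2) in sorted(pairs.items()):
        for ma, mb in ((r1, r2), (r2, r1)):
            if ma.mapping_quality < 1 or mb.mapping_quality < 1:
                continue
            if ma.reference_name != geneA.chrom or mb.reference_name != geneB.chrom:
                continue
            a_disc = sum(_overlap(ma.reference_start, ma.reference_end, s, e)
                         for s, e in a_spec)
            b_disc = sum(_overlap(mb.reference_start, mb.reference_end, s, e)
                         for s, e in b_spec)
            in_gene_a = _overlap(ma.reference_start, ma.reference_end,
                                 geneA.start, geneA.end) > 0
            in_gene_b = _overlap(mb.reference_start, mb.reference_end,
                                 geneB.start, geneB.end) > 0
            if not (in_gene_a and in_gene_b and a_disc >= 1 and b_disc >= 1):
                continue
            if not _parental_inconsistent(ma, mb, insert_mean, insert_sd):
                continue
            ins = _implied_chimera_insert(ma, mb, ga, gb, identical.inverted)
            if ins is None or not (lo <= ins <= hi):
                continue
            supporting.append(name)
            informative += 1
            break
    return ChimeraSupport(geneA=geneA.name, geneB=geneB.name,
                          pairs=supporting, informative=informative)


def _parental_inconsistent(ma, mb, mean, sd) -> bool:
    """True when the mapped pair cannot come from an intact parental locus."""
    if ma.reference_name != mb.reference_name:
        return True
    if ma.is_reverse == mb.is_reverse:
        return True
    fwd, rev = (ma, mb) if not ma.is_reverse else (mb, ma)
    if fwd.reference_start > rev.reference_start:
        return True  # everted
    return rev.reference_end - fwd.reference_start > mean + 5 * sd


def _implied_chimera_insert(ma, mb, ga, gb, inverted) -> float | None:
    """Insert length the pair implies on the chimeric molecule.

    The chimera joins the gene A side to the gene B side through the shared
    identical interval (counted once, on the B side). For same-orientation
    homologs the A mate lies telomeric of the interval start and the B mate
    centromeric of it; for inverted homologs the B side enters the chimera
    reverse-complemented, so distance is measured from the interval's far
    edge. Both role assignments are tried; the one yielding a plausible
    positive insert is returned.
    """
    _, ja0, ja1 = ga
    _, jb0, jb1 = gb
    cands = []
    if not inverted:
        cands.append((ja0 - ma.reference_start) + (mb.reference_end - jb0))
        cands.append((jb0 - mb.reference_start) + (ma.reference_end - ja0))
    else:
        cands.append((ja0 - ma.reference_start) + (jb1 - mb.reference_start))
        cands.append((mb.reference_end - jb0) + (ma.reference_end - ja0))
    cands = [c for c in cands if c > 0]
    return min(cands) if cands else None


# --------------------------------------------------- breakpoint narrowing

def narrow_breakpoint_interval(seqA: str, seqB: str, approx_break: int,
                               match: int = 1, mismatch: int = -1,
                               gap: int = -2) -> HomologyInterval:
    """Narrow a homology-mediated breakpoint to its identical interval.

    ``seqA`` and ``seqB`` must already be in chimera-forming orientation
    (reverse-complement one homolog of an inverted pair first). They are
    globally aligned with free end gaps; the breakpoint interval is the
    maximal run of identical aligned columns containing the switch column
    (the column holding seqA position ``approx_break``). When that column is
    not identical in both sequences the interval has length 0 and
    ``is_exact`` is False.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    try:  # free end gaps; attribute names changed across Biopython versions
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # pragma: no cover
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    aln = aligner.align(seqA, seqB)[0]

    # aligned columns as parallel coordinate lists, block by block
    cols: list[tuple[int, int, bool]] = []
    blocks_a, blocks_b = aln.aligned
    block_id = []
    for bi, ((a0, a1), (b0, b1)) in enumerate(zip(blocks_a, blocks_b)):
        for off in range(a1 - a0):
            pa, pb = a0 + off, b0 + off
            cols.append((pa, pb, seqA[pa] == seqB[pb]))
            block_id.append(bi)
    switch_idx = next((i for i, (pa, _, _) in enumerate(cols)
                       if pa == approx_break), None)
    if switch_idx is None or not cols[switch_idx][2]:
        return HomologyInterval(seqA_range=(approx_break, approx_break),
                                seqB_range=(0, 0), length=0, is_exact=False)
    lo = switch_idx
    while lo > 0 and cols[lo - 1][2] and block_id[lo - 1] == block_id[lo]:
        lo -= 1
    hi = switch_idx
    while hi + 1 < len(cols) and cols[hi + 1][2] and block_id[hi + 1] == block_id[hi]:
        hi += 1
    a0, b0 = int(cols[lo][0]), int(cols[lo][1])
    a1, b1 = int(cols[hi][0]) + 1, int(cols[hi][1]) + 1
    return HomologyInterval(seqA_range=(a0, a1), seqB_range=(b0, b1),
                            length=a1 - a0, is_exact=True)


def homology_interval_from_features(genome, ident_a: Feature, ident_b: Feature,
                                    ) -> HomologyInterval:
    """Build the genomic identical interval record from a pair of annotated
    identical-region features (used when truth annotation is available)."""
    inverted = ident_a.strand != ident_b.strand
    return HomologyInterval(
        seqA_range=(0, ident_a.end - ident_a.start),
        seqB_range=(0, ident_b.end - ident_b.start),
        length=ident_a.end - ident_a.start,
        is_exact=True,
        genomic_a=(ident_a.chrom, ident_a.start, ident_a.end),
        genomic_b=(ident_b.chrom, ident_b.start, ident_b.end),
        inverted=inverted)
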