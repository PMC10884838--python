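"""Soft-clip clustering, telomere motif scoring, clip realignment and
junction microhomology."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gcrscope import (cluster_soft_clips, score_telomeric, realign_clip,
                      measure_microhomology, revcomp, TELOMERE_CORE)


# ------------------------------------------------------- telomere scoring

def brute_force_best_chain(seq, core=TELOMERE_CORE, max_spacer=2):
    """Exhaustive enumeration of all tandem chains of exact core occurrences
    with inter-core gaps <= max_spacer; returns (best size, best span)."""
    occ = [i for i in range(len(seq) - len(core) + 1)
           if seq[i : i + len(core)] == core]
    best = (0, 0)

    def walk(chain):
        nonlocal best
        size = len(chain)
        span = chain[-1] + len(core) - chain[0] if chain else 0
        if size > best[0] or (size == best[0] and span > best[1]):
            best = (size, span)
        last_end = chain[-1] + len(core)
        for nxt in occ:
            if 0 <= nxt - last_end <= max_spacer:
                walk(chain + [nxt])

    for start in occ:
        walk([start])
    return best


@pytest.mark.parametrize("seq,expected", [
    ("GGTTACGGTTACGGTTAC", (3, True)),       # pure tandem cores
    ("ACGTACGTACGTACGT", (0, False)),        # no core at all
    ("GGTTACAGGTTACCGGTTAC", (3, True)),     # 1 nt spacers tolerated
    ("GGTTAC", (1, False)),                  # below min_copies
    ("GGTTACTTTTGGTTAC", (1, False)),        # gap beyond max_spacer breaks the chain
])
def test_score_telomeric_examples(seq, expected):
    assert score_telomeric(seq) == expected


def test_score_telomeric_matches_exhaustive_enumeration():
    """DP chain score equals brute-force enumeration over all tandem-chain
    decompositions for random short sequences seeded with cores."""
    rng = np.random.default_rng(8)
    for _ in range(300):
        n = int(rng.integers(6, 61))
        seq = "".join("ACGT"[j] for j in rng.integers(0, 4, n))
        # splice in a few cores to make chains likely
        for _ in range(int(rng.integers(0, 4))):
            p = int(rng.integers(0, max(1, len(seq) - 6)))
            seq = seq[:p] + TELOMERE_CORE + seq[p + 6 :]
        score, is_telo = score_telomeric(seq)
        bf_score, bf_span = brute_force_best_chain(seq)
        assert score == bf_score
        if bf_score == 0:
            assert not is_telo


def test_half_coverage_rule():
    # 2 cores covering 12/40 bases: chain present but not telomeric
    seq = "GGTTACGGTTAC" + "ACGATCGATCGGATCAGCTAGCATCGAT"
    score, is_telo = score_telomeric(seq)
    assert score == 2 and not is_telo
    # the same chain over a short sequence is telomeric
    assert score_telomeric("GGTTACGGTTACAAAA") == (2, True)


# -------------------------------------------------------- microhomology

def test_microhomology_examples():
    # simulated-fusion-style clean junction: no shared sequence across it
    assert measure_microhomology("TTAGCCGG", "CCGGAATC") == 0
    # engineered 4-base junction overlap
    assert measure_microhomology("ACGGTT", "TTACGG") == 4   # suffix ACGG == prefix ACGG
    assert measure_microhomology("AAAA", "AAAA") == 4       # identical flanks of length w
    assert measure_microhomology("GATC", "CTAA") == 0


def test_microhomology_bruteforce_equivalence():
    rng = np.random.default_rng(12)
    for _ in range(200):
        a = "".join("ACGT"[j] for j in rng.integers(0, 4, int(rng.integers(1, 15))))
        b = "".join("ACGT"[j] for j in rng.integers(0, 4, int(rng.integers(1, 15))))
        expected = max([L for L in range(min(len(a), len(b)) + 1)
                        if b[len(b) - L:] == a[:L]], default=0)
        assert measure_microhomology(a, b) == expected


@given(st.text(alphabet="ACGT", min_size=1, max_size=20),
       st.text(alphabet="ACGT", min_size=1, max_size=20))
@settings(max_examples=200, deadline=None)
def test_microhomology_symmetric_under_role_swap(a, b):
    """Swapping the retained/partner roles while reorienting both flanks to
    the opposite junction-forming strand preserves the measured length."""
    assert measure_microhomology(a, b) == \
        measure_microhomology(revcomp(b), revcomp(a))


# ------------------------------------------------------------- clustering

def test_no_clips_gives_empty_list(plain_library):
    _, _, sam = plain_library
    assert cluster_soft_clips(sam) == []


def test_fusion_cluster_at_truth_junction(event_datasets):
    """Fusion reads produce one high-support cluster at the first retained
    base whose outward consensus realigns inside the rDNA unit."""
    ds = event_datasets["chromosome_fusion"]
    clusters = [c for c in cluster_soft_clips(ds.sam, min_mapq=1)
                if c.chrom == ds.truth.chrom]
    assert len(clusters) == 1
    c = clusters[0]
    assert c.junction == ds.truth.first_retained
    assert c.side == "left_clip"
    assert c.support >= 3
    # consensus (outward = toward the telomere-proximal rDNA side) must be
    # the reverse complement of the rDNA bases ending at the partner pos
    pchrom, pcoord, _ = ds.truth.partner
    pos = pcoord - 1
    expect = revcomp(ds.genome.chroms[pchrom][pos - len(c.consensus_clip) : pos])
    mismatches = sum(1 for x, y in zip(c.consensus_clip, expect) if x != y)
    assert mismatches <= 2  # consensus tolerates sequencing errors


def test_telomere_cluster_is_g_rich(event_datasets):
    ds = event_datasets["telomere_addition"]
    clusters = cluster_soft_clips(ds.sam, min_mapq=1)
    mine = [c for c in clusters if c.chrom == ds.truth.chrom]
    assert len(mine) == 1
    c = mine[0]
    assert c.junction == ds.truth.first_retained
    score, is_telo = score_telomeric(c.consensus_clip)
    assert is_telo and score >= 4


# ------------------------------------------------------------ realignment

def test_realign_exact_rdna_clip(toy_genome):
    rdna = toy_genome.feature("rdna_l")
    clip = toy_genome.fetch(rdna.chrom, rdna.start + 200, rdna.start + 260)
    hits, flags = realign_clip(clip, toy_genome)
    assert not flags
    top = hits[0]
    assert top.identity == 100.0 and top.length == 60
    # the rDNA unit tandem-repeats at both chrIII ends: all full-length hits
    # fall inside rDNA array features
    arrays = [toy_genome.feature("rdna_l"), toy_genome.feature("rdna_r")]
    full = [h for h in hits if h.length == 60]
    assert len(full) == 6  # 3 copies x 2 arrays
    for h in full:
        assert any(a.start <= h.start and h.end <= a.end for a in arrays)


def test_realign_reverse_complement_hits_minus_strand(toy_genome):
    locus = toy_genome.fetch("chrII", 70_000, 70_050)
    hits, _ = realign_clip(revcomp(locus), toy_genome)
    top = hits[0]
    assert (top.chrom, top.start, top.end, top.strand) == ("chrII", 70_000, 70_050, "-")


def test_realign_short_clip_flagged(toy_genome):
    hits, flags = realign_clip("ACGTACGT", toy_genome)
    assert hits == [] and flags == ["too_short"]


def test_telomeric_clip_realigns_only_to_telomere_tracts(toy_genome):
    """A de novo telomere clip has no genomic partner outside telomeric
    tracts (hits, if any, fall inside telomere_tract features)."""
    from gcrscope import make_telomere_tract
    tract = make_telomere_tract(np.random.default_rng(3), 60)
    hits, _ = realign_clip(tract, toy_genome, min_hit_len=15)
    tracts = [f for f in toy_genome.features if f.kind == "telomere_tract"]
    for h in hits:
        # mismatch-tolerant extension may run a few bases past a tract edge,
        # but every hit must be anchored in a tract
        overlap = max((min(h.end, t.end) - max(h.start, t.start)
                       for t in tracts if t.chrom == h.chrom), default=0)
        assert overlap >= h.length // 2, (h, "hit outside telomere tracts")
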