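"""Synthetic genome construction, rearrangement truth and read simulation."""

import numpy as np
import pytest

import gcrscope as g
from gcrscope import (ToyGenomeConfig, ReadSimConfig, build_toy_genome,
                      apply_rearrangement, simulate_reads, default_event,
                      revcomp, TELOMERE_CORE)
from gcrscope.simulate import lost_intervals

from conftest import small_config


# ------------------------------------------------------------ genome build

def test_p1_pair_shares_exactly_one_identical_block(toy_genome):
    """The same-orientation homologs share one exact internal block of the
    configured length and nothing longer (edges are discriminating)."""
    ia = toy_genome.feature("p1_ident_a")
    ib = toy_genome.feature("p1_ident_b")
    sa = toy_genome.fetch(ia.chrom, ia.start, ia.end)
    sb = toy_genome.fetch(ib.chrom, ib.start, ib.end)
    assert sa == sb and len(sa) == 240
    # extending by one base on either side breaks identity
    assert toy_genome.fetch(ia.chrom, ia.start - 1, ia.end) != \
        toy_genome.fetch(ib.chrom, ib.start - 1, ib.end)
    assert toy_genome.fetch(ia.chrom, ia.start, ia.end + 1) != \
        toy_genome.fetch(ib.chrom, ib.start, ib.end + 1)


def test_p2_pair_shares_reverse_complement_window(toy_genome):
    ia = toy_genome.feature("p2_ident_a")
    ib = toy_genome.feature("p2_ident_b")
    sa = toy_genome.fetch(ia.chrom, ia.start, ia.end)
    sb = toy_genome.fetch(ib.chrom, ib.start, ib.end)
    assert sa == revcomp(sb) and len(sa) == 12
    # junction cleanliness: discriminating bases flank the window
    c = toy_genome.chroms[ia.chrom]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    assert c[ia.end] != comp[c[ib.start - 1]]
    assert c[ia.start - 1] != comp[c[ib.end]]


def test_identical_region_length_is_configurable():
    cfg = small_config(seed=3)
    cfg.p1_identical_len = 100
    gen = build_toy_genome(cfg)
    ia, ib = gen.feature("p1_ident_a"), gen.feature("p1_ident_b")
    assert ia.end - ia.start == 100
    assert gen.fetch(ia.chrom, ia.start, ia.end) == \
        gen.fetch(ib.chrom, ib.start, ib.end)


def test_toy_genome_motifs(toy_genome):
    kinds = {f.kind for f in toy_genome.features}
    assert kinds == {"gene", "telomere_tract", "rdna_array",
                     "identical_region", "essential_gene"}
    # rDNA arrays are tandem copies of one unit at both ends of chrIII
    rl = toy_genome.feature("rdna_l")
    arr = toy_genome.fetch(rl.chrom, rl.start, rl.end)
    unit = (rl.end - rl.start) // 3
    assert arr == arr[:unit] * 3
    rr = toy_genome.feature("rdna_r")
    assert toy_genome.fetch(rr.chrom, rr.start, rr.end) == arr
    # telomeric tracts carry the core motif (G-rich on the right end)
    tr = toy_genome.feature("tel_chrI_R")
    tract = toy_genome.fetch(tr.chrom, tr.start, tr.end)
    assert tract.count(TELOMERE_CORE) >= 10
    tl = toy_genome.feature("tel_chrI_L")
    assert revcomp(toy_genome.fetch(tl.chrom, tl.start, tl.end)).count(TELOMERE_CORE) >= 10


def test_build_determinism(tmp_path):
    a, b = tmp_path / "a.fa", tmp_path / "b.fa"
    build_toy_genome(small_config(seed=9)).to_fasta(a)
    build_toy_genome(small_config(seed=9)).to_fasta(b)
    assert a.read_bytes() == b.read_bytes()


def test_bad_configs_rejected():
    cfg = small_config()
    cfg.chrom_sizes = (60_000, 100_000, 5_000)  # rDNA arrays cannot fit
    with pytest.raises(ValueError):
        build_toy_genome(cfg)
    cfg2 = small_config()
    cfg2.p1_identical_len = cfg2.gene_len  # identical region outside gene
    with pytest.raises(ValueError):
        build_toy_genome(cfg2)


# ---------------------------------------------------------- rearrangements

def test_telomere_addition_arithmetic(toy_genome):
    ev = default_event(toy_genome, "telomere_addition", seed=1)
    mutant, truth = apply_rearrangement(toy_genome, ev)
    ref = toy_genome.chroms["chrII"]
    mut = mutant.chroms["chrII"]
    telo = truth.telomere_seq
    assert len(mut) == (len(ref) - truth.first_retained + 1) + len(telo)
    assert mut.endswith(ref[truth.first_retained - 1 :])
    assert mut.startswith(revcomp(telo))


def test_fusion_junction_has_zero_microhomology(toy_genome):
    """Brute-force suffix/prefix scan at the fusion junction finds no exact
    overlap usable as microhomology, and no chance base lets an alignment
    extend across the junction."""
    ev = default_event(toy_genome, "chromosome_fusion", seed=1)
    mutant, truth = apply_rearrangement(toy_genome, ev)
    pchrom, pcoord, _ = truth.partner
    pos = pcoord - 1
    f0 = truth.first_retained - 1
    partner_flank = toy_genome.chroms[pchrom][pos - 20 : pos]
    retained_flank = toy_genome.chroms["chrII"][f0 : f0 + 20]
    overlap = max((L for L in range(21)
                   if partner_flank[-L:] == retained_flank[:L] or L == 0),
                  default=0)
    assert overlap == 0
    # junction bases in the mutant molecule
    mut = mutant.chroms["chrII"]
    assert mut[pos - 1] == toy_genome.chroms[pchrom][pos - 1]
    assert mut[pos] == toy_genome.chroms["chrII"][f0]
    assert toy_genome.chroms[pchrom][pos - 1] != toy_genome.chroms["chrII"][f0 - 1]
    assert toy_genome.chroms["chrII"][f0] != toy_genome.chroms[pchrom][pos]
    # the partner breakpoint stays inside the rDNA array
    rdna = toy_genome.feature("rdna_l")
    assert rdna.start < pos < rdna.end


def test_translocation_is_single_switch_chimera(toy_genome):
    """The mutant chromosome is donor-prefix + recipient-suffix switching
    source exactly once inside the identical region."""
    ev = default_event(toy_genome, "homology_translocation", seed=1)
    mutant, truth = apply_rearrangement(toy_genome, ev)
    mut = mutant.chroms["chrII"]
    chr1 = toy_genome.chroms["chrI"]
    chr2 = toy_genome.chroms["chrII"]
    pa = truth.partner[1] - 1
    hs = truth.homology_interval[0]
    assert mut == chr1[:pa] + chr2[hs:]
    # base-by-base against both parental genes: the chimera follows the
    # donor exactly up to the identical region's end and the recipient
    # exactly from its start, so the set of possible switch points is
    # exactly the identical region (switching source exactly once inside it)
    hxt_a, hxt_b = toy_genome.feature("hxtA"), toy_genome.feature("hxtB")
    gl = hxt_a.end - hxt_a.start
    gene_region = mut[hxt_a.start : hxt_a.start + gl]
    a_seq = chr1[hxt_a.start : hxt_a.end]
    b_seq = chr2[hxt_b.start : hxt_b.end]
    p = next(i for i in range(gl + 1)
             if i == gl or gene_region[i] != a_seq[i])
    s = next(i for i in range(gl + 1)
             if i == gl or gene_region[gl - 1 - i] != b_seq[gl - 1 - i])
    ident = toy_genome.feature("p1_ident_a")
    off = ident.start - hxt_a.start
    assert p == off + (ident.end - ident.start)   # donor match ends after the block
    assert gl - s == off                          # recipient match starts at the block
    assert p + s - gl == ident.end - ident.start  # ambiguity window == 240


def test_inversion_plus_deletion_geometry(toy_genome):
    ev = default_event(toy_genome, "inversion_plus_deletion", seed=1)
    mutant, truth = apply_rearrangement(toy_genome, ev)
    ref = toy_genome.chroms["chrII"]
    mut = mutant.chroms["chrII"]
    s1 = truth.homology_interval[0]
    s2e = toy_genome.feature("p2_ident_b").end
    f0 = truth.first_retained - 1
    telo = truth.telomere_seq
    assert mut == revcomp(telo) + revcomp(ref[s1 : f0 + 1]) + ref[s2e:]
    # first retained base lies inside the middle gene
    mid = toy_genome.feature("alrM")
    assert mid.start <= f0 < mid.end
    # lost reference intervals: terminal piece plus the interior piece
    lost = lost_intervals(toy_genome, truth)
    assert lost == [(0, s1), (f0 + 1, s2e)]


def test_essential_gene_protects_against_lethal_truncation(toy_genome):
    ess = toy_genome.feature("ess1")
    ev = g.RearrangementEvent("telomere_addition", "chrII",
                              first_retained=ess.end + 10,
                              telomere_seq=TELOMERE_CORE * 10)
    with pytest.raises(ValueError, match="essential"):
        apply_rearrangement(toy_genome, ev)


def test_event_record_invariants(toy_genome):
    with pytest.raises(ValueError):
        g.RearrangementEvent("telomere_addition", "chrII", 100,
                             partner=("chrI", 5, "+")).validate()
    with pytest.raises(ValueError):
        g.RearrangementEvent("homology_translocation", "chrII", 100,
                             partner=("chrI", 5, "+")).validate()  # no homology interval
    with pytest.raises(ValueError):
        g.RearrangementEvent("nonsense", "chrII", 100).validate()


# ------------------------------------------------------------------- reads

def test_error_free_reads_from_reference_are_exact(plain_library):
    genome, reads, _ = plain_library
    n_checked = 0
    for rd in reads.reads[:4000]:
        assert rd.ref_chrom is not None
        assert rd.left_clip == 0 and rd.right_clip == 0
        ref = genome.chroms[rd.ref_chrom]
        assert rd.stored_seq == ref[rd.ref_start : rd.ref_start + rd.match_len]
        n_checked += 1
    assert n_checked == 4000


def test_pair_count_matches_coverage_arithmetic(plain_library):
    genome, reads, _ = plain_library
    cfg = reads.config
    expected = round(cfg.coverage * genome.total_length / (2 * cfg.read_len))
    assert len(reads.reads) == 2 * expected


def test_mean_depth_near_target(plain_library):
    genome, reads, _ = plain_library
    total_bases = sum(rd.match_len for rd in reads.reads)
    mean_depth = total_bases / genome.total_length
    assert abs(mean_depth - reads.config.coverage) / reads.config.coverage < 0.15


def test_simulation_determinism(tmp_path, toy_genome):
    ev = default_event(toy_genome, "telomere_addition", seed=2)
    mutant, _ = apply_rearrangement(toy_genome, ev)
    cfg = ReadSimConfig(seed=33, coverage=5)
    for tag in ("x", "y"):
        rs = simulate_reads(mutant, cfg)
        rs.write_fastq(tmp_path / f"{tag}_1.fq", tmp_path / f"{tag}_2.fq")
        rs.write_sam(tmp_path / f"{tag}.sam")
    assert (tmp_path / "x_1.fq").read_bytes() == (tmp_path / "y_1.fq").read_bytes()
    assert (tmp_path / "x_2.fq").read_bytes() == (tmp_path / "y_2.fq").read_bytes()
    assert (tmp_path / "x.sam").read_bytes() == (tmp_path / "y.sam").read_bytes()


def test_junction_reads_clip_the_appended_telomere(toy_genome):
    """Error-free reads spanning a telomere-addition junction soft-clip
    exactly the appended repeat bases (reconstructed from fragment
    coordinates), and matched+clipped parts reproduce the mutant fragment."""
    ev = default_event(toy_genome, "telomere_addition", seed=4)
    mutant, truth = apply_rearrangement(toy_genome, ev)
    rs = simulate_reads(mutant, ReadSimConfig(seed=5, error_rate=0.0))
    telo_rc = revcomp(truth.telomere_seq)
    tlen = len(telo_rc)
    mut = mutant.chroms["chrII"]
    crossing = [rd for rd in rs.reads
                if rd.m_chrom == "chrII" and rd.m0 < tlen < rd.m1
                and rd.ref_chrom is not None]
    assert crossing, "no junction-spanning reads simulated"
    for rd in crossing:
        clip = rd.left_clip if not rd.sam_reverse else rd.right_clip
        assert clip == tlen - rd.m0
        # conservation: clipped + matched parts reproduce the fragment
        frag = mut[rd.m0 : rd.m1]
        assert rd.stored_seq == frag
        assert rd.ref_start == truth.first_retained - 1
        # clipped bases are exactly the tract suffix
        assert frag[: tlen - rd.m0] == telo_rc[rd.m0 :]


def test_read_config_validation():
    with pytest.raises(ValueError):
        ReadSimConfig(read_len=300, insert_mean=200).validate()
    with pytest.raises(ValueError):
        ReadSimConfig(error_rate=0.2).validate()
    with pytest.raises(ValueError):
        ReadSimConfig(coverage=0).validate()
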