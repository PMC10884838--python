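"""Mechanism classification, reports and full-pipeline behaviour."""

import json
import random

import pytest

import gcrscope as g
from gcrscope import (classify, codon_span_length_nt, permissive_junction_span,
                      write_reports, run_pipeline)
from gcrscope.classify import EvidenceBundle
from gcrscope.simulate import lost_intervals

from conftest import EXPECTED_MECHANISM, SMALL_SIZES


def test_codon_span_arithmetic():
    """An identical region spanning codons 286-365 is 240 nt long."""
    assert codon_span_length_nt(286, 365) == 240
    assert codon_span_length_nt(1, 1) == 3
    with pytest.raises(ValueError):
        codon_span_length_nt(10, 9)


def test_permissive_junction_window_arithmetic():
    """71 kb to the nearest essential gene minus a 5 kb silencing buffer
    leaves a ~66 kb window for viable junctions."""
    assert permissive_junction_span(71_000, 5_000) == 66_000
    with pytest.raises(ValueError):
        permissive_junction_span(4_000, 5_000)


# ------------------------------------------------------------- end to end

def test_mechanisms_and_junctions_recovered(analyzed, event_datasets):
    """Simulate-then-analyze recovers the truth mechanism and the exact
    junction for all four event types; homology-event junctions fall at the
    declared edge of (hence inside) the truth identical interval."""
    for et, (bundle, profile, calls) in analyzed.items():
        truth = event_datasets[et].truth
        assert len(calls) == 1, (et, calls)
        c = calls[0]
        assert c.mechanism == EXPECTED_MECHANISM[et]
        assert c.junction == truth.first_retained
        if truth.homology_interval is not None and \
                truth.event_type == "homology_translocation":
            lo, hi = truth.homology_interval
            assert lo <= c.junction - 1 < hi


def test_every_deletion_gets_exactly_one_call(analyzed):
    for et, (bundle, _, calls) in analyzed.items():
        dels = [c for c in bundle.cnv_calls if c.kind == "deletion"]
        assert len(calls) == len(dels) == 1


def test_junction_agrees_with_depth_boundary(analyzed):
    """For simple mechanisms the junction lies within one bin of the depth
    boundary; for the complex event it is linked through the inversion."""
    for et, (bundle, _, calls) in analyzed.items():
        c = calls[0]
        cnv = next(x for x in bundle.cnv_calls
                   if x.kind == "deletion" and x.chrom == c.chrom)
        if et != "inversion_plus_deletion":
            assert abs(c.junction - cnv.boundary) <= 200
        else:
            assert any(e.startswith("group:") for e in c.evidence_ids)


def test_partner_loci(analyzed, event_datasets):
    fusion = analyzed["chromosome_fusion"][2][0]
    genome = event_datasets["chromosome_fusion"].genome
    rdna = [genome.feature("rdna_l"), genome.feature("rdna_r")]
    pc, pp = fusion.partner
    assert any(f.chrom == pc and f.start < pp <= f.end for f in rdna)
    trans = analyzed["homology_translocation"][2][0]
    truth = event_datasets["homology_translocation"].truth
    assert trans.partner == (truth.partner[0], truth.partner[1])


def test_translocation_cites_duplication_and_chimera(analyzed):
    bundle, _, calls = analyzed["homology_translocation"]
    dup = [c for c in bundle.cnv_calls if c.kind == "duplication"]
    assert dup and dup[0].chrom == "chrI"
    assert 1.7 < dup[0].mean_ratio < 2.3
    c = calls[0]
    assert any(e.startswith("chimera:") for e in c.evidence_ids)


def test_silencing_annotation_near_new_telomere(analyzed, event_datasets):
    """A retained gene within 5 kb of a de novo telomere is flagged as a
    silencing candidate (no expression claim)."""
    _, _, calls = analyzed["inversion_plus_deletion"]
    notes = calls[0].notes
    assert any(n.startswith("near_new_telomere:") for n in notes)


def test_classification_order_independent(analyzed):
    rng = random.Random(0)
    for et, (bundle, _, calls) in analyzed.items():
        shuffled = EvidenceBundle(
            cnv_calls=rng.sample(bundle.cnv_calls, len(bundle.cnv_calls)),
            clusters=rng.sample(bundle.clusters, len(bundle.clusters)),
            groups=rng.sample(bundle.groups, len(bundle.groups)),
            chimeras=rng.sample(bundle.chimeras, len(bundle.chimeras)),
            homology=rng.sample(bundle.homology, len(bundle.homology)))
        feats = None
        redo = classify(shuffled)
        orig = classify(bundle)
        key = lambda cs: [(c.chrom, c.side, c.mechanism, c.junction, c.partner)
                          for c in cs]
        assert key(redo) == key(orig)


def test_classify_requires_a_deletion():
    with pytest.raises(ValueError):
        classify(EvidenceBundle())


# ---------------------------------------------------------------- reports

def test_write_reports_empty_calls(tmp_path):
    paths = write_reports([], EvidenceBundle(), tmp_path / "out")
    tsv = paths["tsv"].read_text().splitlines()
    assert tsv[0].startswith("chrom\t") and len(tsv) == 1
    vcf = [l for l in paths["vcf"].read_text().splitlines()
           if not l.startswith("##")]
    assert vcf == ["#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]


def test_vcf_del_record_contract(analyzed, event_datasets, tmp_path):
    bundle, profile, calls = analyzed["telomere_addition"]
    genome = event_datasets["telomere_addition"].genome
    paths = write_reports(calls, bundle, tmp_path / "o", genome=genome,
                          profile=profile)
    recs = [l for l in paths["vcf"].read_text().splitlines()
            if not l.startswith("#")]
    assert len(recs) == 1
    chrom, pos, _, _, alt, _, _, info = recs[0].split("\t")
    assert alt == "<DEL>"
    assert f"END={calls[0].junction - 1}" in info
    assert "MECH=telomere_addition" in info
    # depth tables emitted per chromosome
    assert any(k.startswith("depth_") for k in paths)


def test_unwritable_outdir_errors(analyzed, tmp_path):
    bundle, profile, calls = analyzed["telomere_addition"]
    blocked = tmp_path / "f"
    blocked.write_text("")
    with pytest.raises((ValueError, OSError)):
        write_reports(calls, bundle, blocked / "sub")


# --------------------------------------------------------------- pipeline

def _sim_config(tmp_path, seed=400):
    return {
        "simulate": {"event_type": "telomere_addition", "seed": seed,
                     "genome": {"seed": seed, "chrom_sizes": list(SMALL_SIZES),
                                "essential_gap": 20_000},
                     "reads": {"seed": seed + 1, "coverage": 25.0}},
        "outdir": str(tmp_path / "out"),
    }


def test_run_pipeline_round_trip_and_determinism(tmp_path):
    cfg = _sim_config(tmp_path)
    res1 = run_pipeline(cfg)
    assert [c.mechanism for c in res1.calls] == ["de_novo_telomere_addition"]
    assert res1.calls[0].junction == res1.truth[0].first_retained
    first = {p.name: p.read_bytes() for p in (tmp_path / "out").iterdir()}
    res2 = run_pipeline(cfg)
    second = {p.name: p.read_bytes() for p in (tmp_path / "out").iterdir()}
    assert first == second  # byte-identical reports on rerun


def test_run_pipeline_yaml_and_missing_inputs(tmp_path):
    import yaml
    bad = {"inputs": {"reference_fasta": "x.fa"}, "outdir": str(tmp_path)}
    with pytest.raises(ValueError, match="alignments"):
        run_pipeline(bad)
    with pytest.raises(ValueError, match="simulate"):
        run_pipeline({"outdir": str(tmp_path)})
    p = tmp_path / "cfg.yaml"
    p.write_text(yaml.safe_dump(bad))
    with pytest.raises(ValueError, match="alignments"):
        run_pipeline(p)


def test_truth_events_recoverable_property(event_datasets):
    """Sanity link between simulator truth and depth-visible loss: the lost
    reference intervals never include the essential gene."""
    for et, ds in event_datasets.items():
        ess = ds.genome.feature("ess1")
        for a, b in lost_intervals(ds.genome, ds.truth):
            assert not (a < ess.end and ess.start < b)
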