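"""Mechanism classification of terminal deletions and pipeline orchestration.

Every terminal-deletion depth call is explained by exactly one mechanism
call, decided from junction-level evidence in a fixed order: a telomeric
clip consensus means de novo telomere addition (upgraded to a complex
inversion-plus-deletion when an inversion signal and a homology-narrowed
inversion breakpoint sit centromeric of the junction on the same arm); a
clip realigning to another chromosome's duplicated terminal region with
chimera support means a homology-driven unbalanced translocation; a clip
realigning elsewhere with at most ``microhom_max`` bases of junction
microhomology and no duplication at the partner means a homology-independent
chromosome fusion; anything else is unresolved. Telomeric clips are checked
first because they would otherwise realign to telomeric tracts and
masquerade as fusions.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .genome import Genome, Feature, revcomp
from .mappability import (compute_mappability, extract_unique_regions,
                          write_regions_bed)
from .depth import (DepthProfile, TerminalCnvCall, windowed_depth,
                    call_terminal_cnv, write_cnv_tsv)
from .junctions import (SoftClipCluster, ClipCharacterization,
                        cluster_soft_clips, score_telomeric, realign_clip,
                        measure_microhomology, write_cluster_tsv)
from .pairs import (DiscordantGroup, ChimeraSupport, HomologyInterval,
                    find_discordant_pairs, collect_chimera_support,
                    narrow_breakpoint_interval)
from . import simulate as sim

logger = logging.getLogger(__name__)

MECHANISMS = ("homology_driven_translocation", "homology_independent_fusion",
              "de_novo_telomere_addition", "complex_inversion_plus_deletion",
              "unresolved")


# ------------------------------------------------------- printed arithmetic

def codon_span_length_nt(first_codon: int, last_codon: int) -> int:
    """Nucleotide length of an inclusive codon span (codons 286-365 -> 240 nt)."""
    if last_codon < first_codon or first_codon < 1:
        raise ValueError("need 1 <= first_codon <= last_codon")
    return (last_codon - first_codon + 1) * 3


def permissive_junction_span(distance_to_essential_bp: int,
                             silencing_buffer_bp: int) -> int:
    """Span of positions where a viable terminal-deletion junction may fall:
    the distance from the last dispensable locus to the nearest essential
    gene, minus the telomeric-silencing buffer that must separate the new
    telomere from it (71 kb - 5 kb -> ~66 kb)."""
    if silencing_buffer_bp > distance_to_essential_bp:
        raise ValueError("buffer exceeds the available distance")
    return distance_to_essential_bp - silencing_buffer_bp


# ---------------------------------------------------------------- evidence

@dataclass
class EvidenceBundle:
    cnv_calls: list[TerminalCnvCall] = field(default_factory=list)
    clusters: list[tuple[SoftClipCluster, ClipCharacterization]] = field(default_factory=list)
    groups: list[DiscordantGroup] = field(default_factory=list)
    chimeras: list[ChimeraSupport] = field(default_factory=list)
    homology: list[HomologyInterval] = field(default_factory=list)


@dataclass
class MechanismCall:
    chrom: str
    side: str
    mechanism: str
    junction: int                      # 1-based first retained base
    partner: tuple[str, int] | None
    confidence: str                    # high | low
    evidence_ids: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def characterize_cluster(cluster: SoftClipCluster, genome: Genome,
                         flank: int = 20, min_telo_copies: int = 2,
                         ) -> ClipCharacterization:
    """Telomere content, realignment partners and junction microhomology of
    one soft-clip cluster consensus."""
    score, is_telo = score_telomeric(cluster.consensus_clip,
                                     min_copies=min_telo_copies)
    hits, flags = realign_clip(cluster.consensus_clip, genome)
    seq = genome.chroms[cluster.chrom]
    j = cluster.junction  # 1-based
    w = min(flank, len(cluster.consensus_clip))
    # partner flank in joined-molecule orientation, ending at the junction;
    # retained flank starting at the junction (reverse strand for right clips)
    partner_flank = revcomp(cluster.consensus_clip[:w])
    if cluster.side == "left_clip":
        retained_flank = seq[j - 1 : j - 1 + flank]
    else:
        retained_flank = revcomp(seq[max(0, j - flank) : j])
    micro = measure_microhomology(retained_flank, partner_flank)
    return ClipCharacterization(telomere_score=score, is_telomeric=is_telo,
                                partner_hits=hits, microhomology_len=micro,
                                flags=flags)


# ------------------------------------------------------------ classification

def _dup_covers(cnv_calls, chrom, pos0, slack: int = 200) -> bool:
    """Is 0-based position pos0 inside (or within ``slack`` bp of) a called
    terminal duplication? Slack absorbs the window-quantised boundary: a
    homology switch point sits exactly at the duplication's inner edge."""
    for c in cnv_calls:
        if c.kind != "duplication" or c.chrom != chrom:
            continue
        if c.side == "left" and pos0 < c.boundary + slack:
            return True
        if c.side == "right" and pos0 >= c.boundary - 1 - slack:
            return True
    return False


def classify(bundle: EvidenceBundle, features: list[Feature] | None = None,
             bin: int = 200, min_support: int = 3, microhom_max: int = 1,
             telo_reach: int = 25_000) -> list[MechanismCall]:
    """One MechanismCall per terminal-deletion depth call (see module doc).

    Output is invariant under permutation of the evidence lists: candidate
    selection always sorts deterministically.
    """
    deletions = sorted((c for c in bundle.cnv_calls if c.kind == "deletion"),
                       key=lambda c: (c.chrom, c.side))
    if not deletions:
        raise ValueError("bundle contains no terminal deletion call")
    calls = []
    for cnv in deletions:
        calls.append(_classify_one(cnv, bundle, features or [], bin,
                                   min_support, microhom_max, telo_reach))
    return calls


def _arm_distance(cnv: TerminalCnvCall, junction: int) -> int:
    """Signed distance from the depth boundary toward the centromere."""
    return (junction - cnv.boundary) if cnv.side == "left" else (cnv.boundary - junction)


def _near_boundary(cnv: TerminalCnvCall, junction: int, bin: int) -> bool:
    """Is the junction consistent with the depth transition? The true
    junction may fall anywhere in the masked gap between the aberrant run's
    inner edge and the boundary window, widened by one bin on each side."""
    inner = cnv.inner_edge or cnv.boundary
    lo, hi = sorted((inner, cnv.boundary))
    return lo - bin <= junction <= hi + bin


def _classify_one(cnv, bundle, features, bin, min_support, microhom_max,
                  telo_reach) -> MechanismCall:
    idx = {id(c): i for i, (c, _) in enumerate(bundle.clusters)}
    on_arm = sorted(
        ((c, ch) for (c, ch) in bundle.clusters
         if c.chrom == cnv.chrom and -bin <= _arm_distance(cnv, c.junction) <= telo_reach),
        key=lambda t: (abs(_arm_distance(cnv, t[0].junction)), t[0].junction))
    near = [t for t in on_arm if _near_boundary(cnv, t[0].junction, bin)]
    ev = [f"cnv:{cnv.chrom}:{cnv.side}"]
    notes: list[str] = []

    telo = sorted((t for t in on_arm if t[1].is_telomeric),
                  key=lambda t: abs(_arm_distance(cnv, t[0].junction)))
    if telo:
        cl, ch = telo[0]
        ev.append(f"cluster:{idx[id(cl)]}")
        mech = "de_novo_telomere_addition"
        linked = False
        inv_groups = [g for g in bundle.groups
                      if g.kind.startswith("inversion")
                      and g.locusA[0] == cnv.chrom]
        hom_centromeric = [
            h for h in bundle.homology
            if h.inverted and h.genomic_b is not None
            and h.genomic_b[0] == cnv.chrom
            and _arm_distance(cnv, h.genomic_b[1] + 1) > _arm_distance(cnv, cl.junction)]
        if inv_groups and hom_centromeric:
            mech = "complex_inversion_plus_deletion"
            linked = True
            ev.append(f"group:{bundle.groups.index(inv_groups[0])}")
            ev.append(f"homology:{bundle.homology.index(hom_centromeric[0])}")
        agree = _near_boundary(cnv, cl.junction, bin) or linked
        conf = "high" if (cl.support >= 2 * min_support and agree) else "low"
        notes.extend(_telomere_notes(cl.junction, cnv, features))
        return MechanismCall(cnv.chrom, cnv.side, mech, cl.junction, None,
                             conf, ev, notes)

    for cl, ch in near:
        if not ch.partner_hits:
            continue
        hit = ch.partner_hits[0]
        ev2 = ev + [f"cluster:{idx[id(cl)]}"]
        dup = _dup_covers(bundle.cnv_calls, hit.chrom, hit.start)
        chim = [c for c in bundle.chimeras if c.informative >= 1]
        if hit.chrom != cnv.chrom and dup and chim:
            ev2.append(f"chimera:{bundle.chimeras.index(chim[0])}")
            conf = "high" if cl.support >= 2 * min_support else "low"
            return MechanismCall(cnv.chrom, cnv.side,
                                 "homology_driven_translocation", cl.junction,
                                 (hit.chrom, hit.start + 1), conf, ev2, notes)
        if ch.microhomology_len <= microhom_max and not dup:
            conf = "high" if cl.support >= 2 * min_support else "low"
            n = list(notes)
            n.append("fusion_note: a fusion joining two centromere-bearing "
                     "chromosomes would be dicentric; its subsequent fate "
                     "(breakage or centromere inactivation) is not inferred")
            return MechanismCall(cnv.chrom, cnv.side,
                                 "homology_independent_fusion", cl.junction,
                                 (hit.chrom, hit.start + 1), conf, ev2, n)

    # Clip-free homology-driven translocation: an identical region longer
    # than the read length yields no junction soft clips (no read can span
    # it), so the junction rests on chimera pairs, the partner duplication
    # and the homology interval; the junction is reported at the interval's
    # telomere-facing edge on the deleted chromosome.
    call = _clipfree_translocation(cnv, bundle, features, bin, min_support, ev, notes)
    if call is not None:
        return call
    return MechanismCall(cnv.chrom, cnv.side, "unresolved", cnv.boundary,
                         None, "low", ev, notes)


def _gene_chrom(features, name) -> str | None:
    for f in features:
        if f.name == name and f.kind == "gene":
            return f.chrom
    return None


def _clipfree_translocation(cnv, bundle, features, bin, min_support, ev,
                            notes) -> MechanismCall | None:
    for hi in bundle.homology:
        if hi.genomic_a is None or hi.genomic_b is None:
            continue
        for site, partner in ((hi.genomic_a, hi.genomic_b),
                              (hi.genomic_b, hi.genomic_a)):
            if site[0] != cnv.chrom or partner[0] == cnv.chrom:
                continue
            junction = site[1] + 1 if cnv.side == "left" else site[2]
            if not _near_boundary(cnv, junction, bin):
                continue
            if not _dup_covers(bundle.cnv_calls, partner[0], partner[1]):
                continue
            chims = [c for c in bundle.chimeras if c.informative >= 1
                     and {_gene_chrom(features, c.geneA),
                          _gene_chrom(features, c.geneB)} == {site[0], partner[0]}]
            if not chims:
                continue
            chim = chims[0]
            ev2 = ev + [f"homology:{bundle.homology.index(hi)}",
                        f"chimera:{bundle.chimeras.index(chim)}"]
            for gi, g in enumerate(bundle.groups):
                if g.kind == "inter_chromosomal" and \
                        {g.locusA[0], g.locusB[0]} == {site[0], partner[0]}:
                    ev2.append(f"group:{gi}")
                    break
            conf = "high" if chim.informative >= 2 * min_support else "low"
            return MechanismCall(cnv.chrom, cnv.side,
                                 "homology_driven_translocation", int(junction),
                                 (partner[0], int(partner[1]) + 1), conf, ev2,
                                 list(notes))
    return None


def _telomere_notes(junction, cnv, features) -> list[str]:
    """Flag retained genes within 5 kb of a de novo telomere (candidate
    telomeric silencing; no expression claim)."""
    out = []
    for f in features:
        if f.kind != "gene" or f.chrom != cnv.chrom:
            continue
        if cnv.side == "left":
            retained = f.end > junction - 1
            dist = f.start - (junction - 1)
        else:
            retained = f.start < junction
            dist = junction - f.end
        if retained and dist < 5000:
            out.append(f"near_new_telomere:{f.name}")
    return out


# ----------------------------------------------------------------- reports

def _jsonable(obj):
    import numpy as np
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_reports(calls: list[MechanismCall], bundle: EvidenceBundle, outdir,
                  genome: Genome | None = None,
                  profile: DepthProfile | None = None) -> dict[str, Path]:
    """TSV summary, JSON evidence, minimal VCF and per-chromosome depth
    tables. Returns the paths written."""
    import json
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ValueError(f"output directory not writable: {outdir}") from exc
    paths = {}

    tsv = outdir / "mechanism_calls.tsv"
    rows = [{"chrom": c.chrom, "side": c.side, "mechanism": c.mechanism,
             "junction": c.junction,
             "partner": f"{c.partner[0]}:{c.partner[1]}" if c.partner else ".",
             "confidence": c.confidence,
             "evidence": ",".join(c.evidence_ids),
             "notes": ";".join(c.notes) if c.notes else "."}
            for c in calls]
    pd.DataFrame(rows, columns=["chrom", "side", "mechanism", "junction",
                                "partner", "confidence", "evidence", "notes"]
                 ).to_csv(tsv, sep="\t", index=False)
    paths["tsv"] = tsv

    js = outdir / "evidence.json"
    payload = {
        "calls": [asdict(c) for c in calls],
        "cnv_calls": [asdict(c) for c in bundle.cnv_calls],
        "clusters": [{"cluster": asdict(cl), "characterization": asdict(ch)}
                     for cl, ch in bundle.clusters],
        "groups": [asdict(g) for g in bundle.groups],
        "chimeras": [asdict(c) for c in bundle.chimeras],
        "homology": [asdict(h) for h in bundle.homology],
    }
    js.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")
    paths["json"] = js

    vcf = outdir / "calls.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="Deletion end">\n')
        fh.write('##INFO=<ID=MECH,Number=1,Type=String,Description="Deletion mechanism">\n')
        if genome is not None:
            for name, seq in genome.chroms.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls):
            mech = c.mechanism.replace("de_novo_", "").replace("complex_", "")
            if c.mechanism in ("de_novo_telomere_addition",
                               "complex_inversion_plus_deletion", "unresolved"):
                pos = 1 if c.side == "left" else c.junction
                end = c.junction - 1 if c.side == "left" else \
                    (len(genome.chroms[c.chrom]) if genome else c.junction)
                ref = genome.chroms[c.chrom][pos - 1] if genome else "N"
                fh.write(f"{c.chrom}\t{pos}\tDEL{i}\t{ref}\t<DEL>\t.\tPASS\t"
                         f"SVTYPE=DEL;END={end};MECH={mech}\n")
            else:
                pch, ppos = c.partner
                ref = genome.chroms[c.chrom][c.junction - 1] if genome else "N"
                alt = f"]{pch}:{ppos}]{ref}"
                fh.write(f"{c.chrom}\t{c.junction}\tBND{i}\t{ref}\t{alt}\t.\t"
                         f"PASS\tSVTYPE=BND;MECH={mech}\n")
    paths["vcf"] = vcf

    if profile is not None:
        for chrom, sub in profile.windows.groupby("chrom", sort=False):
            p = outdir / f"depth_{chrom}.tsv"
            sub[["start", "end", "normalized_depth"]].to_csv(p, sep="\t", index=False)
            paths[f"depth_{chrom}"] = p
    return paths


# ----------------------------------------------------------------- pipeline

@dataclass
class PipelineResult:
    calls: list[MechanismCall]
    bundle: EvidenceBundle
    profile: DepthProfile
    genome: Genome
    truth: list[sim.RearrangementEvent] = field(default_factory=list)
    outputs: dict[str, Path] = field(default_factory=dict)


def _paired_identical_regions(features: list[Feature]) -> list[tuple[Feature, Feature]]:
    """Identical-region features paired by shared name prefix: '<name>_a'
    with '<name>_b'."""
    idents = {f.name: f for f in features if f.kind == "identical_region"}
    pairs = []
    for name, fa in sorted(idents.items()):
        if name.endswith("_a") and name[:-2] + "_b" in idents:
            pairs.append((fa, idents[name[:-2] + "_b"]))
    return pairs


def _gene_containing(features, ident: Feature) -> Feature | None:
    for f in features:
        if f.kind == "gene" and f.chrom == ident.chrom \
                and f.start <= ident.start and ident.end <= f.end:
            return f
    return None


def _narrowed_interval(genome: Genome, features, ident_a: Feature,
                       ident_b: Feature) -> HomologyInterval | None:
    """Narrow the breakpoint interval by aligning the two homologs carrying
    an annotated identical region, then lift the run back to the genome."""
    ga = _gene_containing(features, ident_a)
    gb = _gene_containing(features, ident_b)
    if ga is None or gb is None:
        return None
    inverted = ga.strand != gb.strand
    seq_a = genome.fetch(ga.chrom, ga.start, ga.end)
    if ga.strand == "-":
        seq_a = revcomp(seq_a)
    seq_b = genome.fetch(gb.chrom, gb.start, gb.end)
    # chimera-forming orientation: orient B like A
    flip_b = inverted
    if ga.strand == "-":
        seq_b_oriented = revcomp(seq_b) if gb.strand == "+" else seq_b
    else:
        seq_b_oriented = revcomp(seq_b) if gb.strand == "-" else seq_b
    # switch coordinate on oriented A
    if ga.strand == "+":
        approx = ident_a.start - ga.start
    else:
        approx = ga.end - ident_a.end
    hi = narrow_breakpoint_interval(seq_a, seq_b_oriented, approx)
    if not hi.is_exact:
        return None
    a0, a1 = hi.seqA_range
    b0, b1 = hi.seqB_range
    if ga.strand == "+":
        genomic_a = (ga.chrom, int(ga.start + a0), int(ga.start + a1))
    else:
        genomic_a = (ga.chrom, int(ga.end - a1), int(ga.end - a0))
    # oriented-B index maps forward onto gb when B was not flipped relative
    # to its own strand
    if (gb.strand == "+" and not flip_b) or (gb.strand == "-" and flip_b and ga.strand == "-"):
        genomic_b = (gb.chrom, int(gb.start + b0), int(gb.start + b1))
    else:
        genomic_b = (gb.chrom, int(gb.end - b1), int(gb.end - b0))
    hi.genomic_a = genomic_a
    hi.genomic_b = genomic_b
    hi.inverted = inverted
    return hi


def analyze(genome: Genome, alignments, k: int = 100, m: int = 2,
            min_region_len: int = 1000, bin: int = 200,
            del_ratio_max: float = 0.25, dup_ratio_min: float = 1.5,
            min_windows: int = 10, min_clip: int = 10, min_support: int = 3,
            insert_mean: float | None = None, insert_sd: float | None = None,
            microhom_max: int = 1) -> tuple[EvidenceBundle, DepthProfile, list[MechanismCall]]:
    """Run the evidence stages (mappability -> depth -> CNV -> junctions ->
    pairs/chimeras -> homology) and classify. ``alignments`` is a SAM/BAM
    path mapped against ``genome``."""
    logger.info("mappability: k=%d m=%d", k, m)
    track = compute_mappability(genome, k=k, m=m)
    regions = extract_unique_regions(track, min_len=min_region_len)
    logger.info("unique regions: %d", len(regions))
    chrom_lengths = {n: len(s) for n, s in genome.chroms.items()}
    profile = windowed_depth(alignments, regions, bin=bin,
                             chrom_lengths=chrom_lengths)
    cnv = call_terminal_cnv(profile, del_ratio_max=del_ratio_max,
                            dup_ratio_min=dup_ratio_min,
                            min_windows=min_windows)
    logger.info("terminal CNV calls: %s", [(c.chrom, c.side, c.kind) for c in cnv])
    clusters = cluster_soft_clips(alignments, min_clip=min_clip,
                                  min_support=min_support)
    boundaries = [(c.chrom, c.boundary) for c in cnv]
    charac = []
    for cl in clusters:
        # characterize clusters on chromosomes with a terminal CNV call
        if any(cl.chrom == ch for ch, _ in boundaries) or not boundaries:
            charac.append((cl, characterize_cluster(cl, genome)))
    groups = find_discordant_pairs(alignments, insert_mean=insert_mean,
                                   insert_sd=insert_sd,
                                   min_pairs=min_support)
    chimeras = []
    homology = []
    feats = genome.features
    for ident_a, ident_b in _paired_identical_regions(feats):
        hi = _narrowed_interval(genome, feats, ident_a, ident_b)
        if hi is None:
            continue
        homology.append(hi)
        ga = _gene_containing(feats, ident_a)
        gb = _gene_containing(feats, ident_b)
        try:
            chim = collect_chimera_support(alignments, ga, gb, hi,
                                           insert_mean=insert_mean,
                                           insert_sd=insert_sd)
        except ValueError:
            continue
        if chim.support:
            chimeras.append(chim)
    bundle = EvidenceBundle(cnv_calls=cnv, clusters=charac, groups=groups,
                            chimeras=chimeras, homology=homology)
    deletions = [c for c in cnv if c.kind == "deletion"]
    calls = classify(bundle, features=feats, bin=bin,
                     min_support=min_support,
                     microhom_max=microhom_max) if deletions else []
    return bundle, profile, calls


def simulate_cohort_files(outdir: Path, event_type: str, seed: int,
                          genome_cfg: sim.ToyGenomeConfig | None = None,
                          read_cfg: sim.ReadSimConfig | None = None,
                          ) -> tuple[Genome, sim.RearrangementEvent, Path]:
    """Build a toy genome, apply one event, simulate reads; write FASTA, BED,
    FASTQ, truth SAM and truth JSON under ``outdir``. Returns (reference,
    truth event, truth SAM path)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gcfg = genome_cfg or sim.ToyGenomeConfig(seed=seed)
    rcfg = read_cfg or sim.ReadSimConfig(seed=seed + 1)
    genome = sim.build_toy_genome(gcfg)
    event = sim.default_event(genome, event_type, seed=seed + 2)
    mutant, truth = sim.apply_rearrangement(genome, event)
    reads = sim.simulate_reads(mutant, rcfg)
    genome.to_fasta(outdir / "reference.fa")
    mutant.as_genome().to_fasta(outdir / "mutant.fa")
    genome.features_to_bed(outdir / "features.bed")
    reads.write_fastq(outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
    sam = outdir / "truth.sam"
    reads.write_sam(sam)
    sim.write_truth_json([truth], outdir / "truth_events.json")
    return genome, truth, sam


def run_pipeline(config) -> PipelineResult:
    """Execute the full pipeline from a config mapping or YAML path.

    The config either requests a simulation (``simulate:``) or names real
    inputs (``inputs: {reference_fasta, features_bed, alignments}``); stage
    parameters live under ``params:``; reports go to ``outdir``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    params = dict(config.get("params", {}))
    outdir = Path(config.get("outdir", "gcrscope_out"))
    truth: list[sim.RearrangementEvent] = []

    if "simulate" in config:
        s = config["simulate"]
        with tempfile.TemporaryDirectory() as td:
            workdir = Path(s.get("workdir", td))
            workdir.mkdir(parents=True, exist_ok=True)
            gcfg = sim.ToyGenomeConfig(**s.get("genome", {}))
            rcfg = sim.ReadSimConfig(**s.get("reads", {}))
            genome, tr, sam = simulate_cohort_files(
                workdir, s["event_type"], int(s.get("seed", 0)),
                genome_cfg=gcfg, read_cfg=rcfg)
            truth = [tr]
            bundle, profile, calls = analyze(genome, sam, **params)
    elif "inputs" in config:
        inp = config["inputs"]
        for key in ("reference_fasta", "alignments"):
            if key not in inp:
                raise ValueError(f"config missing required input: {key}")
        genome = Genome.from_fasta(inp["reference_fasta"],
                                   bed_path=inp.get("features_bed"))
        bundle, profile, calls = analyze(genome, inp["alignments"], **params)
    else:
        raise ValueError("config must provide either 'simulate' or 'inputs'")

    outputs = write_reports(calls, bundle, outdir, genome=genome,
                            profile=profile)
    write_cnv_tsv(bundle.cnv_calls, outdir / "terminal_cnv.tsv")
    write_cluster_tsv(bundle.clusters, outdir / "junction_clusters.tsv")
    if truth:
        sim.write_truth_json(truth, outdir / "truth_events.json")
    logger.info("mechanisms: %s", [(c.chrom, c.mechanism, c.junction) for c in calls])
    return PipelineResult(calls=calls, bundle=bundle, profile=profile,
                          genome=genome, truth=truth, outputs=outputs)
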