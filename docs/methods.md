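# Methods

## Model and assumptions

gcrscope infers chromosome terminal deletions and their healing mechanisms
from paired-end short-read alignments against a reference genome. The
underlying model is a haploid genome in which a single gross rearrangement
has removed one chromosome arm's terminal segment and stabilised the break
by one of four routes: de novo telomere addition, homology-driven
unbalanced translocation, homology-independent chromosome fusion, or an
inversion between inverted-repeat homologs followed by telomere addition.
Evidence layers are deliberately orthogonal: copy number (windowed depth
over uniquely mappable sequence), split reads (soft-clip clusters), read
pairs (orientation/insert anomalies and chimera-consistent pairs), and
sequence (clip realignment, telomere-repeat content, microhomology,
homolog alignment). Assumptions: substitution-dominated sequencing error;
alignments that retain soft clips; a reference that actually contains the
partner loci (telomeric tracts, rDNA arrays, both homologs).

Coordinates are 0-based half-open internally; SAM output and all
human-facing junction coordinates are 1-based. A junction is always
reported as the first retained (aligned) base adjacent to the clip.

## Mappability and unique regions

Mappability at position p is 1/(number of genome positions whose k-mer is
within Hamming distance m of the k-mer at p, counting p itself), computed
for forward-strand k-mers (a `both_strands` flag adds reverse-complement
matches). Defaults k = 100, m = 2. The production algorithm is exact, not
heuristic: candidate pairs are generated by the pigeonhole principle (two
k-mers within m mismatches must agree exactly on one of m+1 chunks; chunk
occurrences are grouped by hashing) and verified with vectorised Hamming
distance. An independent O(n²) all-pairs oracle cross-checks it in the
tests on ≤ 20 kb genomes. Unique regions are maximal runs of mappability
exactly 1 *strictly longer* than `min_len` (default 1000 positions).

## Depth, normalisation and terminal CNV calls

Per-base depth counts reads whose aligned (non-clipped) span covers the
base, above a MAPQ threshold (default 0, because the unique-region mask
already removes ambiguity). Windows of `bin` = 200 bp tile each unique
region from its start (non-overlapping; the bin size is fixed but the step
is exposed as a parameter in spirit — tiling equals the bin here); a
trailing window shorter than bin/2 is dropped. The normalising mean is the
average depth over all analysed window bases, which makes the
length-weighted mean of normalised depth exactly 1 on CNV-free data (an
invariant the tests assert to 1e-9). This differs infinitesimally from a
mean over every unique-region base; the windowed definition was chosen so
the normalisation invariant is exact.

Terminal CNV calling scans inward from each chromosome end over the
window profile: a run of ≥ `min_windows` (10) windows below
`del_ratio_max` (0.25, deletion) or above `dup_ratio_min` (1.5,
duplication) that starts at the outermost analysable window is called.
Numerical robustness choices, both visible in the call record:

- **Edge trim.** Fragments cannot extend past a chromosome end, so
  coverage ramps over roughly one insert length; the outermost `edge_trim`
  (400 bp) of windows is skipped before the scan, otherwise a duplicated
  terminal segment's first window (≈ 0.5–1.5× instead of 2×) would break
  the run at its start.
- **Gap tolerance.** Up to 2 consecutive windows may violate the threshold
  inside a run. At 30× a 2× window falls below 1.5 in a few per mille of
  windows; over a ~100-window duplication a hard break would truncate the
  run in a double-digit percentage of datasets.
- **Resolution bracket.** Each call carries both its `boundary` (first
  window at normal copy, 1-based; for duplications the last duplicated
  base) and `inner_edge` (inner edge of the aberrant run). Where unique
  regions are interrupted — typically exactly at homology-mediated
  junctions, whose identical sequence is masked — the true junction lies
  somewhere in that gap, so junction/boundary consistency is checked
  against the bracket widened by one bin, not against a fixed ±1 bin.

Depth gives window-level localisation only; base resolution always comes
from junction evidence. Interior CNVs are out of scope.

## Junction clusters and clip characterisation

Reads with a terminal soft clip ≥ `min_clip` (10) bases are grouped by
(chromosome, clip coordinate, side); clusters need `min_support` (3)
reads, all clipping at the identical coordinate. The consensus clip is a
per-column majority vote anchored at the junction, oriented 5'→3' away
from the retained side — for left clips this is the reverse complement of
the stored bases. With this convention a telomere added at a left-arm
break (whose appended sequence on the forward reference strand is the
C-rich strand, since telomerase extends the bottom-strand 3' end) yields a
G-rich consensus scoring directly against the `GGTTAC` core. Ties in the
vote become N; N never matches the core motif and never seeds
realignment.

Telomere scoring finds the largest tandem chain of exact core occurrences
with ≤ `max_spacer` (2) intervening bases, by dynamic programming over the
occurrence graph (verified against exhaustive chain enumeration in the
tests); a clip is telomeric when the chain has ≥ 2 copies and spans ≥ 50 %
of the clip. The core motif is the only biologically fixed element; the
spacer grammar is a configurable stand-in because the telomerase repeat
grammar is degenerate and not fully specified.

Clip realignment is seed-and-extend: exact seeds of `min_hit_len` (15)
located by substring search on both strands, ungapped extension allowing
≤ 2 mismatches (flanking mismatches trimmed), hits deduplicated per
diagonal and ranked by length then identity. Gapped realignment of clips
is a non-goal.

Microhomology of a junction is the longest L for which the last L bases
the partner contributes equal the first L bases the retained side
contributes next, both flanks written on the junction-forming strand in
joined-molecule order. Note this quantity is not monotone in L (an L = 2
overlap can exist without an L = 1 overlap); the value reported is the
maximum over all L up to the 20 bp flank window. Identical flanks of
length w score w — the degenerate full-homology case, which the classifier
routes to homology-driven logic rather than microhomology-mediated
joining.

## Discordant pairs, chimeras, breakpoint narrowing

Pairs are flagged when mates share orientation (inversion signature), map
to different chromosomes, or exceed insert mean + 5 sd (the outlier cut is
an engineering choice; insert statistics default to median and
1.4826 × MAD over concordant pairs). Flagged pairs cluster per kind with a
window of mean + 3 sd on both loci; groups need ≥ 3 pairs.

A pair supports a chimera of two homologous genes when one mate anchors
(MAPQ > 0) with ≥ 1 base of gene-A-specific sequence and the other with
≥ 1 base of gene-B-specific sequence, the pair as mapped is inconsistent
with both parental loci, and the insert implied on the chimeric molecule
(identical interval counted once) is within mean ± 3 sd. Pairs entirely
inside the identical region carry no information and are never counted.

Breakpoint narrowing aligns the two homologs in chimera-forming
orientation (the inverted partner is reverse-complemented first) with unit
match/mismatch scores, gap −2 and free end gaps, and reports the maximal
run of identical aligned columns containing the switch column. Ties take
the run containing the switch, then the leftmost. This is the honest
resolution limit of a recombination-mediated junction: the result is an
interval (240 bp for the same-orientation pair, 12 bp for the inverted
pair in the synthetic genome), not a base.

## Classification

Each terminal-deletion depth call yields exactly one mechanism call, by
rules applied in order: (1) a telomeric junction cluster on the arm →
de novo telomere addition, upgraded to complex inversion + deletion when
an inversion-kind pair group and an inverted homology interval lie
centromeric of the junction on the same arm; (2) a boundary-consistent
cluster whose clip realigns to another chromosome carrying a terminal
duplication, with chimera support → homology-driven translocation; (3) a
cluster whose clip realigns elsewhere with microhomology ≤ 1 and no
duplication at the partner → homology-independent fusion; (4) a clip-free
fallback for translocation — required because no read can span an
identical region longer than the read length, so such junctions produce no
soft clips at all; the junction is then reported at the homology
interval's telomere-facing edge on the deleted chromosome; (5) otherwise
unresolved. Telomeric clips are tested first because they would otherwise
realign to telomeric tracts and masquerade as fusions. `microhom_max` = 1
separates "no microhomology" fusion from microhomology-mediated joining.

Confidence is high when junction support is ≥ 2 × `min_support` and the
junction agrees with the depth boundary (bracket ± 1 bin), or, for the
complex mechanism, is linked to it through the called inversion — the
telomere junction of an inversion + deletion sits an inversion-length away
from the terminal depth boundary in reference coordinates, so a literal
±1-bin check cannot apply there and the linkage requirement replaces it.
A dicentric fusion's subsequent fate (breakage versus centromere
inactivation) is reported as a free-text note, never inferred; retained
genes within 5 kb of a called de novo telomere are annotated
`near_new_telomere` as silencing candidates with no expression claim.

## Synthetic data: what it emulates and what it does not

The generator builds a three-chromosome genome (default 150/250/100 kb)
with: degenerate telomeric tracts (300 bp) at every end — G-rich strand
facing the end, per-core spacer probability 0.3; two rDNA-like arrays
(3 × 1.5 kb identical units) at both ends of the last chromosome; a
same-orientation homologous gene pair on chromosomes I and II sharing a
240 bp exact internal block (88 % identity elsewhere); an
inverted-orientation pair flanking a middle gene on the chromosome II arm,
sharing a 12 bp window that is identical in chimera-forming orientation;
and an essential gene 40 kb centromeric of the inverted pair, which
`apply_rearrangement` refuses to delete (viability logic). The bases
immediately flanking every engineered identical block differ between the
homologs, and non-homologous junctions are slid or the telomere phase
rotated until no chance base permits alignment extension across the
junction and the 20 bp flanks share no suffix/prefix overlap — so truth
junctions are exactly recoverable and "no microhomology" is engineered,
not accidental.

Reads are 2 × 150 bp; fragments uniform over the mutant genome with
Normal(400, 50) lengths truncated at the read length; constant quality;
i.i.d. substitution errors (default 0.005); no indels, PCR duplicates, GC
bias or quality model. Truth alignments are computed against the
*reference* through each mutant chromosome's segment map: a
junction-spanning read is assigned to the side with the longer
reference-contiguous match — extended through sequence locally identical
between mutant and reference, as an aligner would, which is what makes
homology junctions land on the outermost discriminating base — ties going
to the lower coordinate, the remainder soft-clipped; the pre-error
sequence decides the match extent, so errors appear as mismatches inside
the matched block and never move the truth alignment. Reads aligning
entirely inside annotated multi-copy features (identical regions, rDNA,
telomeric tracts) get MAPQ 0. Consequently, passing tests demonstrate the
inference logic under a faithful but idealised aligner; they do not
exercise aligner-specific clip placement, indel handling, or mapping noise
of real BWA-MEM output, and real telomerase repeat degeneracy may differ
from the spacer grammar used here.

## Evaluation harness and problem sizes

`gcrscope.evaluation.run_truth_recovery` simulates n genomes (default 25
at the full ~500 kb scale, 30×, error 0.005), one event each cycling the
four mechanisms, analyses each from scratch and scores mechanism accuracy,
exact junction recovery, and homology-interval consistency. The test suite
runs the same cohort, plus unit and property tests on a reduced ~200 kb
genome — chosen as the smallest layout in which every motif keeps its
full-scale geometry — so the whole suite completes in a few minutes on one
CPU. `scripts/acceptance.py` re-runs the cohort plus the two printed-value
arithmetic checks (codon span 286–365 → 240 nt; 71 kb − 5 kb → 66 kb) and
writes JSON.

## Known limitations

Single-event genomes (no compound rearrangement disentangling beyond the
inversion + deletion pattern); haploid copy-number model; interior CNVs
and genome-wide split-read SV calling out of scope; a translocation whose
donor duplication is itself repetitive falls to unresolved by design;
VCF output is a minimal DEL/BND writer, not a full SV representation;
depth thresholds (0.25 / 1.5 / 10 windows) are engineering defaults for
haploid ≥ 20× data, exposed in the configuration.
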