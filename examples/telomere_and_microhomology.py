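"""Characterising clipped sequence: telomeric content and microhomology.

The clipped part of junction-spanning reads carries the partner sequence of
the rearrangement. Tandem copies of the fission-yeast core telomere repeat
GGTTAC (spacers tolerated) indicate telomerase healing; a suffix/prefix
overlap between the junction flanks measures microhomology, which separates
homology-independent fusion (0-1 bp) from microhomology-mediated joining.
"""

from gcrscope import score_telomeric, measure_microhomology

for clip in ("GGTTACGGTTACGGTTACGGTTAC",      # pure tandem cores
             "GGTTACAGGTTACCGGTTACGGTTAC",    # degenerate, 1 nt spacers
             "ACGTACGTACGTACGTACGTACGT"):     # not telomeric
    score, is_telo = score_telomeric(clip)
    print(f"{clip}: {score} tandem core copies, telomeric={is_telo}")

# junction flanks in joined-molecule order (partner ends at the junction,
# retained side starts there)
print("clean fusion junction:",
      measure_microhomology("TTAGCCGG", "CCGGAATC"), "bp microhomology")
print("4 bp overlap junction:",
      measure_microhomology("ACGGTT", "TTACGG"), "bp microhomology")
# A clean junction (0 bp) joined to rDNA is the homology-independent
# chromosome fusion signature; identical flanks would instead indicate a
# homology-driven junction and are routed to homology analysis.
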