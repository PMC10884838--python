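"""Narrowing a homology-mediated breakpoint to its identical interval.

A junction formed by recombination between two homologous genes cannot be
resolved to a base: any crossover inside their shared identical sequence
yields the same molecule. Aligning the homologs (in chimera-forming
orientation) and taking the maximal run of identical columns around the
switch gives the honest answer - an interval, here the 12 bp shared window
of an inverted gene pair.
"""

import numpy as np

from gcrscope import narrow_breakpoint_interval, revcomp

rng = np.random.default_rng(5)
rand = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))

gene_a = rand(900)
# a diverged paralog (~12% substitutions), then plant a 12 bp identical
# window with discriminating bases at both edges
b = list(gene_a)
for i in np.flatnonzero(rng.random(900) < 0.12):
    b[i] = "ACGT"[("ACGT".index(b[i]) + 1 + int(rng.integers(0, 3))) % 4]
w = 450
b[w : w + 12] = gene_a[w : w + 12]
b[w - 1] = "A" if gene_a[w - 1] != "A" else "C"
b[w + 12] = "A" if gene_a[w + 12] != "A" else "C"
gene_b_genomic = revcomp("".join(b))   # the paralog sits on the - strand

hi = narrow_breakpoint_interval(gene_a, revcomp(gene_b_genomic),
                                approx_break=w + 5)
print(f"breakpoint interval: {hi.length} bp, exact={hi.is_exact}")
print(f"on gene A: {hi.seqA_range}, on oriented gene B: {hi.seqB_range}")
# length 12 == the engineered shared window: the breakpoint is ambiguous
# over exactly those 12 bases, matching what sequence evidence can support.
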