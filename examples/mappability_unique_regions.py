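"""Exact k-mer mappability and the unique-region mask.

Read-depth CNV evidence is only meaningful where reads map uniquely, so the
pipeline masks the genome to regions > 1 kb in which every position's k-mer
is unique up to the mismatch budget. This example shows the mask on a small
genome containing a tandem repeat array.
"""

import numpy as np

from gcrscope import Genome, compute_mappability, extract_unique_regions

rng = np.random.default_rng(0)
rand = lambda n: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
unit = rand(400)
chrom = rand(3000) + unit * 3 + rand(3000)   # a 3-copy array mid-chromosome

genome = Genome(chroms={"c": chrom})
track = compute_mappability(genome, k=100, m=2)
vals = track.values["c"]
print(f"positions scored: {len(vals)}")
print(f"unique positions: {(vals == 1.0).sum()}  "
      f"(array positions score 1/copy-number = {vals[3200]:.2f})")
for r in extract_unique_regions(track, min_len=1000):
    print(f"unique region: {r.chrom}:{r.start}-{r.end} ({len(r)} bp)")
# Both flanks are unique; no region survives inside the array, so depth
# windows (and CNV calls) are never computed over ambiguous sequence.
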