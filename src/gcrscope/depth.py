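"""Windowed read depth over unique regions and terminal CNV calling.

Per-base depth counts reads whose aligned (non-clipped) span covers the base,
subject to a mapping-quality filter. Windows of ``bin`` bp tile each unique
region from its start; a trailing partial window shorter than bin/2 is
dropped. Depth is normalised by the mean depth over all analysed window
bases, so the length-weighted mean of normalised depth over a CNV-free
genome is exactly 1.

Terminal copy-number calls scan inward from each chromosome end: a run of at
least ``min_windows`` consecutive profile windows below ``del_ratio_max``
(deletion) or above ``dup_ratio_min`` (duplication) that starts at the
outermost analysable window is called. Interior CNVs are out of scope here;
base-resolution boundaries come from soft-clip evidence downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .mappability import UniqueRegion


@dataclass
class DepthProfile:
    windows: pd.DataFrame      # chrom, start, end, raw_depth, normalized_depth
    bin: int
    genome_mean: float

    def to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.windows.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.normalized_depth:.6g}\n")


@dataclass(frozen=True)
class TerminalCnvCall:
    chrom: str
    side: str        # left | right
    kind: str        # deletion | duplication
    boundary: int    # 1-based: first base at normal copy (del) / last duplicated (dup)
    mean_ratio: float
    n_windows: int
    # 1-based inner edge of the outermost aberrant run (last analysable base
    # on the aberrant side); with the boundary it brackets the masked gap in
    # which the true junction must lie, so depth resolution is gap-wide, not
    # one bin, where unique regions are interrupted
    inner_edge: int = 0


def _open_alignments(alignments):
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments, False
    return pysam.AlignmentFile(str(alignments)), True


def per_base_depth(alignments, chrom_lengths: dict[str, int],
                   min_mapq: int = 0) -> tuple[dict[str, np.ndarray], int]:
    """Aligned-span depth per base; returns (arrays, n_used_reads).

    Soft-clipped bases contribute nothing (the aligned span excludes clips).
    """
    cov = {c: np.zeros(ln + 1, dtype=np.int64) for c, ln in chrom_lengths.items()}
    af, close = _open_alignments(alignments)
    n = 0
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            c = read.reference_name
            if c not in cov:
                raise ValueError(f"alignment references unknown chromosome {c}")
            cov[c][read.reference_start] += 1
            cov[c][read.reference_end] -= 1
            n += 1
    finally:
        if close:
            af.close()
    if n == 0:
        raise ValueError("no usable alignments in input")
    return {c: np.cumsum(a[:-1]) for c, a in cov.items()}, n


def windowed_depth(alignments, regions: list[UniqueRegion], bin: int = 200,
                   min_mapq: int = 0,
                   chrom_lengths: dict[str, int] | None = None) -> DepthProfile:
    """Average depth in ``bin``-bp windows tiling the unique regions."""
    if not regions:
        raise ValueError("no unique regions supplied")
    if chrom_lengths is None:
        af, close = _open_alignments(alignments)
        chrom_lengths = dict(zip(af.references, af.lengths))
        if close:
            af.close()
        alignments = alignments  # reopened inside per_base_depth
    for r in regions:
        if r.chrom not in chrom_lengths or r.end > chrom_lengths[r.chrom]:
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} outside alignment header")
    depth, _ = per_base_depth(alignments, chrom_lengths, min_mapq=min_mapq)

    rows = []
    base_sum = 0
    base_n = 0
    for r in regions:
        arr = depth[r.chrom]
        start = r.start
        while start < r.end:
            end = min(start + bin, r.end)
            if end - start < max(1, bin // 2) and start != r.start:
                break  # trailing partial window too short
            seg = arr[start:end]
            rows.append((r.chrom, start, end, float(seg.mean())))
            base_sum += int(seg.sum())
            base_n += end - start
            start += bin
    genome_mean = base_sum / base_n
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "raw_depth"])
    if genome_mean == 0:
        raise ValueError("zero mean depth over unique regions")
    df["normalized_depth"] = df["raw_depth"] / genome_mean
    return DepthProfile(windows=df, bin=bin, genome_mean=genome_mean)


def _scan_end(sub: pd.DataFrame, from_left: bool, del_max: float,
              dup_min: float, min_windows: int, chrom: str,
              edge_trim: int = 400) -> list[TerminalCnvCall]:
    """Scan one chromosome end of the window table (already chrom-sorted).

    Windows within ``edge_trim`` bp of the outermost analysable window are
    skipped: fragment placement cannot extend past the chromosome end, so
    coverage ramps up over roughly one insert length there and the outermost
    window underestimates copy number.
    """
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    if from_left:
        keep = starts >= starts[0] + edge_trim
        idx = [i for i in range(len(sub)) if keep[i]]
    else:
        keep = ends <= ends[-1] - edge_trim
        idx = [i for i in range(len(sub) - 1, -1, -1) if keep[i]]
    if not idx:
        return []
    nd = sub["normalized_depth"].to_numpy()
    calls = []
    for kind, pred in (("deletion", lambda v: v < del_max),
                       ("duplication", lambda v: v > dup_min)):
        # tolerate up to max_gap consecutive noisy windows inside the run
        # (a 2x window at 30x dips below the duplication threshold by chance
        # in a few per mille of windows; a hard break there would truncate
        # long runs regularly)
        max_gap = 2
        run = []
        gap = 0
        for i in idx:
            if pred(nd[i]):
                run.append(i)
                gap = 0
            else:
                gap += 1
                if gap > max_gap:
                    break
        if len(run) >= min_windows:
            brk = run[-1] + (1 if from_left else -1)
            if 0 <= brk < len(sub):
                row = sub.iloc[brk]
                boundary = int(row.start) + 1 if from_left else int(row.end)
            else:
                # run spans the whole profile: boundary at its inner edge
                row = sub.iloc[run[-1]]
                boundary = int(row.end) + 1 if from_left else int(row.start)
            if kind == "duplication":
                # report the last duplicated base, not the first normal one
                boundary = boundary - 1 if from_left else boundary + 1
            inner_row = sub.iloc[run[-1]]
            inner_edge = int(inner_row.end) if from_left else int(inner_row.start) + 1
            seg = nd[run]
            calls.append(TerminalCnvCall(
                chrom=chrom, side="left" if from_left else "right", kind=kind,
                boundary=boundary, mean_ratio=float(seg.mean()),
                n_windows=len(run), inner_edge=inner_edge))
    return calls


def call_terminal_cnv(profile: DepthProfile, del_ratio_max: float = 0.25,
                      dup_ratio_min: float = 1.5, min_windows: int = 10,
                      edge_trim: int = 400) -> list[TerminalCnvCall]:
    """Terminal deletions/duplications anchored at chromosome ends."""
    calls: list[TerminalCnvCall] = []
    for chrom, sub in profile.windows.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        calls.extend(_scan_end(sub, True, del_ratio_max, dup_ratio_min,
                               min_windows, chrom, edge_trim))
        calls.extend(_scan_end(sub, False, del_ratio_max, dup_ratio_min,
                               min_windows, chrom, edge_trim))
    return calls


def write_cnv_tsv(calls: list[TerminalCnvCall], path) -> None:
    df = pd.DataFrame([c.__dict__ for c in calls],
                      columns=["chrom", "side", "kind", "boundary",
                               "mean_ratio", "n_windows", "inner_edge"])
    df.to_csv(path, sep="\t", index=False)
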