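"""Exact k-mer mappability and unique-region extraction.

Mappability of position p is 1 / (number of genome positions whose k-mer is
within Hamming distance m of the k-mer starting at p, counting p itself); it
is defined for p <= len(chrom) - k and counts forward-strand k-mers only
(``both_strands=True`` adds reverse-complement occurrences). Regions longer
than ``min_len`` where every position has mappability exactly one are the
unique regions used downstream for read-depth analysis.

The production algorithm is exact: candidate neighbor pairs are generated by
the pigeonhole principle (a k-mer pair within m mismatches must agree exactly
on at least one of m+1 chunks) and verified by vectorised Hamming distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class MappabilityTrack:
    """Per-position mappability values in (0, 1]; one vector per chromosome,
    defined for k-mer start positions only (length len(chrom) - k + 1)."""

    values: dict[str, np.ndarray]
    k: int
    m: int


@dataclass(frozen=True)
class UniqueRegion:
    """Maximal run (> min_len) of positions with mappability exactly 1;
    0-based half-open over k-mer start positions."""

    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


def _chunk_spans(k: int, m: int) -> list[tuple[int, int]]:
    n = m + 1
    base, extra = divmod(k, n)
    spans, off = [], 0
    for i in range(n):
        ln = base + (1 if i < extra else 0)
        spans.append((off, ln))
        off += ln
    return spans


def _candidate_pairs(codes: np.ndarray, valid: np.ndarray, k: int, m: int,
                     ) -> np.ndarray:
    """Unordered candidate pairs (as valid-index pairs) sharing >=1 exact
    chunk; guaranteed superset of all pairs within Hamming distance m."""
    pair_chunks: list[np.ndarray] = []
    sw = np.lib.stride_tricks.sliding_window_view(codes, k)
    for off, ln in _chunk_spans(k, m):
        sub = np.ascontiguousarray(sw[valid, off : off + ln])
        keys = sub.view([("", np.uint8)] * ln).ravel()
        order = np.argsort(keys, kind="stable")
        sk = keys[order]
        boundary = np.empty(len(sk), dtype=bool)
        boundary[0] = True
        boundary[1:] = sk[1:] != sk[:-1]
        group_start = np.flatnonzero(boundary)
        group_end = np.append(group_start[1:], len(sk))
        sizes = group_end - group_start
        for gi in np.flatnonzero(sizes >= 2):
            gs, ge = group_start[gi], group_end[gi]
            idx = np.sort(order[gs:ge])
            ii, jj = np.triu_indices(len(idx), k=1)
            pair_chunks.append(idx[ii].astype(np.int64) * len(valid) + idx[jj])
    if not pair_chunks:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(pair_chunks))


def compute_mappability(genome: Genome, k: int = 100, m: int = 2,
                        both_strands: bool = False) -> MappabilityTrack:
    """Exact per-position mappability for every chromosome.

    ``m`` is the mismatch budget (0-2); ``k`` the k-mer length. Guarded to
    genomes of at most 5 Mb. With ``both_strands`` the neighbor count also
    includes reverse-complement matches (off by default, matching the
    forward-strand counting convention of k-mer mappability tools).
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if m not in (0, 1, 2):
        raise ValueError("m must be 0, 1 or 2")
    if genome.total_length > 5_000_000:
        raise ValueError("genome too large for exact mappability (> 5 Mb)")
    shortest = min(len(s) for s in genome.chroms.values())
    if k > shortest:
        raise ValueError("k exceeds the shortest chromosome")

    names = list(genome.chroms)
    seq_cat = "".join(genome.chroms[n] for n in names)
    if both_strands:
        seq_cat = seq_cat + revcomp(seq_cat)
    codes = _encode(seq_cat)

    # valid k-mer start positions (never spanning a chromosome boundary)
    valids, offsets = [], {}
    off = 0
    for n in names:
        ln = len(genome.chroms[n])
        offsets[n] = off
        valids.append(np.arange(off, off + ln - k + 1, dtype=np.int64))
        off += ln
    fwd_n = sum(len(v) for v in valids)
    if both_strands:
        total = off
        for n in reversed(names):
            ln = len(genome.chroms[n])
            # revcomp of chromosome n occupies [2*total - offsets[n] - ln, ...)
            start = 2 * total - offsets[n] - ln
            valids.append(np.arange(start, start + ln - k + 1, dtype=np.int64))
    valid = np.concatenate(valids)

    pairs = _candidate_pairs(codes, valid, k, m)
    neighbors = np.zeros(len(valid), dtype=np.int64)
    if len(pairs):
        pi = pairs // len(valid)
        pj = pairs % len(valid)
        sw = np.lib.stride_tricks.sliding_window_view(codes, k)
        # verify in blocks to bound memory
        for lo in range(0, len(pi), 262144):
            hi = min(lo + 262144, len(pi))
            a = sw[valid[pi[lo:hi]]]
            b = sw[valid[pj[lo:hi]]]
            ok = (a != b).sum(axis=1) <= m
            np.add.at(neighbors, pi[lo:hi][ok], 1)
            np.add.at(neighbors, pj[lo:hi][ok], 1)
    values_flat = 1.0 / (1.0 + neighbors[:fwd_n])

    values: dict[str, np.ndarray] = {}
    pos = 0
    for n in names:
        ln = len(genome.chroms[n]) - k + 1
        values[n] = values_flat[pos : pos + ln].copy()
        pos += ln
    return MappabilityTrack(values=values, k=k, m=m)


def compute_mappability_bruteforce(genome: Genome, k: int, m: int,
                                   ) -> MappabilityTrack:
    """Independent O(n^2) all-pairs Hamming oracle (small genomes only)."""
    if genome.total_length > 20_000:
        raise ValueError("brute-force oracle limited to 20 kb")
    names = list(genome.chroms)
    kmers = []
    index = []
    for n in names:
        c = _encode(genome.chroms[n])
        sw = np.lib.stride_tricks.sliding_window_view(c, k)
        kmers.append(sw)
        index.extend((n, i) for i in range(sw.shape[0]))
    allk = np.concatenate(kmers, axis=0).astype(np.int16)
    counts = np.zeros(allk.shape[0], dtype=np.int64)
    for i in range(allk.shape[0]):
        d = (allk != allk[i]).sum(axis=1)
        counts[i] = int((d <= m).sum())  # includes self
    values: dict[str, np.ndarray] = {}
    pos = 0
    for n in names:
        ln = len(genome.chroms[n]) - k + 1
        values[n] = 1.0 / counts[pos : pos + ln]
        pos += ln
    return MappabilityTrack(values=values, k=k, m=m)


def extract_unique_regions(track: MappabilityTrack, min_len: int = 1000,
                           ) -> list[UniqueRegion]:
    """Maximal runs of mappability == 1 strictly longer than ``min_len``,
    sorted and non-overlapping."""
    out: list[UniqueRegion] = []
    for chrom, vals in track.values.items():
        ones = vals == 1.0
        if not ones.any():
            continue
        padded = np.concatenate(([False], ones, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            if e - s > min_len:
                out.append(UniqueRegion(chrom, int(s), int(e)))
    out.sort(key=lambda r: (r.chrom, r.start))
    return out


def write_regions_bed(regions: list[UniqueRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
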