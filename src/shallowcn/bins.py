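"""Fixed-size genomic bins and their sequence-derived annotations.

The copy-number profile lives on a tiling of the genome into non-overlapping,
fixed-size bins (default 15 kb).  Each bin carries annotations computed from
the reference sequence alone: GC content of its characterized bases, the
characterized fraction (share of A/C/G/T bases, i.e. ``1 - r`` where ``r`` is
the proportion of N's), average 50-mer mappability scaled 0-100, and percent
overlap with externally supplied blacklist regions.  These annotations are
sample-independent and can be computed once per reference build and bin size.

Coordinates are 0-based half-open internally; text output is 1-based
inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinGrid",
    "BinAnnotation",
    "make_bins",
    "annotate_sequence",
    "compute_mappability",
    "load_mappability_track",
    "overlap_regions",
    "autosome_mask",
    "bin_class_counts",
]

_GC_BYTES = frozenset(b"GC")
_ACGT_BYTES = frozenset(b"ACGT")

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def _revcomp(seq: bytes) -> bytes:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class BinGrid:
    """Non-overlapping fixed-size tiling of a genome.

    ``chromosomes`` is an ordered list of ``(name, length)`` pairs; the last
    bin of each chromosome may be shorter than ``bin_size``.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int
    chrom_code: np.ndarray = field(repr=False)  # int code per bin
    start: np.ndarray = field(repr=False)
    end: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def chrom(self) -> np.ndarray:
        """Chromosome name per bin."""
        names = np.asarray(self.chrom_names, dtype=object)
        return names[self.chrom_code]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def chrom_offsets(self) -> dict[str, int]:
        """Index of the first bin of each chromosome."""
        out, off = {}, 0
        for name, length in self.chromosomes:
            out[name] = off
            off += -(-length // self.bin_size)
        return out

    def bin_index(self, chrom: str, pos: int) -> int:
        """Bin containing 0-based position ``pos`` (-1 if outside grid)."""
        lengths = self.lengths
        if chrom not in lengths or not (0 <= pos < lengths[chrom]):
            return -1
        return self.chrom_offsets()[chrom] + pos // self.bin_size

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end}
        )


def make_bins(chrom_lengths: Sequence[tuple[str, int]], bin_size: int = 15000) -> BinGrid:
    """Tile each chromosome into ``ceil(length / bin_size)`` contiguous bins.

    The final bin of a chromosome is truncated at the chromosome end, so per
    chromosome the bins partition ``[0, length)`` exactly.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    names = [n for n, _ in chrom_lengths]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")
    codes, starts, ends = [], [], []
    for code, (name, length) in enumerate(chrom_lengths):
        if length < 1:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        s = np.arange(0, length, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, length)
        codes.append(np.full(len(s), code, dtype=np.int32))
        starts.append(s)
        ends.append(e)
    return BinGrid(
        chromosomes=list(chrom_lengths),
        bin_size=int(bin_size),
        chrom_code=np.concatenate(codes),
        start=np.concatenate(starts),
        end=np.concatenate(ends),
    )


@dataclass
class BinAnnotation:
    """Per-bin sequence annotations.

    ``gc`` is the percentage of characterized (A/C/G/T) bases that are G or C,
    NaN where a bin has no characterized base.  ``char_frac`` is the fraction
    of the bin that is characterized (``1 - r``).  ``mappability`` and
    ``encode_overlap_pct`` are on a 0-100 scale.  ``usable`` is the working
    mask for downstream analysis.
    """

    gc: np.ndarray
    char_frac: np.ndarray
    mappability: np.ndarray | None = None
    encode_overlap_pct: np.ndarray | None = None
    usable: np.ndarray | None = None

    def __post_init__(self):
        if self.usable is None:
            self.usable = self.char_frac > 0

    def frame(self, grid: BinGrid) -> pd.DataFrame:
        df = grid.frame()
        df["start"] = df["start"] + 1  # 1-based inclusive for text output
        df["gc"] = self.gc
        df["char_frac"] = self.char_frac
        df["mappability"] = (
            self.mappability if self.mappability is not None else np.nan
        )
        df["encode_overlap_pct"] = (
            self.encode_overlap_pct if self.encode_overlap_pct is not None else 0.0
        )
        df["usable"] = self.usable
        return df


def annotate_sequence(grid: BinGrid, reference: Mapping[str, str]) -> BinAnnotation:
    """GC content and characterized fraction of every bin.

    ``gc = 100 * (#G + #C) / (#A + #C + #G + #T)`` over the bin, NaN when the
    bin contains no characterized base; ``char_frac = #ACGT / bin_length``.
    Soft-masked (lowercase) bases count as their uppercase base.
    """
    gc = np.full(grid.n_bins, np.nan)
    char_frac = np.zeros(grid.n_bins)
    offsets = grid.chrom_offsets()
    for name, length in grid.chromosomes:
        if name not in reference:
            raise KeyError(f"reference lacks chromosome {name!r}")
        seq = reference[name]
        if len(seq) < length:
            raise ValueError(
                f"reference sequence for {name!r} is {len(seq)} bp, "
                f"grid declares {length} bp"
            )
        b = np.frombuffer(seq[:length].upper().encode("ascii"), dtype=np.uint8)
        is_gc = (b == ord("G")) | (b == ord("C"))
        is_acgt = is_gc | (b == ord("A")) | (b == ord("T"))
        off = offsets[name]
        nb = -(-length // grid.bin_size)
        starts = np.arange(nb, dtype=np.int64) * grid.bin_size
        gc_counts = np.add.reduceat(is_gc.astype(np.int64), starts)
        acgt_counts = np.add.reduceat(is_acgt.astype(np.int64), starts)
        lens = grid.end[off : off + nb] - grid.start[off : off + nb]
        with np.errstate(invalid="ignore", divide="ignore"):
            gc[off : off + nb] = 100.0 * gc_counts / acgt_counts
        char_frac[off : off + nb] = acgt_counts / lens
    return BinAnnotation(gc=gc, char_frac=char_frac)


def _kmer_frequencies_exact(seqs: dict[str, bytes], k: int) -> dict[bytes, int]:
    counts: dict[bytes, int] = {}
    for seq in seqs.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def compute_mappability(
    grid: BinGrid,
    reference: Mapping[str, str],
    k: int = 50,
    mismatches: int = 0,
    max_bruteforce_bp: int = 20000,
) -> np.ndarray:
    """Average k-mer uniqueness per bin, scaled 0-100.

    For each position ``x``, ``F_k(x)`` counts the occurrences of the k-mer
    starting at ``x`` in the reference sequence and its reverse complement;
    the per-position mappability is ``M_k(x) = 1 / F_k(x)``.  A k-mer
    containing an uncharacterized base is unalignable and scores 0.  The bin
    value is 100 times the mean of ``M_k(x)`` over all positions whose k-mer
    starts in the bin (and fits within the chromosome); bins with no scored
    position get 0.

    ``mismatches=0`` is the exact-match mode (hash-based, scales to any
    genome that fits in memory).  ``mismatches=2`` counts occurrences within
    Hamming distance 2 by brute force and is intended as an oracle for tiny
    genomes only (guarded by ``max_bruteforce_bp``).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    seqs = {
        name: reference[name][:length].upper().encode("ascii")
        for name, length in grid.chromosomes
    }
    if max(len(s) for s in seqs.values()) < k:
        raise ValueError(f"no chromosome is at least k={k} bp long")

    if mismatches == 0:
        forward = _kmer_frequencies_exact(seqs, k)

        def freq(kmer: bytes) -> int:
            return forward.get(kmer, 0) + forward.get(_revcomp(kmer), 0)

    elif mismatches > 0:
        total = sum(len(s) for s in seqs.values())
        if total > max_bruteforce_bp:
            raise ValueError(
                f"mismatch-tolerant mode is brute force; genome is {total} bp, "
                f"limit {max_bruteforce_bp} bp"
            )
        windows = []
        for seq in seqs.values():
            for strand in (seq, _revcomp(seq)):
                arr = np.frombuffer(strand, dtype=np.uint8)
                if len(arr) >= k:
                    idx = np.arange(len(arr) - k + 1)[:, None] + np.arange(k)[None, :]
                    windows.append(arr[idx])
        allw = np.concatenate(windows, axis=0)  # (P, k)

        def freq(kmer: bytes) -> int:
            q = np.frombuffer(kmer, dtype=np.uint8)
            return int(np.count_nonzero((allw != q).sum(axis=1) <= mismatches))

    else:
        raise ValueError("mismatches must be >= 0")

    mapp = np.zeros(grid.n_bins)
    offsets = grid.chrom_offsets()
    for name, length in grid.chromosomes:
        seq = seqs[name]
        npos = length - k + 1
        if npos <= 0:
            continue
        m = np.zeros(npos)
        for x in range(npos):
            kmer = seq[x : x + k]
            if any(c not in _ACGT_BYTES for c in kmer):
                m[x] = 0.0
            else:
                f = freq(kmer)
                m[x] = 1.0 / f if f > 0 else 0.0
        off = offsets[name]
        nb = -(-length // grid.bin_size)
        pos_bin = np.arange(npos) // grid.bin_size
        sums = np.bincount(pos_bin, weights=m, minlength=nb)
        counts = np.bincount(pos_bin, minlength=nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = 100.0 * sums / counts
        vals[counts == 0] = 0.0
        mapp[off : off + nb] = vals
    return mapp


def load_mappability_track(
    grid: BinGrid, intervals: Iterable[tuple[str, int, int, float]]
) -> np.ndarray:
    """Length-weighted mean of a per-interval mappability track per bin.

    Accepts values on a 0-1 or 0-100 scale (autodetected by the maximum);
    the result is always 0-100.  Genome positions absent from the track
    count as 0.  Intervals on chromosomes not in the grid are skipped with a
    warning.
    """
    intervals = list(intervals)
    numer = np.zeros(grid.n_bins)
    offsets = grid.chrom_offsets()
    lengths = grid.lengths
    skipped = set()
    max_val = 0.0
    for chrom, start, end, value in intervals:
        if chrom not in lengths:
            skipped.add(chrom)
            continue
        if end <= start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
        max_val = max(max_val, value)
        start = max(0, start)
        end = min(end, lengths[chrom])
        if end <= start:
            continue
        off = offsets[chrom]
        first, last = start // grid.bin_size, (end - 1) // grid.bin_size
        for b in range(first, last + 1):
            lo = max(start, b * grid.bin_size)
            hi = min(end, (b + 1) * grid.bin_size, lengths[chrom])
            numer[off + b] += value * (hi - lo)
    if skipped:
        warnings.warn(f"track chromosomes not in grid, skipped: {sorted(skipped)}")
    scale = 100.0 if max_val <= 1.0 + 1e-9 else 1.0
    return scale * numer / (grid.end - grid.start)


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def overlap_regions(
    grid: BinGrid, regions: Iterable[tuple[str, int, int]]
) -> np.ndarray:
    """Percent of each bin covered by the union of the given regions.

    Regions are 0-based half-open; overlapping or adjacent pieces are merged
    before measuring, so the result is invariant to how a region is split.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        if end <= start:
            raise ValueError(f"malformed region {chrom}:{start}-{end}")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    covered = np.zeros(grid.n_bins)
    offsets = grid.chrom_offsets()
    lengths = grid.lengths
    for chrom, ivals in by_chrom.items():
        if chrom not in lengths:
            continue
        off = offsets[chrom]
        for s, e in _merge_intervals(ivals):
            s = max(0, s)
            e = min(e, lengths[chrom])
            if e <= s:
                continue
            first, last = s // grid.bin_size, (e - 1) // grid.bin_size
            for b in range(first, last + 1):
                lo = max(s, b * grid.bin_size)
                hi = min(e, (b + 1) * grid.bin_size, lengths[chrom])
                covered[off + b] += hi - lo
    return 100.0 * covered / (grid.end - grid.start)


def autosome_mask(grid: BinGrid) -> np.ndarray:
    """True for bins on autosomes (chromosome name, minus any 'chr' prefix,
    is purely numeric)."""
    is_auto = np.array(
        [name.removeprefix("chr").isdigit() for name in grid.chrom_names]
    )
    return is_auto[grid.chrom_code]


def bin_class_counts(annotation: BinAnnotation) -> dict[str, int]:
    """Counts of fully characterized / partially characterized / all-N bins."""
    cf = annotation.char_frac
    return {
        "total": int(cf.size),
        "all_n": int(np.count_nonzero(cf == 0)),
        "partial": int(np.count_nonzero((cf > 0) & (cf < 1))),
        "full": int(np.count_nonzero(cf == 1)),
    }
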