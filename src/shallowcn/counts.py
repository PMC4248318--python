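"""Per-bin read counts: filtering, binning, partial-bin adjustment,
normalization, and matched-reference comparison.

Reads are assigned to the bin containing their leftmost aligned base.  Counts
of bins only partly covered by characterized sequence are divided by the
characterized fraction ``1 - r`` so that partially-N bins and truncated
chromosome-end bins are on the same footing as full bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .bins import BinAnnotation, BinGrid

__all__ = [
    "AlignedRead",
    "CountProfile",
    "FilterStats",
    "filter_alignments",
    "bin_counts",
    "adjust_partial_bins",
    "normalize",
    "compare_to_reference",
    "mean_reads_per_bin",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignedRead:
    chrom: str
    pos: int  # leftmost aligned base, 0-based
    mapq: int = 0
    is_duplicate: bool = False
    is_unmapped: bool = False


@dataclass
class FilterStats:
    total: int = 0
    unmapped: int = 0
    duplicate: int = 0
    low_mapq: int = 0
    kept: int = 0

    def log(self) -> None:
        logger.info(
            "reads: total %d -> unmapped %d, duplicate %d, mapq<cutoff %d -> kept %d",
            self.total, self.unmapped, self.duplicate, self.low_mapq, self.kept,
        )


def filter_alignments(
    reads: Iterable[AlignedRead],
    mapq_min: int = 37,
    drop_duplicates: bool = True,
    stats: FilterStats | None = None,
) -> Iterator[AlignedRead]:
    """Keep mapped, non-duplicate reads with ``mapq >= mapq_min``.

    The default cutoff of 37 is the highest mapping quality emitted by BWA;
    aligners with different MAPQ scales warrant a different cutoff.
    """
    for read in reads:
        if stats is not None:
            stats.total += 1
        if read.is_unmapped:
            if stats is not None:
                stats.unmapped += 1
            continue
        if drop_duplicates and read.is_duplicate:
            if stats is not None:
                stats.duplicate += 1
            continue
        if read.mapq < mapq_min:
            if stats is not None:
                stats.low_mapq += 1
            continue
        if stats is not None:
            stats.kept += 1
        yield read


def bin_counts(
    reads: Iterable[AlignedRead], grid: BinGrid
) -> tuple[np.ndarray, int]:
    """Count reads per bin by leftmost aligned base.

    Returns ``(raw, skipped)`` where ``skipped`` counts reads on chromosomes
    absent from the grid or outside declared chromosome bounds.
    """
    raw = np.zeros(grid.n_bins, dtype=np.int64)
    offsets = grid.chrom_offsets()
    lengths = grid.lengths
    skipped = 0
    for read in reads:
        length = lengths.get(read.chrom)
        if length is None or not (0 <= read.pos < length):
            skipped += 1
            continue
        raw[offsets[read.chrom] + read.pos // grid.bin_size] += 1
    if skipped:
        logger.warning("%d reads fell outside the bin grid and were skipped", skipped)
    return raw, skipped


def adjust_partial_bins(raw: np.ndarray, annotation: BinAnnotation) -> np.ndarray:
    """Divide counts by the characterized fraction ``1 - r``.

    Bins with no characterized base get NaN (they cannot receive reads and
    are unusable anyway).
    """
    cf = annotation.char_frac
    adjusted = np.full(len(raw), np.nan)
    ok = cf > 0
    adjusted[ok] = raw[ok] / cf[ok]
    return adjusted


def normalize(
    values: np.ndarray, usable: np.ndarray | None = None, mode: str = "median"
) -> np.ndarray:
    """Scale a profile by its median (default) or mean over usable bins.

    Operates on the linear scale; any log2 transform is an export-time
    concern and must never precede noise estimation.
    """
    if mode not in ("median", "mean"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    v = np.asarray(values, dtype=float)
    sel = np.isfinite(v)
    if usable is not None:
        sel &= usable
    if not sel.any():
        raise ValueError("no usable finite values to normalize")
    center = np.median(v[sel]) if mode == "median" else np.mean(v[sel])
    if center <= 0:
        raise ValueError("profile center is non-positive; cannot normalize")
    out = np.full(len(v), np.nan)
    out[sel] = v[sel] / center
    return out


@dataclass
class CountProfile:
    """Per-bin counts for one sample at the successive processing stages."""

    grid: BinGrid
    raw: np.ndarray
    sample_id: str = "sample"
    adjusted: np.ndarray | None = None
    corrected: np.ndarray | None = None
    normalized: np.ndarray | None = None
    usable: np.ndarray | None = field(default=None, repr=False)

    def mean_reads(self, usable: np.ndarray | None = None) -> float:
        """N: mean raw reads per usable bin (counting-statistics depth)."""
        mask = usable if usable is not None else self.usable
        if mask is None:
            mask = np.ones(len(self.raw), dtype=bool)
        if not mask.any():
            raise ValueError("no usable bins")
        return float(np.mean(self.raw[mask]))


def mean_reads_per_bin(raw: np.ndarray, usable: np.ndarray) -> float:
    if not usable.any():
        raise ValueError("no usable bins")
    return float(np.mean(np.asarray(raw, dtype=float)[usable]))


def compare_to_reference(test: CountProfile, ref: CountProfile) -> np.ndarray:
    """Per-bin log2 ratio of two normalized profiles on the same grid.

    Bins where the reference is zero or either value is missing are NaN.
    """
    if test.grid.chromosomes != ref.grid.chromosomes or test.grid.bin_size != ref.grid.bin_size:
        raise ValueError("profiles are on different bin grids")
    if test.normalized is None or ref.normalized is None:
        raise ValueError("both profiles must be normalized first")
    t, r = test.normalized, ref.normalized
    out = np.full(len(t), np.nan)
    ok = np.isfinite(t) & np.isfinite(r) & (r > 0)
    out[ok] = np.log2(t[ok] / r[ok])
    return out
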