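"""Synthetic references, bias surfaces, copy-number profiles, and normal
panels with known ground truth.

The generator realizes the data-generating assumptions behind the pipeline:
per-bin read counts are Poisson with mean proportional to (copy ratio) x
(a smooth multiplicative bias in GC and mappability) x (characterized
fraction).  It can emit a small multi-chromosome reference with N-gaps, GC
gradients, and duplicated (hence mappability ~50) segments; planted
whole-chromosome and focal aberrations; and recurrent anomalous bins shared
across a panel, for blacklist recovery.  Everything is deterministic under
the spec seed.

Counts are simulated at bin level; a read-position emitter (uniform
positions within bins, MAPQ 37) exists solely to exercise the alignment
readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bins import BinAnnotation, BinGrid, make_bins
from .counts import AlignedRead

__all__ = [
    "BiasModel",
    "SimSpec",
    "copy_ratio",
    "truth_annotation",
    "make_reference",
    "simulate_counts",
    "simulate_panel",
    "emit_read_positions",
]

MAPPABILITY_K = 50  # read length the mappability model assumes


@dataclass(frozen=True)
class BiasModel:
    """Parametric multiplicative bias b(GC, mappability), always positive.

    kinds:
      flat       b = 1 (no bias)
      plane      linear in both axes
      separable  f(GC) * g(mappability) — removable by sequential 1D fits
      saddle     a bilinear GC x mappability interaction: the direction of
                 the GC effect flips with mappability, so no product
                 f(GC) * g(mappability) can represent it; the case that only
                 a simultaneous 2D correction can remove
    """

    kind: str = "flat"
    gc_slope: float = 0.3
    map_slope: float = 0.2
    gc_center: float = 45.0
    gc_width: float = 15.0
    interaction: float = 0.25  # saddle: amplitude of the cross term
    floor: float = 0.25

    def __call__(self, gc: np.ndarray, mapp: np.ndarray) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        mapp = np.asarray(mapp, dtype=float)
        if self.kind == "flat":
            return np.ones(np.broadcast(gc, mapp).shape)
        if self.kind == "plane":
            b = (
                1.0
                + self.gc_slope * (gc - 50.0) / 50.0
                + self.map_slope * (mapp - 75.0) / 50.0
            )
            return np.maximum(b, self.floor)
        if self.kind == "separable":
            f = self.floor + np.exp(-((gc - self.gc_center) ** 2) / (2 * self.gc_width**2))
            g = 0.25 + 0.75 * mapp / 100.0
            return f * g
        if self.kind == "saddle":
            b = 1.0 + self.interaction * ((gc - 50.0) / 20.0) * ((mapp - 75.0) / 25.0)
            return np.maximum(b, self.floor)
        raise ValueError(f"unknown bias kind {self.kind!r}")


@dataclass
class SimSpec:
    """Parameters of one synthetic study.

    Defaults emulate a shallow-WGS run at the depth where profiles become
    useful in practice: ~30 reads per 15-kb bin (~0.1x coverage), GC varying
    over a realistic 35-65% range with bin-to-bin spread, and Poisson
    counting noise as the only stochastic component.
    """

    seed: int
    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [("1", 1_500_000), ("2", 1_200_000)]
    )
    bin_size: int = 15000
    gc_range: tuple[float, float] = (35.0, 65.0)
    gc_jitter: float = 6.0  # per-bin SD around the gradient, percent GC
    n_gaps: list[tuple[str, int, int]] = field(default_factory=list)
    duplications: list[tuple[str, int, int]] = field(default_factory=list)
    bias: BiasModel = field(default_factory=BiasModel)
    copy_segments: list[tuple[str, int, int, float]] = field(default_factory=list)
    mean_reads_per_bin: float = 30.0
    n_anomaly_bins: int = 0
    anomaly_factor: float = 3.0
    panel_bias_jitter: float = 0.03

    def grid(self) -> BinGrid:
        return make_bins(self.chrom_lengths, self.bin_size)

    def to_dict(self) -> dict:
        return asdict(self)


def _overlap_mask(grid: BinGrid, intervals: list[tuple[str, int, int]],
                  full_only: bool = False, pad: int = 0) -> np.ndarray:
    """Bins overlapping (or, with full_only, fully inside) any interval.

    ``pad`` shrinks the interval from the right for the full-only test so a
    bin counts only if every k-mer starting in it lies inside the interval.
    """
    mask = np.zeros(grid.n_bins, dtype=bool)
    offsets = grid.chrom_offsets()
    lengths = grid.lengths
    for chrom, s, e in intervals:
        if chrom not in lengths:
            continue
        off = offsets[chrom]
        nb = -(-lengths[chrom] // grid.bin_size)
        starts = grid.start[off : off + nb]
        ends = grid.end[off : off + nb]
        if full_only:
            hit = (starts >= s) & (ends + pad <= e)
        else:
            hit = (starts < e) & (ends > s)
        mask[off : off + nb] |= hit
    return mask


def copy_ratio(spec: SimSpec, grid: BinGrid | None = None) -> np.ndarray:
    """Per-bin true copy ratio (baseline 1.0, planted segments override)."""
    grid = grid or spec.grid()
    ratio = np.ones(grid.n_bins)
    offsets = grid.chrom_offsets()
    lengths = grid.lengths
    for chrom, s, e, r in spec.copy_segments:
        if r < 0:
            raise ValueError("copy ratios must be >= 0")
        off = offsets[chrom]
        nb = -(-lengths[chrom] // grid.bin_size)
        starts = grid.start[off : off + nb]
        ends = grid.end[off : off + nb]
        hit = (starts < e) & (ends > s)
        ratio[off : off + nb][hit] = r
    return ratio


GC_ISOCHORE_BP = 900_000  # wavelength of the smooth GC variation


def _gc_targets(spec: SimSpec, grid: BinGrid) -> np.ndarray:
    """Per-bin target GC: isochore-scale smooth variation plus bin jitter.

    Genomic GC fluctuates on the ~1-Mb isochore scale, so the smooth
    component cycles many times per chromosome (local gradients in both
    directions) rather than ramping monotonically; per-bin jitter adds the
    bin-to-bin spread seen at 15 kb.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    lo, hi = spec.gc_range
    mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
    period = max(2.0, GC_ISOCHORE_BP / grid.bin_size)
    gc = np.empty(grid.n_bins)
    offsets = grid.chrom_offsets()
    for name, length in grid.chromosomes:
        off = offsets[name]
        nb = -(-length // grid.bin_size)
        phase = rng.uniform(0, 2 * np.pi)
        smooth = mid + amp * np.sin(2 * np.pi * np.arange(nb) / period + phase)
        gc[off : off + nb] = smooth + rng.normal(0.0, spec.gc_jitter, nb)
    return np.clip(gc, 15.0, 85.0)


def truth_annotation(spec: SimSpec, grid: BinGrid | None = None) -> BinAnnotation:
    """Ground-truth per-bin annotation without building a sequence.

    GC is the generator's target; mappability is 100 for unique sequence, 50
    for bins whose 50-mers lie fully inside a duplicated segment, NaN for
    bins partially covered by one; char_frac reflects the N-gaps.
    """
    grid = grid or spec.grid()
    gc = _gc_targets(spec, grid)
    char_frac = np.ones(grid.n_bins)
    offsets = grid.chrom_offsets()
    lengths = grid.lengths
    # a duplicated interval holds source + literal copy; the copy's GC is the
    # source's, so mirror the targets when the halves are bin-aligned
    for chrom, s, e in spec.duplications:
        half = (e - s) // 2
        if s % grid.bin_size == 0 and half % grid.bin_size == 0:
            b0 = offsets[chrom] + s // grid.bin_size
            nbh = half // grid.bin_size
            gc[b0 + nbh : b0 + 2 * nbh] = gc[b0 : b0 + nbh]
    for chrom, s, e in spec.n_gaps:
        off = offsets[chrom]
        nb = -(-lengths[chrom] // grid.bin_size)
        starts = grid.start[off : off + nb]
        ends = grid.end[off : off + nb]
        ov = np.maximum(0, np.minimum(ends, e) - np.maximum(starts, s))
        char_frac[off : off + nb] -= ov / (ends - starts)
    char_frac = np.clip(char_frac, 0.0, 1.0)
    gc[char_frac == 0] = np.nan

    # duplicated intervals: both the source and its copy drop to F=2, M=0.5
    dup = list(spec.duplications)
    mapp = np.full(grid.n_bins, 100.0)
    if dup:
        interior = _overlap_mask(grid, dup, full_only=True, pad=MAPPABILITY_K - 1)
        touched = _overlap_mask(grid, dup)
        mapp[touched] = np.nan
        mapp[interior] = 50.0
    gap_touched = _overlap_mask(grid, spec.n_gaps) if spec.n_gaps else np.zeros(grid.n_bins, bool)
    mapp[gap_touched & (char_frac > 0)] = np.nan
    return BinAnnotation(gc=gc, char_frac=char_frac, mappability=mapp)


def make_reference(spec: SimSpec) -> tuple[BinGrid, dict[str, str], BinAnnotation]:
    """Build a concrete reference sequence realizing the spec.

    Each bin's sequence carries its target GC exactly (to rounding);
    duplicated segments are literal sequence copies placed end to end within
    the declared interval (first half = source, second half = copy), so
    their interior 50-mers occur twice; N-gaps overwrite with N.  Returns
    the grid, the sequences, and the ground-truth annotation.
    """
    grid = spec.grid()
    for _, length in spec.chrom_lengths:
        if length < 2 * spec.bin_size:
            raise ValueError("chromosomes must be at least 2 bins long")
    truth = truth_annotation(spec, grid)
    gc = _gc_targets(spec, grid)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    seqs: dict[str, np.ndarray] = {}
    offsets = grid.chrom_offsets()
    for name, length in grid.chromosomes:
        arr = np.empty(length, dtype="S1")
        off = offsets[name]
        nb = -(-length // grid.bin_size)
        for b in range(nb):
            s, e = grid.start[off + b], grid.end[off + b]
            L = e - s
            t = gc[off + b]
            if not np.isfinite(t) or not (0.0 <= t <= 100.0):
                raise ValueError(f"infeasible GC target {t}")
            ngc = int(round(L * t / 100.0))
            bases = np.concatenate([
                rng.choice(np.array([b"G", b"C"]), ngc),
                rng.choice(np.array([b"A", b"T"]), L - ngc),
            ])
            rng.shuffle(bases)
            arr[s:e] = bases
        seqs[name] = arr
    for chrom, s, e in spec.duplications:
        half = (e - s) // 2
        seqs[chrom][s + half : s + 2 * half] = seqs[chrom][s : s + half]
    for chrom, s, e in spec.n_gaps:
        seqs[chrom][s:e] = b"N"
    text = {name: arr.tobytes().decode("ascii") for name, arr in seqs.items()}
    return grid, text, truth


def _lambda(
    spec: SimSpec,
    annotation: BinAnnotation,
    copy: np.ndarray,
    mean_reads: float | None = None,
) -> np.ndarray:
    gc = annotation.gc
    mp = (
        annotation.mappability
        if annotation.mappability is not None
        else np.full(len(gc), 100.0)
    )
    cf = annotation.char_frac
    ok = (cf > 0) & np.isfinite(gc) & np.isfinite(mp)
    lam = np.zeros(len(gc))
    b = spec.bias(gc[ok], mp[ok])
    raw_mean = copy[ok] * b * cf[ok]
    mean_reads = spec.mean_reads_per_bin if mean_reads is None else mean_reads
    lam[ok] = mean_reads * raw_mean / np.mean(raw_mean)
    return lam


def anomaly_bins(spec: SimSpec, annotation: BinAnnotation) -> np.ndarray:
    """Deterministic choice of the recurrent anomalous bins."""
    if spec.n_anomaly_bins == 0:
        return np.array([], dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    gc = annotation.gc
    mp = (
        annotation.mappability
        if annotation.mappability is not None
        else np.full(len(gc), 100.0)
    )
    eligible = np.flatnonzero(
        (annotation.char_frac > 0) & np.isfinite(gc) & np.isfinite(mp)
    )
    return np.sort(rng.choice(eligible, size=spec.n_anomaly_bins, replace=False))


def simulate_counts(
    spec: SimSpec,
    annotation: BinAnnotation,
    rng: np.random.Generator | int | None = None,
    copy: np.ndarray | None = None,
    mean_reads: float | None = None,
) -> np.ndarray:
    """Draw Poisson per-bin raw counts for one sample.

    lambda_i = mean_reads x copy_i x b(gc_i, map_i) x char_frac_i, scaled so
    the mean over characterized bins equals ``mean_reads``.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 404 if rng is None else rng])
        )
    grid = spec.grid()
    copy = copy_ratio(spec, grid) if copy is None else copy
    lam = _lambda(spec, annotation, copy, mean_reads)
    if spec.n_anomaly_bins:
        lam[anomaly_bins(spec, annotation)] *= spec.anomaly_factor
    return rng.poisson(lam).astype(np.int64)


def simulate_panel(
    spec: SimSpec,
    n_samples: int,
    annotation: BinAnnotation | None = None,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Independent normal (copy-neutral) samples sharing the anomaly set.

    Each sample gets a mild sample-specific linear perturbation of the bias
    (libraries never share an identical bias), Poisson counts, and the same
    multiplicative distortion on the recurrent anomalous bins.
    """
    if n_samples < 2:
        raise ValueError("a panel needs at least 2 samples")
    grid = spec.grid()
    annotation = truth_annotation(spec, grid) if annotation is None else annotation
    base_copy = np.ones(grid.n_bins)
    lam0 = _lambda(spec, annotation, base_copy)
    anom = anomaly_bins(spec, annotation)
    gc = np.nan_to_num(annotation.gc, nan=50.0)
    mp = (
        np.nan_to_num(annotation.mappability, nan=100.0)
        if annotation.mappability is not None
        else np.full(grid.n_bins, 100.0)
    )
    ss = np.random.SeedSequence([spec.seed if seed is None else seed, 505])
    out = []
    for child in ss.spawn(n_samples):
        rng = np.random.default_rng(child)
        e1, e2 = rng.normal(0.0, spec.panel_bias_jitter, 2)
        tilt = 1.0 + e1 * (gc - 50.0) / 50.0 + e2 * (mp - 75.0) / 50.0
        lam = lam0 * np.maximum(tilt, 0.05)
        if len(anom):
            lam = lam.copy()
            lam[anom] *= spec.anomaly_factor
        out.append(rng.poisson(lam).astype(np.int64))
    return out


def emit_read_positions(
    raw: np.ndarray,
    grid: BinGrid,
    rng: np.random.Generator | int = 0,
    mapq: int = 37,
) -> pd.DataFrame:
    """Expand per-bin counts into uniform read positions within each bin.

    Produces a table (chrom, pos, mapq, is_duplicate) whose re-binning
    reproduces ``raw`` exactly; used to exercise the SAM/TSV readers.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    rows = []
    names = grid.chrom_names
    for i in np.flatnonzero(raw > 0):
        n = int(raw[i])
        pos = rng.integers(grid.start[i], grid.end[i], size=n)
        chrom = names[grid.chrom_code[i]]
        rows.extend((chrom, int(p), mapq, False) for p in sorted(pos))
    return pd.DataFrame(rows, columns=["chrom", "pos", "mapq", "is_duplicate"])


def reads_from_frame(frame: pd.DataFrame):
    """Iterate a read-position table as AlignedRead records."""
    for row in frame.itertuples(index=False):
        yield AlignedRead(
            chrom=str(row.chrom),
            pos=int(row.pos),
            mapq=int(row.mapq),
            is_duplicate=bool(row.is_duplicate),
        )
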