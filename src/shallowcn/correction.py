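"""Simultaneous GC x mappability bias correction.

Sequencing depth depends jointly on the GC content and the mappability of a
bin, and for degraded (e.g. formalin-fixed) material the two effects
interact: the depth optimum along one axis moves with the other.  Correcting
the axes one at a time cannot remove such a bias.  This module corrects both
at once:

1. bins are grouped into integer (GC, mappability) cells (round-half-to-even)
   and the median adjusted count of each populated cell is taken;
2. a robust two-dimensional local polynomial regression (LOESS) surface is
   fitted through the cell medians;
3. each bin's count is divided by the surface value at its *unrounded*
   (GC, mappability) coordinates.

The LOESS core is implemented here directly: for an evaluation point, the
span-fraction nearest populated cells (Euclidean distance; both axes are on
the same 0-100 scale) receive tricube weights, a polynomial of the requested
degree is fitted by weighted least squares centered at the point, and its
constant term is the fitted value.  ``family="symmetric"`` adds bisquare
robustness reweighting of the cells, the conventional meaning of that
option.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bins import BinAnnotation, BinGrid

__all__ = [
    "MedianGrid",
    "BiasSurface",
    "median_count_grid",
    "fit_surface",
    "correct_counts",
    "residuals",
    "cross_validate_span",
    "iterative_correction",
    "correct_counts_separable",
]


@dataclass
class MedianGrid:
    """Median adjusted count per populated integer (GC, mappability) cell."""

    gc: np.ndarray  # int cell coordinates
    mapp: np.ndarray
    median: np.ndarray
    n_bins: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.gc)


def median_count_grid(
    adjusted: np.ndarray,
    annotation: BinAnnotation,
    usable: np.ndarray | None = None,
) -> MedianGrid:
    """Group usable bins by rounded (GC, mappability) and take cell medians.

    Rounding is round-half-to-even (the IEEE default), so e.g. 40.5 -> 40 and
    41.5 -> 42.
    """
    mask = annotation.usable if usable is None else usable
    mask = mask & np.isfinite(adjusted) & np.isfinite(annotation.gc)
    if annotation.mappability is not None:
        mp = annotation.mappability
        mask = mask & np.isfinite(mp)
    else:
        mp = np.full(len(adjusted), 100.0)
    if not mask.any():
        raise ValueError("no usable bins with defined GC and mappability")
    gc_i = np.rint(annotation.gc[mask]).astype(np.int64)
    mp_i = np.rint(mp[mask]).astype(np.int64)
    vals = adjusted[mask]
    key = gc_i * 101 + mp_i
    order = np.argsort(key, kind="stable")
    key, vals = key[order], vals[order]
    uniq, idx_start, counts = np.unique(key, return_index=True, return_counts=True)
    medians = np.empty(len(uniq))
    for j, (s, c) in enumerate(zip(idx_start, counts)):
        medians[j] = np.median(vals[s : s + c])
    return MedianGrid(
        gc=uniq // 101,
        mapp=uniq % 101,
        median=medians,
        n_bins=counts.astype(np.int64),
    )


def _design(
    dx: np.ndarray, dy: np.ndarray, degree: int, direction: np.ndarray | None
) -> np.ndarray:
    """Polynomial basis centered at the evaluation point; shape (..., p).

    When the cells are collinear, ``direction`` is the unit vector of their
    line and the basis is a 1D polynomial in the coordinate along it.
    """
    if direction is not None:
        t = dx * direction[0] + dy * direction[1]
        cols = [np.ones_like(t)]
        if degree >= 1:
            cols.append(t)
        if degree >= 2:
            cols.append(t * t)
        return np.stack(cols, axis=-1)
    cols = [np.ones_like(dx)]
    if degree >= 1:
        cols += [dx, dy]
    if degree >= 2:
        cols += [dx * dx, dx * dy, dy * dy]
    return np.stack(cols, axis=-1)


@dataclass
class BiasSurface:
    """Fitted 2D local-regression surface over (GC, mappability) cells."""

    cell_gc: np.ndarray
    cell_mapp: np.ndarray
    cell_value: np.ndarray
    span: float = 0.65
    family: str = "symmetric"
    degree: int = 2
    robustness_iters: int = 4
    robust_weights: np.ndarray | None = field(default=None, repr=False)
    direction: np.ndarray | None = field(default=None, repr=False)  # collinear cells

    def _n_params(self) -> int:
        if self.direction is not None:
            return self.degree + 1
        return _min_cells(self.degree)

    def _local_weights(self, px: np.ndarray, py: np.ndarray) -> np.ndarray:
        """Tricube neighborhood weights of every cell for each eval point."""
        x, y = self.cell_gc.astype(float), self.cell_mapp.astype(float)
        n = len(x)
        d = np.hypot(px[:, None] - x[None, :], py[:, None] - y[None, :])
        q = min(n, max(int(math.ceil(self.span * n)), self._n_params() + 1))
        dq = np.partition(d, q - 1, axis=1)[:, q - 1]
        if self.span > 1.0:
            dq = dq * self.span ** 0.5
        dq = np.maximum(dq, 1e-12)
        w = np.clip(1.0 - (d / dq[:, None]) ** 3, 0.0, None) ** 3
        # ensure every point has enough support even with distance ties
        deficient = (w > 0).sum(axis=1) < self._n_params()
        if deficient.any():
            w[deficient] = np.clip(
                1.0 - (d[deficient] / (d[deficient].max(axis=1, keepdims=True) * 1.0001)) ** 3,
                1e-6,
                None,
            ) ** 3
        if self.robust_weights is not None:
            w = w * self.robust_weights[None, :]
        return w

    def evaluate(self, gc, mapp) -> np.ndarray:
        """Fitted surface value at arbitrary (GC, mappability) points."""
        px = np.atleast_1d(np.asarray(gc, dtype=float))
        py = np.atleast_1d(np.asarray(mapp, dtype=float))
        z = self.cell_value
        w = self._local_weights(px, py)
        dx = self.cell_gc[None, :] - px[:, None]
        dy = self.cell_mapp[None, :] - py[:, None]
        X = _design(dx, dy, self.degree, self.direction)  # (P, n, p)
        A = np.einsum("pnj,pn,pnk->pjk", X, w, X, optimize=True)
        b = np.einsum("pnj,pn,n->pj", X, w, z, optimize=True)
        out = np.empty(len(px))
        try:
            beta = np.linalg.solve(A, b[..., None])[..., 0]
            out[:] = beta[:, 0]
        except np.linalg.LinAlgError:
            for i in range(len(px)):
                try:
                    out[i] = np.linalg.solve(A[i], b[i])[0]
                except np.linalg.LinAlgError:
                    sw = np.sqrt(w[i])
                    beta_i, *_ = np.linalg.lstsq(
                        X[i] * sw[:, None], z * sw, rcond=None
                    )
                    out[i] = beta_i[0]
        return out


def _min_cells(degree: int) -> int:
    return math.comb(degree + 2, 2)


def fit_surface(
    grid: MedianGrid,
    span: float = 0.65,
    family: str = "symmetric",
    degree: int = 2,
    robustness_iters: int = 4,
) -> BiasSurface:
    """Fit the robust local-regression surface through the cell medians.

    Cells are unweighted (a cell's median counts once regardless of how many
    bins produced it).  ``family="symmetric"`` runs ``robustness_iters``
    bisquare reweighting passes so isolated anomalous cells do not distort
    the surface; ``family="least-squares"`` (alias ``"gaussian"``) skips
    them.
    """
    if family not in ("symmetric", "least-squares", "gaussian"):
        raise ValueError(f"unknown family {family!r}")
    n = grid.n_cells
    # collinear cells (e.g. a single mappability value) cannot support a
    # full 2D polynomial: fit a 1D local polynomial along their line instead
    direction = None
    pts = np.column_stack([grid.gc, grid.mapp]).astype(float)
    if n >= 2:
        centered = pts - pts.mean(axis=0)
        _, sv, vt = np.linalg.svd(centered, full_matrices=False)
        if sv[1] <= 1e-9 * max(sv[0], 1.0):
            direction = vt[0]
    needed = (degree + 1) if direction is not None else _min_cells(degree)
    if n < needed:
        fallback = (1 + 1) if direction is not None else _min_cells(1)
        if n >= fallback:
            warnings.warn(f"only {n} populated cells; falling back to degree 1")
            degree = 1
        else:
            raise ValueError(
                f"need at least {needed} populated cells, have {n}"
            )
    surface = BiasSurface(
        cell_gc=grid.gc.astype(float),
        cell_mapp=grid.mapp.astype(float),
        cell_value=grid.median.astype(float),
        span=span,
        family=family,
        degree=degree,
        robustness_iters=robustness_iters,
        direction=direction,
    )
    if family == "symmetric":
        for _ in range(robustness_iters):
            fitted = surface.evaluate(surface.cell_gc, surface.cell_mapp)
            resid = surface.cell_value - fitted
            s = np.median(np.abs(resid))
            if s <= 1e-12 * max(1.0, float(np.median(np.abs(surface.cell_value)))):
                break
            u = resid / (6.0 * s)
            rw = np.clip(1.0 - u * u, 0.0, None) ** 2
            surface.robust_weights = rw
    return surface


def _fitted_per_bin(
    surface: BiasSurface,
    annotation: BinAnnotation,
    usable: np.ndarray,
) -> np.ndarray:
    mp = (
        annotation.mappability
        if annotation.mappability is not None
        else np.full(len(annotation.gc), 100.0)
    )
    fitted = np.full(len(annotation.gc), np.nan)
    idx = usable & np.isfinite(annotation.gc) & np.isfinite(mp)
    fitted[idx] = surface.evaluate(annotation.gc[idx], mp[idx])
    return fitted


def correct_counts(
    adjusted: np.ndarray,
    surface: BiasSurface,
    annotation: BinAnnotation,
    usable: np.ndarray | None = None,
) -> np.ndarray:
    """Divide each bin's adjusted count by the surface value at its
    unrounded (GC, mappability).  Bins whose fitted value is not positive
    are masked (NaN) rather than divided."""
    mask = annotation.usable if usable is None else usable
    fitted = _fitted_per_bin(surface, annotation, mask)
    floor = 1e-6 * np.nanmedian(np.abs(fitted))
    corrected = np.full(len(adjusted), np.nan)
    ok = np.isfinite(fitted) & (fitted > max(floor, 0.0)) & np.isfinite(adjusted)
    corrected[ok] = adjusted[ok] / fitted[ok]
    return corrected


def residuals(
    adjusted: np.ndarray,
    surface: BiasSurface,
    annotation: BinAnnotation,
    usable: np.ndarray | None = None,
) -> np.ndarray:
    """Relative residual ``(observed - fitted) / fitted`` per bin.

    A bin with zero observed reads has residual -1; in real genomes those
    concentrate in repetitive sequence where unique alignment fails.
    """
    mask = annotation.usable if usable is None else usable
    fitted = _fitted_per_bin(surface, annotation, mask)
    out = np.full(len(adjusted), np.nan)
    ok = np.isfinite(fitted) & (fitted > 0) & np.isfinite(adjusted)
    out[ok] = (adjusted[ok] - fitted[ok]) / fitted[ok]
    return out


def _fit_for(
    adjusted: np.ndarray,
    annotation: BinAnnotation,
    usable: np.ndarray,
    span: float,
    family: str,
    degree: int,
    robustness_iters: int,
) -> BiasSurface:
    grid = median_count_grid(adjusted, annotation, usable)
    return fit_surface(grid, span=span, family=family, degree=degree,
                       robustness_iters=robustness_iters)


def cross_validate_span(
    adjusted: np.ndarray,
    annotation: BinAnnotation,
    grid: BinGrid,
    spans: list[float],
    usable: np.ndarray | None = None,
    family: str = "symmetric",
    degree: int = 2,
    trim_upper: float = 0.10,
) -> tuple[float, dict[float, float]]:
    """Odd/even cross-validation of the LOESS span.

    The surface is fitted on odd-indexed usable bins only, both parities are
    corrected with it and mean-normalized, and the statistic is the mean of
    the absolute differences between adjacent usable bins (same chromosome)
    after discarding the largest ``trim_upper`` fraction, which absorbs true
    copy-number breakpoints.  Lower is better; returns ``(best_span,
    {span: statistic})``.
    """
    mask = annotation.usable if usable is None else usable
    mask = mask & np.isfinite(adjusted)
    idx = np.flatnonzero(mask)
    if len(idx) < 4:
        raise ValueError("need at least 4 usable bins")
    odd = np.zeros(len(adjusted), dtype=bool)
    odd[idx[1::2]] = True
    stats: dict[float, float] = {}
    chrom = grid.chrom_code
    for span in spans:
        surface = _fit_for(adjusted, annotation, mask & odd, span, family, degree, 4)
        corrected = correct_counts(adjusted, surface, annotation, mask)
        from .counts import normalize

        norm = normalize(corrected, mask, mode="mean")
        vals = norm[idx]
        same_chrom = chrom[idx][1:] == chrom[idx][:-1]
        d = np.abs(np.diff(vals))[same_chrom]
        d = d[np.isfinite(d)]
        d.sort()
        keep = max(1, int(math.floor(len(d) * (1.0 - trim_upper))))
        stats[span] = float(np.mean(d[:keep]))
    best = min(stats, key=stats.get)
    return best, stats


def iterative_correction(
    adjusted: np.ndarray,
    annotation: BinAnnotation,
    resid_cutoff: float,
    usable: np.ndarray | None = None,
    max_iter: int = 15,
    span: float = 0.65,
    family: str = "symmetric",
    degree: int = 2,
) -> tuple[BiasSurface, np.ndarray, int]:
    """Refit the surface after excluding bins with large relative residuals.

    Bins with ``|residual| > resid_cutoff`` (presumably inside copy-number
    aberrations) are dropped from the fit and the surface recomputed, until
    the excluded set stops changing or ``max_iter`` is reached.  Off by
    default in the pipeline; it rarely changes the result materially.
    Returns ``(surface, included_mask, n_iterations)``.
    """
    if resid_cutoff <= 0:
        raise ValueError("resid_cutoff must be positive")
    base = (annotation.usable if usable is None else usable) & np.isfinite(adjusted)
    included = base.copy()
    surface = None
    for it in range(1, max_iter + 1):
        if not included.any():
            raise RuntimeError("iterative correction excluded every bin")
        surface = _fit_for(adjusted, annotation, included, span, family, degree, 4)
        resid = residuals(adjusted, surface, annotation, base)
        new_included = base & (np.abs(resid) <= resid_cutoff)
        if np.array_equal(new_included, included):
            return surface, included, it
        included = new_included
    warnings.warn(f"iterative correction did not converge in {max_iter} iterations")
    return surface, included, max_iter


def correct_counts_separable(
    adjusted: np.ndarray,
    annotation: BinAnnotation,
    usable: np.ndarray | None = None,
    span: float = 0.65,
    robustness_iters: int = 4,
) -> np.ndarray:
    """Sequential 1D correction: GC first, then mappability.

    This is the comparison mode representing the approach of correcting the
    two biases independently.  Counts are divided by a smoothed median-per-
    integer-GC curve, then the result by a smoothed median-per-integer-
    mappability curve.  When a bias genuinely interacts across the two axes
    this cannot remove it, which is the motivation for the simultaneous 2D
    surface.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    mask = annotation.usable if usable is None else usable
    mask = mask & np.isfinite(adjusted) & np.isfinite(annotation.gc)
    mp = (
        annotation.mappability
        if annotation.mappability is not None
        else np.full(len(adjusted), 100.0)
    )
    mask = mask & np.isfinite(mp)

    def one_axis(values: np.ndarray, coord: np.ndarray) -> np.ndarray:
        m = mask & np.isfinite(values)
        cells = np.rint(coord[m]).astype(int)
        uniq = np.unique(cells)
        med = np.array(
            [np.median(values[m][cells == u]) for u in uniq], dtype=float
        )
        if len(uniq) >= 7:
            sm = lowess(
                med, uniq.astype(float), frac=min(1.0, span),
                it=robustness_iters, xvals=coord[m].astype(float),
            )
            fitted = np.asarray(sm, dtype=float)
        else:
            # too few distinct cells to smooth: correct by the cell medians
            lut = dict(zip(uniq, med))
            fitted = np.array([lut[c] for c in cells], dtype=float)
        out = np.full(len(values), np.nan)
        ok = fitted > 0
        out[np.flatnonzero(m)[ok]] = values[m][ok] / fitted[ok]
        return out

    step1 = one_axis(adjusted, annotation.gc)
    return one_axis(step1, mp)
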