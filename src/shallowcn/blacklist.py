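"""Empirical blacklist derivation from a panel of normal samples.

Bins that behave anomalously in *every* normal sample — because of reference
assembly errors, unannotated repeats, or common germline CNVs — corrupt
copy-number profiles and the bias fit itself.  They are found by correcting
each panel sample with the GC x mappability surface, taking the per-bin
median of the relative residuals across the panel, and excluding bins whose
median residual falls outside +/- ``cutoff_sd`` robust standard deviations
of the central peak.  The numeric thresholds are frozen after the first
iteration; subsequent iterations refit the per-sample surfaces without the
excluded bins and re-test every bin against the frozen thresholds until the
excluded set reaches a fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bins import BinAnnotation, BinGrid
from .correction import fit_surface, median_count_grid, residuals
from .noise import first_order_sd

__all__ = [
    "ResidualPanel",
    "Blacklist",
    "panel_medians",
    "robust_sd",
    "derive_blacklist",
    "apply_filters",
    "merge_excluded_regions",
]


def panel_medians(panel_residuals: list[np.ndarray]) -> np.ndarray:
    """Per-bin median of relative residuals across panel samples.

    A bin's median is NaN wherever any structural mask applies to all
    samples; individual missing values propagate through ``nanmedian``.
    """
    if len(panel_residuals) < 2:
        raise ValueError("need at least 2 panel samples")
    lengths = {len(r) for r in panel_residuals}
    if len(lengths) != 1:
        raise ValueError("panel residual vectors differ in length (grid mismatch)")
    stack = np.vstack(panel_residuals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        return np.nanmedian(stack, axis=0)


def robust_sd(
    values: np.ndarray,
    chrom: np.ndarray | None = None,
    trim: float = 0.001,
) -> float:
    """Robust SD of genome-ordered values via trimmed first-order differences.

    Focuses on the width of the central peak of the distribution: the
    extreme ``trim`` fraction of differences at each end is discarded before
    ``sigma = sqrt(sum(d^2)/(2m))``, so heavy tails and isolated spikes do
    not inflate the estimate.  No mean scaling is applied (the residuals are
    already centered near zero).
    """
    return first_order_sd(values, chrom=chrom, trim=trim)


@dataclass
class ResidualPanel:
    """State of one blacklist-derivation pass."""

    median_resid: np.ndarray
    sigma: float
    cutoff_sd: float
    lower: float
    upper: float


@dataclass
class Blacklist:
    """Derived set of excluded bins with provenance."""

    excluded: np.ndarray  # bool per bin
    lower: float
    upper: float
    sigma: float
    cutoff_sd: float
    iterations: int
    converged: bool
    median_resid: np.ndarray = field(repr=False)
    threshold_history: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return int(np.count_nonzero(self.excluded))


def derive_blacklist(
    panel_adjusted: list[np.ndarray],
    annotation: BinAnnotation,
    grid: BinGrid,
    cutoff_sd: float = 4.0,
    max_iter: int = 50,
    usable: np.ndarray | None = None,
    span: float = 0.65,
    family: str = "symmetric",
    trim: float = 0.001,
) -> Blacklist:
    """Iteratively exclude bins with recurrent anomalous residuals.

    Iteration 1 fits each sample's surface on all usable bins, computes the
    per-bin panel-median residual, estimates the robust SD of that vector in
    genome order, and excludes bins outside ``+/- cutoff_sd * sigma``; the
    two numeric thresholds are then frozen.  Later iterations refit each
    surface without the currently excluded bins, recompute residuals for
    *all* usable bins, and re-test against the frozen thresholds — an
    excluded bin whose residual returns inside the band re-enters.  Stops at
    a fixed point, on a 2-cycle (terminating with the union and a warning),
    or at ``max_iter``.
    """
    if len(panel_adjusted) < 2:
        raise ValueError("need a panel of at least 2 normal samples")
    base = (annotation.usable if usable is None else usable).copy()
    for adj in panel_adjusted:
        if len(adj) != grid.n_bins:
            raise ValueError("panel sample not on the given grid")
        base &= np.isfinite(adj)
    excluded = np.zeros(grid.n_bins, dtype=bool)
    lower = upper = sigma = np.nan
    history: list[tuple[float, float]] = []
    seen: list[np.ndarray] = []
    median_resid = np.full(grid.n_bins, np.nan)
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        included = base & ~excluded
        if not included.any():
            raise RuntimeError("blacklist derivation excluded every bin")
        resids = []
        for adj in panel_adjusted:
            cell_grid = median_count_grid(adj, annotation, included)
            surface = fit_surface(cell_grid, span=span, family=family)
            resids.append(residuals(adj, surface, annotation, base))
        median_resid = panel_medians(resids)
        if it == 1:
            sigma = robust_sd(median_resid[base], chrom=grid.chrom_code[base], trim=trim)
            if sigma <= 0:
                raise ValueError("robust SD of panel residuals is zero")
            lower, upper = -cutoff_sd * sigma, cutoff_sd * sigma
        history.append((lower, upper))
        new_excluded = base & ((median_resid < lower) | (median_resid > upper))
        if np.array_equal(new_excluded, excluded):
            excluded = new_excluded
            converged = True
            break
        if any(np.array_equal(new_excluded, s) for s in seen):
            warnings.warn("blacklist iteration entered a cycle; taking the union")
            excluded = excluded | new_excluded
            converged = True
            break
        seen.append(excluded.copy())
        excluded = new_excluded
    else:
        warnings.warn(f"blacklist did not stabilize in {max_iter} iterations")
    return Blacklist(
        excluded=excluded,
        lower=float(lower),
        upper=float(upper),
        sigma=float(sigma),
        cutoff_sd=cutoff_sd,
        iterations=iterations,
        converged=converged,
        median_resid=median_resid,
        threshold_history=history,
    )


def apply_filters(
    annotation: BinAnnotation,
    derived: Blacklist | None = None,
    encode_filter: bool = True,
    mappability_min: float | None = None,
    residual_filter: bool = True,
    autosomes: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Combine all exclusion criteria into the usable-bin mask.

    A bin is usable when it has characterized sequence, no overlap with the
    external blacklist (if enabled), is not in the derived blacklist (if
    enabled), and meets the mappability floor (if set).  Returns the mask
    and a dict of per-reason exclusion masks.
    """
    n = len(annotation.char_frac)
    reasons: dict[str, np.ndarray] = {}
    reasons["all-N"] = annotation.char_frac == 0
    usable = ~reasons["all-N"]
    if autosomes is not None:
        reasons["non-autosome"] = ~autosomes
        usable &= autosomes
    if encode_filter and annotation.encode_overlap_pct is not None:
        reasons["encode-overlap"] = annotation.encode_overlap_pct > 0
        usable &= ~reasons["encode-overlap"]
    if mappability_min is not None and annotation.mappability is not None:
        reasons["low-mappability"] = annotation.mappability < mappability_min
        usable &= ~reasons["low-mappability"]
    if residual_filter and derived is not None:
        reasons["panel-residual"] = derived.excluded
        usable &= ~derived.excluded
    return usable, reasons


def merge_excluded_regions(
    grid: BinGrid, excluded: np.ndarray
) -> list[tuple[str, int, int]]:
    """Merge maximal runs of consecutive excluded bins into regions.

    Returns 0-based half-open ``(chrom, start, end)`` records, one per
    continuous run within a chromosome.
    """
    regions: list[tuple[str, int, int]] = []
    names = grid.chrom_names
    idx = np.flatnonzero(excluded)
    if len(idx) == 0:
        return regions
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1 and grid.chrom_code[i] == grid.chrom_code[prev]:
            prev = i
            continue
        regions.append(
            (names[grid.chrom_code[run_start]],
             int(grid.start[run_start]), int(grid.end[prev]))
        )
        run_start = prev = i
    regions.append(
        (names[grid.chrom_code[run_start]],
         int(grid.start[run_start]), int(grid.end[prev]))
    )
    return regions
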