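"""Profile noise and its counting-statistics expectation.

A copy-number profile normalized to mean 1 whose counts are pure Poisson has
variance 1/N, where N is the average number of reads per bin.  The measured
profile variance is estimated with a mean-scaled, 0.1%-trimmed first-order
(successive-difference) estimator, which is sensitive to bin-to-bin noise
but largely blind to step-like structure from true aberrations.  The excess
of the measured variance over 1/N quantifies noise from sample handling and
processing, independent of sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "NoiseSummary",
    "sigma_diff",
    "first_order_sd",
    "expected_sigma",
    "log2_variance_factor",
    "subsample",
    "variance_regression",
    "segment_snr",
    "noise_summary",
]


def _trim_consistency_factor(trim: float) -> float:
    """E[d^2 retained] / E[d^2] when trimming a Gaussian at both ends.

    Dividing by this makes the trimmed estimator consistent for the SD of
    the Gaussian core (about +1.05% at trim=0.001), so that a pure-counting
    profile reads back sigma = sqrt(1/N) without a small trim-induced bias.
    """
    if trim <= 0:
        return 1.0
    z = sps.norm.ppf(1.0 - trim)
    return (1.0 - 2.0 * (z * sps.norm.pdf(z) + trim)) / (1.0 - 2.0 * trim)


def first_order_sd(
    values: np.ndarray,
    chrom: np.ndarray | None = None,
    trim: float = 0.001,
    trim_correction: bool = True,
) -> float:
    """Robust SD from first-order differences of consecutive values.

    Differences are taken between consecutive finite values within a
    chromosome (never across a boundary), the lowest and highest ``trim``
    fractions of the differences are discarded, and
    ``sigma = sqrt(sum(d^2) / (2 m))`` over the m retained differences
    (E[d^2] = 2 sigma^2 for independent values).  The trimming makes the
    estimate reflect the width of the central peak, immune to a small number
    of huge outliers; ``trim_correction`` removes the slight downward bias
    the trimming induces on a Gaussian core.
    """
    v = np.asarray(values, dtype=float)
    if chrom is None:
        chrom = np.zeros(len(v), dtype=np.int64)
    diffs = []
    for c in np.unique(chrom):
        x = v[chrom == c]
        x = x[np.isfinite(x)]
        if len(x) >= 2:
            diffs.append(np.diff(x))
    if not diffs:
        raise ValueError("fewer than 2 consecutive finite values")
    d = np.concatenate(diffs)
    d.sort()
    k = int(np.floor(trim * len(d)))
    if k > 0:
        d = d[k:-k]
    if len(d) < 3:
        raise ValueError("fewer than 3 retained differences")
    sigma2 = float(np.sum(d * d)) / (2.0 * len(d))
    if trim_correction:
        sigma2 /= _trim_consistency_factor(trim)
    return float(np.sqrt(sigma2))


def sigma_diff(
    profile: np.ndarray,
    chrom: np.ndarray | None = None,
    trim: float = 0.001,
    trim_correction: bool = True,
) -> float:
    """Mean-scaled 0.1%-trimmed first-order SD of a linear-scale profile.

    The profile is scaled by its mean first, so the result is invariant to
    global rescaling and directly comparable with the counting-statistics
    expectation sqrt(1/N).  Must be fed the linear (never log2) profile.
    """
    v = np.asarray(profile, dtype=float)
    finite = np.isfinite(v)
    if not finite.any() or not np.any(v[finite] != 0):
        raise ValueError("profile is empty or all zero")
    m = np.mean(v[finite])
    if m <= 0:
        raise ValueError("profile mean is non-positive")
    return first_order_sd(v / m, chrom=chrom, trim=trim, trim_correction=trim_correction)


def expected_sigma(N: float) -> float:
    """Counting-statistics expectation E[sigma] = sqrt(1/N) for a mean-1
    profile with N reads per bin."""
    if N <= 0:
        raise ValueError("N must be positive")
    return float(np.sqrt(1.0 / N))


def log2_variance_factor() -> float:
    """Variance inflation when measuring on the log2 scale.

    By the delta method, var(log2 X) = (log2 e)^2 var(X) for X near 1, so a
    log2-scale profile has counting variance (log2 e)^2 / N ~ 2.08 / N.
    """
    return float(np.log2(np.e) ** 2)


def subsample(
    raw: np.ndarray,
    target_mean: float,
    seed: int | np.random.Generator,
    usable: np.ndarray | None = None,
) -> np.ndarray:
    """Binomial thinning of per-bin counts to a target mean reads per bin.

    Each read is kept independently with probability target/current mean;
    for Poisson input the thinned counts are exactly Poisson at the lower
    depth, so this is distributionally equivalent to resampling reads.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = np.asarray(raw)
    mask = np.ones(len(raw), dtype=bool) if usable is None else usable
    current = float(np.mean(raw[mask]))
    if target_mean > current:
        raise ValueError(
            f"target mean {target_mean} exceeds current mean {current:.3f}"
        )
    p = target_mean / current
    if p >= 1.0:
        return raw.copy()
    return rng.binomial(raw.astype(np.int64), p)


def variance_regression(
    Ns: np.ndarray, var_hats: np.ndarray
) -> tuple[float, float]:
    """OLS of measured profile variance against 1/N across depths.

    For pure counting noise the theoretical line is slope 1, intercept 0;
    the fitted intercept measures depth-independent excess variance.
    Returns ``(slope, intercept)``.
    """
    Ns = np.asarray(Ns, dtype=float)
    var_hats = np.asarray(var_hats, dtype=float)
    if len(Ns) < 3:
        raise ValueError("need at least 3 depth points")
    x = 1.0 / Ns
    slope, intercept = np.polyfit(x, var_hats, 1)
    return float(slope), float(intercept)


def segment_snr(
    normalized: np.ndarray,
    segment: np.ndarray,
    chrom: np.ndarray | None = None,
    trim: float = 0.001,
) -> float:
    """Signal-to-noise ratio of a segment against the rest of the profile.

    SNR = |mean over segment - mean over baseline| / sigma_hat, with
    sigma_hat the trimmed first-order SD of the whole mean-scaled profile
    (which is insensitive to the step the segment itself introduces).
    """
    v = np.asarray(normalized, dtype=float)
    segment = np.asarray(segment, dtype=bool)
    finite = np.isfinite(v)
    seg = segment & finite
    base = ~segment & finite
    if not seg.any() or not base.any():
        raise ValueError("segment and baseline must both be non-empty")
    sig = abs(float(np.mean(v[seg])) - float(np.mean(v[base])))
    sigma = sigma_diff(v, chrom=chrom, trim=trim)
    return sig / sigma


@dataclass
class NoiseSummary:
    """Measured vs expected noise for one profile."""

    N: float
    sigma_hat: float
    expected_sigma: float

    @property
    def var_hat(self) -> float:
        return self.sigma_hat ** 2

    @property
    def excess_var(self) -> float:
        return self.var_hat - 1.0 / self.N


def noise_summary(
    profile: np.ndarray,
    raw: np.ndarray,
    usable: np.ndarray,
    chrom: np.ndarray | None = None,
    trim: float = 0.001,
) -> NoiseSummary:
    """Summarize noise of a corrected linear-scale profile.

    N is the mean *raw* reads per usable bin (the counting depth); sigma_hat
    is measured on the corrected profile restricted to usable bins.
    """
    v = np.where(usable, profile, np.nan)
    N = float(np.mean(np.asarray(raw, dtype=float)[usable]))
    return NoiseSummary(
        N=N,
        sigma_hat=sigma_diff(v, chrom=chrom, trim=trim),
        expected_sigma=expected_sigma(N),
    )
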