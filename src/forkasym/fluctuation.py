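"""Luria-Delbrück fluctuation analysis by the Lea-Coulson method of the median.

Parallel cultures grown from small inocula accumulate mutants in jackpot
fashion: a mutation arising early yields a large clone, so mutant counts
across cultures are heavy-tailed.  The Lea-Coulson method of the median
estimates the expected number of mutations per culture ``m`` from the
median mutant count ``r̃`` via the transcendental relation

    r̃/m − ln(m) = 1.24,

whose left side is strictly decreasing in ``m`` on (0, ∞), so the root is
unique and found by monotone bracketing.  The mutation rate per cell per
division is then ``m / Nt`` for final viable count ``Nt`` (the standard
approximation: cumulative divisions ≈ Nt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LEA_COULSON_CONST",
    "FluctuationExperiment",
    "RateEstimate",
    "lea_coulson_m",
    "estimate_rate_median",
    "fold_change",
]

LEA_COULSON_CONST = 1.24


@dataclass(frozen=True)
class FluctuationExperiment:
    """Mutant colony counts from parallel cultures of one fluctuation assay.

    Parameters
    ----------
    counts
        Mutant colonies per culture (r_i), one entry per culture.
    Nt
        Final viable cells per culture.
    plating_fraction
        Fraction of each culture actually plated on selective medium;
        the observed median is divided by it before solving.
    """

    counts: tuple[int, ...]
    Nt: float
    plating_fraction: float = 1.0

    def __init__(self, counts, Nt, plating_fraction=1.0):
        counts = tuple(int(c) for c in counts)
        if len(counts) < 2:
            raise ValueError("a fluctuation experiment needs at least 2 cultures")
        if any(c < 0 for c in counts):
            raise ValueError("mutant counts must be non-negative")
        if Nt <= 0:
            raise ValueError("Nt must be positive")
        if not 0 < plating_fraction <= 1:
            raise ValueError("plating_fraction must be in (0, 1]")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "Nt", float(Nt))
        object.__setattr__(self, "plating_fraction", float(plating_fraction))

    @property
    def n_cultures(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class RateEstimate:
    """Mutation-rate estimate from one fluctuation experiment.

    ``m`` is the expected number of mutations per culture; ``rate`` is
    mutations per cell per division (= m/Nt).  ``method`` records the
    statistic actually used: "median" for the Lea-Coulson solve, "p0"
    for the zero-fraction fallback when the median is 0.  For an
    all-zero experiment the estimate is censored: no point estimate,
    only ``rate_upper_bound`` (ln 2 / Nt scale).
    """

    m: float
    rate: float
    ci_low: float
    ci_high: float
    method: str = "median"
    censored: bool = False
    rate_upper_bound: float | None = None


def lea_coulson_m(median_count: float, rtol: float = 1e-10) -> float:
    """Solve r̃/m − ln(m) = 1.24 for m given the (corrected) median count.

    The left side decreases strictly in m, so a sign-bracketing interval
    is expanded log-wise from [1e-6, 1e6] if necessary and the root is
    polished to relative tolerance ``rtol``.
    """
    if median_count < 0:
        raise ValueError("median count must be non-negative")

    def f(m: float) -> float:
        return median_count / m - math.log(m) - LEA_COULSON_CONST

    lo, hi = 1e-6, 1e6
    while f(lo) < 0 and lo > 1e-300:
        lo /= 1e3
    while f(hi) > 0 and hi < 1e300:
        hi *= 1e3
    return float(brentq(f, lo, hi, rtol=rtol, xtol=1e-300))


def _point_estimate(counts: np.ndarray, plating_fraction: float) -> tuple[float, str]:
    """(m, method) for one vector of counts; NaN m if all-zero (censored)."""
    median = float(np.median(counts)) / plating_fraction
    if median > 0:
        return lea_coulson_m(median), "median"
    n_zero = int(np.count_nonzero(counts == 0))
    if n_zero == counts.size:
        return math.nan, "censored"
    # Median 0 with some positive cultures: fall back to the P0 method,
    # m = -ln(fraction of mutant-free cultures).
    return -math.log(n_zero / counts.size), "p0"


def estimate_rate_median(
    exp: FluctuationExperiment,
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> RateEstimate:
    """Estimate the mutation rate per cell division by the method of the median.

    Confidence bounds are percentile bootstrap over cultures (``n_boot``
    resamples; pass 0 to skip).  All-zero counts yield a censored
    estimate carrying only an upper bound.
    """
    counts = np.asarray(exp.counts)
    m, method = _point_estimate(counts, exp.plating_fraction)
    if method == "censored":
        return RateEstimate(
            m=math.nan,
            rate=math.nan,
            ci_low=math.nan,
            ci_high=math.nan,
            method="median",
            censored=True,
            rate_upper_bound=math.log(2) / exp.Nt,
        )
    rate = m / exp.Nt
    ci_low = ci_high = rate
    if n_boot > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.integers(0, counts.size, size=(n_boot, counts.size))
        resamples = counts[idx]
        medians = np.median(resamples, axis=1)
        n_zeros = np.count_nonzero(resamples == 0, axis=1)
        cache: dict[tuple[float, int], float] = {}
        ms = np.empty(n_boot)
        for i, (med, nz) in enumerate(zip(medians, n_zeros)):
            key = (float(med), int(nz))
            if key not in cache:
                med_corr = float(med) / exp.plating_fraction
                if med_corr > 0:
                    cache[key] = lea_coulson_m(med_corr)
                elif nz == counts.size:
                    cache[key] = math.nan
                else:
                    cache[key] = -math.log(nz / counts.size)
            ms[i] = cache[key]
        rates = ms / exp.Nt
        ci_low = float(np.nanpercentile(rates, 2.5))
        ci_high = float(np.nanpercentile(rates, 97.5))
        ci_low = min(ci_low, rate)
        ci_high = max(ci_high, rate)
    return RateEstimate(m=m, rate=rate, ci_low=ci_low, ci_high=ci_high, method=method)


def fold_change(a: RateEstimate, b: RateEstimate) -> float:
    """Fold elevation a.rate / b.rate.

    Returns NaN (undefined) when either estimate is censored and +inf
    when the denominator rate is exactly zero.
    """
    if a.censored or b.censored:
        return math.nan
    if b.rate == 0:
        return math.inf
    return a.rate / b.rate
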