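"""Divergence landscapes, activity intervals, dating and the burst test.

A divergence landscape is the bp-weighted distribution of per-copy K2P
divergences to consensus: a relative timeline of TE activity within one
genome.  Conservative activity boundaries are read off as central weighted
quantile intervals (95% by default, 99% as the maximum duration) and
converted to absolute ages by t = d / (2 mu), i.e. divergence over twice
the neutral substitution rate.  Two bursts of genome invasions are compared
with a two-sample t-test on the dated invasion minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .divergence import CopyDivergence
from .errors import HorizonteError

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class RateSpec:
    """A neutral substitution rate, per year or per generation.

    ``generation_time_days`` is used only for per-generation rates (e.g.
    nematode mutation-accumulation rates combined with a 90-day generation
    time).
    """

    value: float
    unit: Literal["per_year", "per_generation"] = "per_year"
    generation_time_days: float = 90.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise HorizonteError("substitution rate must be positive")
        if self.generation_time_days <= 0:
            raise HorizonteError("generation time must be positive")
        if self.unit not in ("per_year", "per_generation"):
            raise HorizonteError(f"unknown rate unit {self.unit!r}")

    def per_year(self) -> float:
        if self.unit == "per_year":
            return self.value
        return self.value * (DAYS_PER_YEAR / self.generation_time_days)

    def per_myr(self) -> float:
        return self.per_year() * 1e6


@dataclass(frozen=True)
class DivergenceLandscape:
    """bp-weighted divergence distribution for one taxon.

    The un-binned per-copy values are retained: quantiles are computed on
    them (weights = aligned bp), while ``bins()`` provides the contiguous
    left-closed right-open binning used for plotting.
    """

    taxon: str
    copies: tuple[CopyDivergence, ...]
    bin_width: float = 0.01

    def __post_init__(self) -> None:
        if not self.copies:
            raise HorizonteError("empty landscape")
        if self.bin_width <= 0:
            raise HorizonteError("bin_width must be positive")

    @property
    def total_bp(self) -> int:
        return sum(c.aligned_bp for c in self.copies)

    def values_weights(self) -> tuple[np.ndarray, np.ndarray]:
        d = np.array([c.d for c in self.copies], dtype=float)
        w = np.array([c.aligned_bp for c in self.copies], dtype=np.int64)
        return d, w

    def bins(self) -> tuple[np.ndarray, np.ndarray]:
        """(bin lower edges, per-bin bp), contiguous from 0."""
        d, w = self.values_weights()
        nbins = int(np.floor(d.max() / self.bin_width)) + 1
        counts = np.zeros(nbins, dtype=np.int64)
        idx = np.floor(d / self.bin_width).astype(int)
        np.add.at(counts, idx, w)
        lowers = np.arange(nbins) * self.bin_width
        return lowers, counts


def build_landscape(divs: Sequence[CopyDivergence],
                    bin_width: float = 0.01,
                    taxon: str = "") -> DivergenceLandscape:
    """Assemble a landscape; each copy contributes its aligned bp to the
    bin containing its divergence."""
    return DivergenceLandscape(taxon=taxon, copies=tuple(divs),
                               bin_width=bin_width)


@dataclass(frozen=True)
class ActivityInterval:
    """Central ``coverage`` interval of the weighted divergence
    distribution, in substitutions/site."""

    coverage: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise HorizonteError("interval lower exceeds upper")


def weighted_quantile(values: np.ndarray, weights: np.ndarray,
                      q: float) -> float:
    """Quantile of integer-weighted values, exactly equivalent to
    ``np.quantile`` (linear interpolation) on the list in which each value
    is repeated ``weight`` times — without materialising that list."""
    if not 0 <= q <= 1:
        raise HorizonteError("quantile must lie in [0, 1]")
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=np.int64)[order]
    if np.any(w <= 0):
        raise HorizonteError("weights must be positive integers")
    total = int(w.sum())
    if total == 1:
        return float(v[0])
    pos = q * (total - 1)            # fractional index into expanded list
    lo = int(np.floor(pos))
    hi = min(lo + 1, total - 1)
    cum = np.cumsum(w)               # cum[i]-1 = last expanded index of v[i]
    v_lo = v[np.searchsorted(cum, lo + 1)]
    v_hi = v[np.searchsorted(cum, hi + 1)]
    frac = pos - lo
    return float(v_lo * (1 - frac) + v_hi * frac)


def activity_interval(land: DivergenceLandscape,
                      coverage: float = 0.95,
                      side: Literal["central", "lower", "upper"] = "central",
                      ) -> ActivityInterval:
    """Conservative activity boundaries on the divergence scale.

    The default reads the central ``coverage`` interval: lower bound at the
    (1-coverage)/2 weighted quantile, upper at 1-(1-coverage)/2.  The upper
    boundary is the latest possible onset of activity (invasion minimum),
    the lower boundary the earliest possible end (extinction minimum).
    ``side='lower'``/``'upper'`` give one-sided intervals instead.
    """
    if not 0 < coverage <= 1:
        raise HorizonteError("coverage must lie in (0, 1]")
    d, w = land.values_weights()
    if side == "central":
        alpha = (1.0 - coverage) / 2.0
        lo, hi = alpha, 1.0 - alpha
    elif side == "lower":
        lo, hi = 0.0, coverage
    elif side == "upper":
        lo, hi = 1.0 - coverage, 1.0
    else:
        raise HorizonteError(f"unknown side {side!r}")
    return ActivityInterval(coverage=coverage,
                            lower=weighted_quantile(d, w, lo),
                            upper=weighted_quantile(d, w, hi))


def divergence_to_time(d: float, rate: RateSpec) -> float:
    """Absolute age in Myr: divergence over twice the substitution rate.

    Per-generation rates are first scaled to per-year using a 365.25-day
    year and the spec'd generation time.
    """
    if d < 0:
        raise HorizonteError("divergence must be non-negative")
    return d / (2.0 * rate.per_myr())


@dataclass(frozen=True)
class ActivityEstimate:
    """Dated activity boundaries for one taxon, in Myr.

    ``invasion_min``/``extinction_min`` come from the 95% interval (the
    conservative onset/end), ``invasion_max``/``extinction_max`` from the
    99% interval (maximum duration), ``mean_activity`` from the bp-weighted
    mean divergence.  For well-behaved landscapes
    invasion_max >= invasion_min >= mean_activity >= extinction_min >=
    extinction_max.
    """

    taxon: str
    invasion_min: float
    invasion_max: float
    extinction_min: float
    extinction_max: float
    mean_activity: float


def estimate_activity(land: DivergenceLandscape, rate: RateSpec,
                      coverage_min: float = 0.95,
                      coverage_max: float = 0.99) -> ActivityEstimate:
    """Convert a landscape into dated invasion/extinction estimates."""
    inner = activity_interval(land, coverage_min)
    outer = activity_interval(land, coverage_max)
    d, w = land.values_weights()
    mean_d = float(np.average(d, weights=w))
    return ActivityEstimate(
        taxon=land.taxon,
        invasion_min=divergence_to_time(inner.upper, rate),
        invasion_max=divergence_to_time(outer.upper, rate),
        extinction_min=divergence_to_time(inner.lower, rate),
        extinction_max=divergence_to_time(outer.lower, rate),
        mean_activity=divergence_to_time(mean_d, rate),
    )


@dataclass(frozen=True)
class WaveTestResult:
    """Two-sample t-test on invasion dates of two candidate bursts."""

    statistic: float
    pvalue: float
    df: float
    flavor: Literal["welch", "student"]
    n1: int = 0
    n2: int = 0


def wave_test(group1: Sequence[float], group2: Sequence[float],
              flavor: Literal["welch", "student"] = "welch",
              ) -> WaveTestResult:
    """Two-sided two-sample t-test on invasion-minimum dates (Myr).

    Welch (unequal variances) by default; Student's pooled-variance
    optionally.  If both groups are constant with equal means the test is
    degenerate and p = 1 by convention.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise HorizonteError("each group needs at least 2 dates")
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.std() == 0 and g2.std() == 0 and g1.mean() == g2.mean():
        df = (len(g1) + len(g2) - 2)
        return WaveTestResult(0.0, 1.0, float(df), flavor,
                              len(g1), len(g2))
    res = stats.ttest_ind(g1, g2, equal_var=(flavor == "student"))
    return WaveTestResult(float(res.statistic), float(res.pvalue),
                          float(res.df), flavor, len(g1), len(g2))


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def write_landscape_table(land: DivergenceLandscape,
                          path: str | Path) -> None:
    lowers, counts = land.bins()
    with open(path, "w") as fh:
        fh.write("bin_lower\tbp\n")
        for lo, bp in zip(lowers, counts):
            fh.write(f"{lo:.4f}\t{int(bp)}\n")


def write_activity_table(estimates: Sequence[ActivityEstimate],
                         path: str | Path) -> None:
    """Activity estimates, Myr to one decimal."""
    with open(path, "w") as fh:
        fh.write("taxon\tinvasion_min\tinvasion_max\textinction_min\t"
                 "extinction_max\tmean_activity\n")
        for est in estimates:
            fh.write(f"{est.taxon}\t{est.invasion_min:.1f}\t"
                     f"{est.invasion_max:.1f}\t{est.extinction_min:.1f}\t"
                     f"{est.extinction_max:.1f}\t{est.mean_activity:.1f}\n")


def plot_landscape(land: DivergenceLandscape, path: str | Path,
                   color: str = "firebrick") -> None:
    """Bar plot of the binned landscape (bp per divergence bin)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lowers, counts = land.bins()
    fig, ax = plt.subplots(figsize=(6, 2.5))
    ax.bar(lowers, counts, width=land.bin_width, align="edge",
           color=color, edgecolor="none")
    ax.set_xlabel("K2P divergence to consensus (CpG-excluded)")
    ax.set_ylabel("bp")
    ax.set_title(land.taxon)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
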