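"""Histogram analysis of the per-voxel BBBo summaries.

Over the voxels classified as BBBo, per-parameter histograms of Dyn, TT and
AOT characterize how strongly and how long the barrier opened.  The AOT
histogram in particular decays roughly exponentially — most voxels undergo
low-to-medium opening while strongly opened voxels are exponentially rare —
so an exponential model A * exp(-x / tau) is fit to the AOT counts, and
cumulative-fraction queries (percent of voxels with AOT below a threshold)
summarize the distribution's tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .bbbo import BBBoResult, ParamMaps

__all__ = [
    "Histogram",
    "HistogramSet",
    "ExponentialFit",
    "BinConfig",
    "InsufficientDataError",
    "build_histograms",
    "fit_exponential",
    "cumulative_fraction",
    "mean_sem_histograms",
    "calibrate_exponential_rate",
    "exponential_fraction_below",
]


class InsufficientDataError(ValueError):
    """Raised when too few nonempty bins (or values) support an operation."""


@dataclass(frozen=True)
class Histogram:
    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if e.ndim != 1 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if c.shape != (e.size - 1,) or np.any(c < 0):
            raise ValueError("counts must be nonnegative with len(edges)-1 entries")
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "counts", c)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class HistogramSet:
    """Per-parameter histograms over the BBBo voxels."""

    dyn: Histogram
    tt: Histogram
    aot: Histogram


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares fit of counts to A * exp(-x / tau)."""

    amplitude: float
    tau: float
    r2: float

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.amplitude < 0:
            raise ValueError("require tau > 0 and amplitude >= 0")


@dataclass(frozen=True)
class BinConfig:
    """Histogram bin widths: Dyn in %, TT in min, AOT in min x norm. units."""

    dyn_width: float = 2.5
    tt_width: float = 2.5
    aot_width: float = 0.2


def _bin_values(values: np.ndarray, width: float) -> Histogram:
    if values.size == 0:
        return Histogram(edges=np.array([0.0, width]), counts=np.array([0.0]))
    upper = max(float(values.max()), 0.0)
    n_bins = max(int(np.ceil((upper + 1e-12) / width)), 1)
    edges = width * np.arange(n_bins + 1, dtype=float)
    counts, _ = np.histogram(values, bins=edges)
    # values exactly at the last edge belong to the top bin
    counts[-1] += np.sum(values == edges[-1])
    return Histogram(edges=edges, counts=counts.astype(float))


def build_histograms(
    maps: ParamMaps, bbbo: BBBoResult, bins: BinConfig = BinConfig()
) -> HistogramSet:
    """Histogram Dyn/TT/AOT over BBBo voxels; counts always sum to n_voxels."""
    mask = bbbo.mask
    return HistogramSet(
        dyn=_bin_values(maps.dyn_map[mask], bins.dyn_width),
        tt=_bin_values(maps.tt_map[mask], bins.tt_width),
        aot=_bin_values(maps.aot_map[mask], bins.aot_width),
    )


def fit_exponential(hist: Histogram) -> ExponentialFit:
    """Fit A * exp(-x / tau) to counts at bin centers, through the last
    nonempty bin, by unweighted least squares on the raw counts."""
    nonempty = np.nonzero(hist.counts > 0)[0]
    if nonempty.size < 3:
        raise InsufficientDataError(
            f"exponential fit needs >= 3 nonempty bins, got {nonempty.size}"
        )
    stop = nonempty[-1] + 1
    x = hist.centers[:stop]
    y = hist.counts[:stop]

    def model(x, a, tau):
        return a * np.exp(-x / tau)

    a0 = float(y.max())
    tau0 = max(float(np.sum(x * y) / max(np.sum(y), 1e-12)), x[1] - x[0])
    popt, _ = curve_fit(
        model, x, y, p0=(a0, tau0),
        bounds=((0.0, 1e-9), (np.inf, np.inf)), maxfev=20000,
    )
    resid = model(x, *popt) - y
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    return ExponentialFit(amplitude=float(popt[0]), tau=float(popt[1]), r2=r2)


def cumulative_fraction(values: Sequence[float], threshold: float) -> float:
    """Percent of values strictly below ``threshold``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InsufficientDataError("cumulative fraction of an empty sample")
    return float(100.0 * np.mean(values < threshold))


def mean_sem_histograms(
    histograms: Sequence[Histogram],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bin-wise mean and SEM across subjects (group-average histogram).

    All histograms must share bin width and origin; shorter ones are
    zero-padded to the longest.  Returns (centers, mean, sem).
    """
    if not histograms:
        raise InsufficientDataError("no histograms to average")
    widths = {round(float(h.edges[1] - h.edges[0]), 12) for h in histograms}
    if len(widths) != 1:
        raise ValueError("histograms must share a common bin width")
    n_bins = max(h.counts.size for h in histograms)
    ref = max(histograms, key=lambda h: h.counts.size)
    stacked = np.zeros((len(histograms), n_bins))
    for i, h in enumerate(histograms):
        stacked[i, : h.counts.size] = h.counts
    mean = stacked.mean(axis=0)
    sem = (
        stacked.std(axis=0, ddof=1) / np.sqrt(len(histograms))
        if len(histograms) > 1
        else np.zeros(n_bins)
    )
    return ref.centers, mean, sem


def calibrate_exponential_rate(fraction_below: float, threshold: float) -> float:
    """Rate lambda of an exponential AOT distribution matching one quantile.

    Given that a fraction ``fraction_below`` (0..1) of voxels lie below
    ``threshold``, solve 1 - exp(-lambda * threshold) = fraction_below.
    """
    if not 0 < fraction_below < 1:
        raise ValueError("fraction_below must lie strictly in (0, 1)")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return -np.log(1.0 - fraction_below) / threshold


def exponential_fraction_below(threshold: float, rate: float) -> float:
    """Percent of an Exp(rate) population below ``threshold`` (CDF x 100)."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return float(100.0 * (1.0 - np.exp(-rate * max(threshold, 0.0))))
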