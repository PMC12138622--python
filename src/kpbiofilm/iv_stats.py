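"""Distributional statistics of cyclic-voltammetry current samples.

Cyclic voltammetry sweeps a triangular voltage and records current; the
pooled current sample across sweeps is summarized here by its first four
moments, box-plot quantiles with 1.5*IQR whiskers, and a maximum-likelihood
Gaussian profile.  Kurtosis uses the non-excess convention (Gaussian = 3)
so values like 2.80 read directly as "flatter than normal".

Because vertical segments of an I-V loop are oversampled in voltage, an
optional density-weighted resampler is provided that equalizes counts
across voltage bins before pooling; it is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError, FitError

logger = logging.getLogger(__name__)

__all__ = [
    "IVSweep",
    "MomentSummary",
    "BoxSummary",
    "GaussianFit",
    "summarize_moments",
    "box_summary",
    "fit_gaussian",
    "density_weighted_resample",
]


@dataclass
class IVSweep:
    """Paired voltage (V) / current (uA) arrays with per-point sweep index."""

    voltage: np.ndarray
    current: np.ndarray
    sweep_index: np.ndarray
    scan_rate: float | None = None  # mV/s, metadata
    sample_label: str = ""

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        self.sweep_index = np.asarray(self.sweep_index, dtype=int)
        if not (self.voltage.size == self.current.size == self.sweep_index.size):
            raise DataError("voltage, current, sweep_index must have equal length")
        if np.any(np.diff(self.sweep_index) < 0):
            raise DataError("sweep_index must be non-decreasing")

    @property
    def n_sweeps(self) -> int:
        return int(np.unique(self.sweep_index).size)


@dataclass
class MomentSummary:
    mean: float
    sd: float  # sample SD, n-1 denominator
    skewness: float  # standardized third central moment (n denominator)
    kurtosis: float  # non-excess: Gaussian -> 3
    n: int


@dataclass
class BoxSummary:
    q25: float
    q50: float
    q75: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray


@dataclass
class GaussianFit:
    """ML Gaussian profile f(x | mu, sigma_N)."""

    mu: float
    sigma_N: float  # sqrt of mean squared deviation (n denominator)
    log_likelihood: float

    def pdf(self, x: np.ndarray | float) -> np.ndarray | float:
        return sps.norm.pdf(x, loc=self.mu, scale=self.sigma_N)


def summarize_moments(values: np.ndarray) -> MomentSummary:
    """Mean, sample SD, and standardized third/fourth moments of a sample.

    Zero-variance input returns NaN skewness/kurtosis but still reports
    mean and SD.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("need at least 2 values")
    if not np.all(np.isfinite(v)):
        raise DataError("values must be finite")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd == 0.0:
        return MomentSummary(mean=mean, sd=sd, skewness=np.nan, kurtosis=np.nan, n=v.size)
    skew = float(sps.skew(v, bias=True))
    kurt = float(sps.kurtosis(v, fisher=False, bias=True))
    return MomentSummary(mean=mean, sd=sd, skewness=skew, kurtosis=kurt, n=v.size)


def box_summary(values: np.ndarray) -> BoxSummary:
    """Quartiles (linear interpolation) and Tukey whiskers at 1.5*IQR.

    Whiskers sit on the most extreme data points within 1.5*IQR of the
    quartiles; points beyond are flagged as outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise DataError("box_summary needs at least 5 values")
    q25, q50, q75 = np.quantile(v, [0.25, 0.50, 0.75], method="linear")
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxSummary(
        q25=float(q25),
        q50=float(q50),
        q75=float(q75),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=outliers,
    )


def fit_gaussian(values: np.ndarray) -> GaussianFit:
    """Maximum-likelihood Gaussian: mu = sample mean, sigma_N with n denominator."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("need at least 2 values")
    mu = float(v.mean())
    sigma = float(v.std(ddof=0))
    if sigma == 0.0:
        raise FitError("zero variance: Gaussian fit undefined")
    ll = float(np.sum(sps.norm.logpdf(v, loc=mu, scale=sigma)))
    return GaussianFit(mu=mu, sigma_N=sigma, log_likelihood=ll)


def density_weighted_resample(
    sweep: IVSweep, n_bins: int, seed: int = 0
) -> np.ndarray:
    """Correct CV sampling bias by resampling equal counts per voltage bin.

    Points are binned by voltage into ``n_bins`` equal-width bins; each
    non-empty bin contributes the same number of bootstrap draws (with
    replacement), so voltage regions oversampled by slow sweep segments no
    longer dominate the pooled current sample.  Empty bins are skipped with
    a logged note.  ``n_bins = 1`` is a plain bootstrap of the full sample.
    """
    if n_bins < 1:
        raise DataError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    v, i = sweep.voltage, sweep.current
    edges = np.linspace(v.min(), v.max(), n_bins + 1)
    # rightmost edge inclusive
    which = np.clip(np.digitize(v, edges) - 1, 0, n_bins - 1)
    occupied = [b for b in range(n_bins) if np.any(which == b)]
    n_empty = n_bins - len(occupied)
    if n_empty:
        logger.info("density_weighted_resample: skipped %d empty voltage bins", n_empty)
    per_bin = max(1, int(round(v.size / len(occupied))))
    out = []
    for b in occupied:
        pool = i[which == b]
        out.append(rng.choice(pool, size=per_bin, replace=True))
    return np.concatenate(out)
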