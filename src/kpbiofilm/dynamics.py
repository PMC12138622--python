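"""Nonlinear characterization of bioelectric potential time series.

The composite-biofilm recordings analysed here are slow (~1 Hz sampled)
extracellular potential traces.  This module provides the standard
nonlinear-dynamics toolbox applied to them: binned Shannon entropy,
time-delay (Takens) embedding and phase portraits, a Rosenstein-style
largest Lyapunov exponent, a Grassberger-Procaccia correlation dimension,
normalized cross-correlation and percentile-extremes summaries.

All estimators are deterministic given the trace and configuration;
randomness lives only in trace generation (see :mod:`kpbiofilm.synthetic_data`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .errors import DataError, EstimationError, ParameterError

__all__ = [
    "SignalTrace",
    "EntropyResult",
    "EmbeddingConfig",
    "DynamicsSummary",
    "shannon_entropy",
    "delay_embed",
    "estimate_tau",
    "largest_lyapunov",
    "correlation_dimension",
    "cross_correlation",
    "percentile_extremes",
    "summarize_dynamics",
]


@dataclass
class SignalTrace:
    """A potential time series: time in seconds, potential in millivolts."""

    time: np.ndarray
    potential: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        if self.time.shape != self.potential.shape:
            raise DataError("time and potential must have equal length")
        if self.time.size < 2:
            raise DataError("trace needs at least 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def sampling_rate(self) -> float:
        """Sampling rate in Hz derived from the median time step."""
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class EntropyResult:
    """Binned Shannon entropy H = -sum p_i log2 p_i of a potential trace."""

    H: float
    n_bins: int
    bin_edges: np.ndarray
    occupancy: np.ndarray


@dataclass
class EmbeddingConfig:
    """Time-delay embedding parameters: lag tau (samples), dimension m."""

    tau: int
    m: int
    theiler_window: int | None = None

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ParameterError("tau must be >= 1 sample")
        if self.m < 2:
            raise ParameterError("embedding dimension m must be >= 2")
        if self.theiler_window is None:
            # default Theiler exclusion = one lag
            self.theiler_window = self.tau
        if self.theiler_window < 0:
            raise ParameterError("theiler_window must be >= 0")


@dataclass
class DynamicsSummary:
    largest_le: float
    correlation_dimension: float
    entropy_bits: float
    embedding: EmbeddingConfig
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def shannon_entropy(
    trace: SignalTrace,
    n_bins: int = 8,
    range_mode: str = "observed",
    fixed_range: tuple[float, float] | None = None,
) -> EntropyResult:
    """Shannon entropy of the amplitude distribution over equal-width bins.

    ``range_mode='observed'`` bins over [min, max] of the trace (default).
    ``range_mode='fixed'`` bins over ``fixed_range``; samples outside the
    range are clipped into the edge bins, so a signal confined well inside
    one bin of a wide absolute range yields 0 bits.

    A constant trace occupies a single bin and returns exactly 0 bits.
    """
    if n_bins < 2:
        raise ParameterError("n_bins must be >= 2")
    v = trace.potential
    if v.size == 0:
        raise DataError("empty trace")
    if v.size < n_bins:
        warnings.warn(
            f"trace has {v.size} samples < {n_bins} bins; entropy is unreliable",
            stacklevel=2,
        )
    if range_mode == "observed":
        lo, hi = float(v.min()), float(v.max())
    elif range_mode == "fixed":
        if fixed_range is None:
            raise ParameterError("range_mode='fixed' requires fixed_range")
        lo, hi = map(float, fixed_range)
        if not lo < hi:
            raise ParameterError("fixed_range must be increasing")
    else:
        raise ParameterError(f"unknown range_mode {range_mode!r}")

    if lo == hi:  # constant trace: single occupied bin, H = 0 by convention
        edges = np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
        occ = np.zeros(n_bins)
        occ[0] = 1.0
        return EntropyResult(H=0.0, n_bins=n_bins, bin_edges=edges, occupancy=occ)

    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(np.clip(v, lo, hi), bins=edges)
    p = counts / counts.sum()
    nz = p[p > 0]
    H = float(-(nz * np.log2(nz)).sum())  # 0*log 0 := 0
    return EntropyResult(H=H, n_bins=n_bins, bin_edges=edges, occupancy=p)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def delay_embed(trace: SignalTrace, cfg: EmbeddingConfig) -> np.ndarray:
    """Takens delay embedding x_i = [s(t_i), s(t_i+tau), ..., s(t_i+(m-1)tau)].

    Returns an array of shape (n - (m-1)*tau, m).  With m = 2 the rows are
    the (V(t), V(t+tau)) phase-portrait coordinates.
    """
    s = trace.potential
    n_pts = s.size - (cfg.m - 1) * cfg.tau
    if n_pts < 1:
        raise DataError(
            f"trace too short for embedding: need > {(cfg.m - 1) * cfg.tau} samples"
        )
    return np.column_stack([s[i * cfg.tau : i * cfg.tau + n_pts] for i in range(cfg.m)])


def estimate_tau(trace: SignalTrace, method: str = "acf_zero") -> int:
    """Embedding lag from the first zero crossing of the autocorrelation.

    Falls back to max(1, n//20) when the autocorrelation never crosses zero
    (e.g. strongly trended or constant traces).  Deterministic.
    """
    if method != "acf_zero":
        raise ParameterError(f"unknown tau estimation method {method!r}")
    v = trace.potential
    n = v.size
    if n < 50:
        raise DataError("estimate_tau needs at least 50 samples")
    x = v - v.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:  # constant trace: autocorrelation undefined
        return max(1, n // 20)
    acf = np.correlate(x, x, mode="full")[n - 1 :] / denom
    crossings = np.nonzero(acf <= 0)[0]
    if crossings.size == 0:
        return max(1, n // 20)
    return int(max(1, crossings[0]))


# ---------------------------------------------------------------------------
# largest Lyapunov exponent (Rosenstein)
# ---------------------------------------------------------------------------

def largest_lyapunov(
    trace: SignalTrace,
    cfg: EmbeddingConfig,
    fit_range: tuple[int, int] = (0, 8),
) -> float:
    """Largest Lyapunov exponent per sample, Rosenstein nearest-neighbor method.

    For every embedded point the nearest neighbor outside the Theiler window
    is found; the mean log pairwise distance is tracked over ``fit_range``
    steps and the least-squares slope of that divergence curve is returned.
    Positive values indicate exponential trajectory divergence (chaos);
    values <= 0 indicate regular (fixed-point / limit-cycle) dynamics.

    Distances are floored at 1e-10 of the attractor diameter so exactly
    recurrent (periodic) trajectories yield a flat curve and a zero slope
    instead of floating-point log noise.
    """
    if trace.n < 500:
        warnings.warn("largest_lyapunov: n < 500, estimate may be unreliable", stacklevel=2)
    k_lo, k_hi = fit_range
    if not (0 <= k_lo < k_hi):
        raise ParameterError("fit_range must satisfy 0 <= lo < hi")
    emb = delay_embed(trace, cfg)
    n = emb.shape[0]
    n_base = n - k_hi
    if n_base < 2:
        raise DataError("trace too short for the requested fit_range")
    w = cfg.theiler_window

    scale = float(np.ptp(trace.potential)) * np.sqrt(cfg.m)
    if scale == 0.0:
        raise EstimationError("constant trace has no divergence to measure")
    floor = 1e-10 * scale

    tree = cKDTree(emb[:n_base])
    k_query = min(2 * w + 5, n_base)
    dists, idxs = tree.query(emb[:n_base], k=k_query)
    nn = np.full(n_base, -1, dtype=int)
    for i in range(n_base):
        for j in idxs[i]:
            if abs(int(j) - i) > w:
                nn[i] = int(j)
                break
    valid = nn >= 0
    if not valid.any():
        raise EstimationError("no neighbor pairs outside the Theiler window")
    i_ref = np.nonzero(valid)[0]
    j_ref = nn[valid]

    ks = np.arange(k_lo, k_hi + 1)
    y = np.empty(ks.size)
    for out, k in enumerate(ks):
        d = np.linalg.norm(emb[i_ref + k] - emb[j_ref + k], axis=1)
        y[out] = float(np.mean(np.log(np.maximum(d, floor))))
    coeffs = np.polyfit(ks, y, 1)
    slope = float(coeffs[0])
    # below the resolution of the log-divergence curve (distance floor),
    # divergence is indistinguishable from zero
    if abs(slope) < 1e-9:
        return 0.0
    return slope


# ---------------------------------------------------------------------------
# correlation dimension (Grassberger-Procaccia)
# ---------------------------------------------------------------------------

def correlation_dimension(
    trace: SignalTrace,
    cfg: EmbeddingConfig,
    r_grid: np.ndarray | None = None,
    max_points: int = 1500,
    scaling_region: tuple[int, int] | None = None,
) -> float:
    """Correlation dimension D2 from the Grassberger-Procaccia sum.

    C(r) = fraction of point pairs (Theiler-excluded) within distance r;
    D2 is the slope of log C(r) vs log r over the scaling region.  The
    scaling region defaults to the longest contiguous log-log segment whose
    local slopes vary by less than 10% of their mean; pass ``scaling_region``
    (index bounds into the radius grid) to override.
    """
    if trace.n < 500:
        warnings.warn("correlation_dimension: n < 500, estimate may be unreliable", stacklevel=2)
    if float(np.ptp(trace.potential)) == 0.0:
        raise EstimationError("constant trace: correlation dimension undefined")
    emb = delay_embed(trace, cfg)
    n = emb.shape[0]
    if n > max_points:  # O(n^2) distances: decimate uniformly
        pos = np.linspace(0, n - 1, max_points).astype(int)
        emb = emb[pos]
    else:
        pos = np.arange(n)

    d = pdist(emb)
    # pairwise |i-j| in original sample indices for the Theiler exclusion
    ii, jj = np.triu_indices(pos.size, k=1)
    sep = np.abs(pos[ii] - pos[jj])
    d = d[sep > cfg.theiler_window]
    d = d[d > 0]
    if d.size < 100:
        raise EstimationError("too few valid pairs for the correlation sum")

    if r_grid is None:
        lo, hi = np.quantile(d, [0.01, 0.5])
        r_grid = np.geomspace(max(lo, 1e-12), hi, 24)
    r_grid = np.asarray(r_grid, dtype=float)
    d_sorted = np.sort(d)
    C = np.searchsorted(d_sorted, r_grid, side="right") / d.size
    good = C > 0
    log_r, log_C = np.log(r_grid[good]), np.log(C[good])
    if log_r.size < 4:
        raise EstimationError("correlation sum empty over the radius grid")

    if scaling_region is None:
        a, b = _auto_scaling_region(log_r, log_C)
    else:
        a, b = scaling_region
    coeffs = np.polyfit(log_r[a : b + 1], log_C[a : b + 1], 1)
    return float(coeffs[0])


def _auto_scaling_region(log_r: np.ndarray, log_C: np.ndarray) -> tuple[int, int]:
    """Longest contiguous window with local-slope variation < 10% of its mean."""
    slopes = np.diff(log_C) / np.diff(log_r)
    n_s = slopes.size
    best = (0, min(2, n_s))  # fallback: first few segments
    best_len = 0
    for a in range(n_s):
        for b in range(a + 2, n_s + 1):
            win = slopes[a:b]
            mean = win.mean()
            if mean <= 0:
                continue
            if (win.max() - win.min()) <= 0.10 * mean and (b - a) > best_len:
                best, best_len = (a, b), b - a
    a, b = best
    return a, b  # segment [a, b] spans grid points a .. b (inclusive of b)


# ---------------------------------------------------------------------------
# linear comparisons
# ---------------------------------------------------------------------------

def cross_correlation(a: SignalTrace, b: SignalTrace, max_lag: int) -> np.ndarray:
    """Normalized cross-correlation in [-1, 1] for lags -max_lag..+max_lag.

    Positive lag means b is shifted later than a.  Zero-variance inputs
    yield an all-NaN result (undefined markers).
    """
    if abs(a.sampling_rate - b.sampling_rate) > 0.01 * a.sampling_rate:
        raise DataError("traces must share a sampling rate")
    x = a.potential - a.potential.mean()
    y = b.potential - b.potential.mean()
    n = min(x.size, y.size)
    x, y = x[:n], y[:n]
    sx, sy = x.std(), y.std()
    lags = np.arange(-max_lag, max_lag + 1)
    if sx == 0.0 or sy == 0.0:
        return np.full(lags.size, np.nan)
    out = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            xs, ys = x[: n - lag], y[lag:]
        else:
            xs, ys = x[-lag:], y[: n + lag]
        out[i] = float(np.mean(xs * ys) / (sx * sy))
    return out


def percentile_extremes(
    trace: SignalTrace, lo: float = 25.0, hi: float = 75.0
) -> tuple[float, float, float]:
    """Interpolated percentiles (linear rule) and their spread q_hi - q_lo."""
    if trace.n < 4:
        raise DataError("percentile_extremes needs at least 4 samples")
    v_lo, v_hi = np.percentile(trace.potential, [lo, hi], method="linear")
    return float(v_lo), float(v_hi), float(v_hi - v_lo)


def summarize_dynamics(
    trace: SignalTrace,
    cfg: EmbeddingConfig | None = None,
    n_bins: int = 8,
    fit_range: tuple[int, int] = (0, 8),
) -> DynamicsSummary:
    """One-call characterization: entropy, largest LE and D2 for a trace."""
    if cfg is None:
        tau = estimate_tau(trace)
        cfg = EmbeddingConfig(tau=tau, m=2)
    ent = shannon_entropy(trace, n_bins=n_bins)
    le = largest_lyapunov(trace, cfg, fit_range=fit_range)
    d2 = correlation_dimension(trace, cfg)
    return DynamicsSummary(
        largest_le=le,
        correlation_dimension=d2,
        entropy_bits=ent.H,
        embedding=cfg,
    )
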