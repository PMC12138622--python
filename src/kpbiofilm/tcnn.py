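"""Temporal-coding neural-network objects built from potential recordings.

A recording of two biofilm samples is an (n, 2) potential matrix p over a
shared time vector t.  Each neuron owns a contiguous time block of one
sample column; its temporal code c[j, i] is the indicator p[i, col] > theta
(strict), and a companion latency-weight matrix stores T minus the time
since the column's first suprathreshold sample (clipped to [0, T]) wherever
the code fires.  Synaptic weight matrices W in [-1, 1]^(N x N) are
initialized either i.i.d. uniform or from the correlation of code rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, ParameterError

__all__ = [
    "PotentialMatrix",
    "TemporalCodeMatrix",
    "WeightMatrix",
    "ActivationModel",
    "temporal_encode",
    "init_weights",
    "activate",
    "export_heatmap",
    "load_weights",
]

ACTIVATIONS = ("identity", "sigmoid", "tanh", "step")


@dataclass
class PotentialMatrix:
    """Time vector (s) and per-sample potential columns (V)."""

    t: np.ndarray
    p: np.ndarray  # shape (n, n_samples); typically n_samples = 2

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim == 1:
            self.p = self.p[:, None]
        if self.t.size != self.p.shape[0]:
            raise DataError("t and rows of p must align")
        if np.any(np.diff(self.t) <= 0):
            raise DataError("t must be strictly increasing")
        if not np.all(np.isfinite(self.p)):
            raise DataError("p must be finite")


@dataclass
class TemporalCodeMatrix:
    c: np.ndarray  # binary, (N, n)
    latency_weight: np.ndarray  # seconds, (N, n); 0 where c = 0
    theta: float
    T: float
    N: int
    neuron_columns: np.ndarray  # sample column owned by each neuron


@dataclass
class WeightMatrix:
    W: np.ndarray  # (N, N), entries in [-1, 1]
    scheme: str
    seed: int


@dataclass
class ActivationModel:
    w: np.ndarray
    b: float
    f: str = "identity"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.f not in ACTIVATIONS:
            raise ParameterError(f"activation must be one of {ACTIVATIONS}")


def _neuron_blocks(n: int, n_cols: int, N: int) -> list[tuple[int, slice]]:
    """Assign N neurons to contiguous equal-length time blocks per column.

    Neurons are split as evenly as possible across sample columns; within a
    column each neuron owns a contiguous slice of the n time samples.
    """
    per_col = [N // n_cols + (1 if k < N % n_cols else 0) for k in range(n_cols)]
    blocks: list[tuple[int, slice]] = []
    for col, n_neur in enumerate(per_col):
        if n_neur == 0:
            continue
        edges = np.linspace(0, n, n_neur + 1).astype(int)
        for j in range(n_neur):
            blocks.append((col, slice(edges[j], edges[j + 1])))
    return blocks


def temporal_encode(
    pm: PotentialMatrix, theta: float, T: float, N: int
) -> TemporalCodeMatrix:
    """Spike-encode a potential matrix: c[j, i] = 1 iff p[i, col_j] > theta.

    The indicator is strict, so a potential exactly at the threshold does
    not spike.  The latency weight of a spiking entry is
    clip(T - (t_i - t_first), 0, T) where t_first is the time of the
    column's first suprathreshold sample: early spikes within the coding
    window T carry the largest weight.
    """
    if T <= 0:
        raise ParameterError("time window T must be > 0")
    if N < 1:
        raise ParameterError("N must be >= 1")
    n, n_cols = pm.p.shape
    blocks = _neuron_blocks(n, n_cols, N)
    c = np.zeros((N, n), dtype=int)
    lw = np.zeros((N, n), dtype=float)
    spikes = pm.p > theta  # (n, n_cols), strict
    # first suprathreshold time per column
    t_first = np.full(n_cols, np.nan)
    for col in range(n_cols):
        idx = np.nonzero(spikes[:, col])[0]
        if idx.size:
            t_first[col] = pm.t[idx[0]]
    for j, (col, sl) in enumerate(blocks):
        c[j, sl] = spikes[sl, col]
        if np.isfinite(t_first[col]):
            offs = pm.t[sl] - t_first[col]
            lw[j, sl] = np.where(c[j, sl] == 1, np.clip(T - offs, 0.0, T), 0.0)
    cols = np.array([col for col, _ in blocks], dtype=int)
    return TemporalCodeMatrix(c=c, latency_weight=lw, theta=theta, T=T, N=N, neuron_columns=cols)


def init_weights(
    N: int,
    scheme: str = "uniform",
    seed: int = 0,
    code: TemporalCodeMatrix | None = None,
) -> WeightMatrix:
    """Initial synaptic weights in [-1, 1]^(N x N).

    ``uniform``: i.i.d. uniform on [-1, 1].  ``code_correlation``: W_ij is
    the Pearson correlation of code rows i and j (0 for zero-variance rows),
    clipped to [-1, 1]; this produces the structured heatmap patterns seen
    when weights are seeded from recorded activity.
    """
    if N < 1:
        raise ParameterError("N must be >= 1")
    if scheme == "uniform":
        rng = np.random.default_rng(seed)
        W = rng.uniform(-1.0, 1.0, size=(N, N))
    elif scheme == "code_correlation":
        if code is None:
            raise ParameterError("code_correlation scheme requires a code matrix")
        if code.c.shape[0] != N:
            raise ParameterError("code matrix row count must equal N")
        rows = code.c.astype(float)
        sd = rows.std(axis=1)
        W = np.zeros((N, N))
        ok = sd > 0
        if ok.any():
            corr = np.corrcoef(rows[ok])
            corr = np.atleast_2d(corr)
            W[np.ix_(ok, ok)] = corr
        np.fill_diagonal(W, np.where(ok, 1.0, 0.0))
        W = np.clip(W, -1.0, 1.0)
    else:
        raise ParameterError(f"unknown weight scheme {scheme!r}")
    return WeightMatrix(W=W, scheme=scheme, seed=seed)


def activate(model: ActivationModel, x: np.ndarray) -> float:
    """Single-unit response y = f(w . x + b)."""
    x = np.asarray(x, dtype=float)
    if x.shape != model.w.shape:
        raise TypeError("input vector length must match weight vector length")
    pre = float(np.dot(model.w, x) + model.b)
    if model.f == "identity":
        return pre
    if model.f == "sigmoid":
        return float(1.0 / (1.0 + np.exp(-pre)))
    if model.f == "tanh":
        return float(np.tanh(pre))
    # step: right-open convention, boundary pre = 0 maps to 0
    return 1.0 if pre > 0 else 0.0


def export_heatmap(wm: WeightMatrix, path: str | Path) -> Path:
    """Write a PNG heatmap of W on a fixed [-1, 1] color scale plus a JSON
    sidecar carrying the exact matrix; returns the PNG path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(wm.W, cmap="coolwarm", vmin=-1.0, vmax=1.0, interpolation="nearest")
    ax.set_xlabel("postsynaptic neuron")
    ax.set_ylabel("presynaptic neuron")
    fig.colorbar(im, ax=ax, label="synaptic weight")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"W": wm.W.tolist(), "scheme": wm.scheme, "seed": wm.seed})
    )
    return path


def load_weights(json_path: str | Path) -> WeightMatrix:
    data = json.loads(Path(json_path).read_text())
    return WeightMatrix(W=np.array(data["W"], dtype=float), scheme=data["scheme"], seed=data["seed"])
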