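"""Delimited-text readers/writers for traces, sweeps and spectra.

All tabular files are plain CSV with a one-line header naming the columns
and their units (``time_s,potential_mV`` etc.).  An optional JSON sidecar
(<stem>.json) carries generator parameters, the seed and unit metadata so
provenance round-trips through file I/O.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SignalTrace
from .impedance import ImpedanceSpectrum
from .iv_stats import IVSweep

__all__ = [
    "write_trace",
    "read_trace",
    "write_iv",
    "read_iv",
    "write_spectrum",
    "read_spectrum",
    "write_sidecar",
    "read_sidecar",
]


def write_sidecar(path: str | Path, meta: dict) -> Path:
    side = Path(path).with_suffix(".json")
    side.write_text(json.dumps(meta, indent=2, default=float))
    return side


def read_sidecar(path: str | Path) -> dict | None:
    side = Path(path).with_suffix(".json")
    if not side.exists():
        return None
    return json.loads(side.read_text())


def write_trace(trace: SignalTrace, path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "potential_mV": trace.potential}).to_csv(
        path, index=False
    )
    sidecar = {"label": trace.label, "units": {"time": "s", "potential": "mV"}}
    if meta:
        sidecar.update(meta)
    write_sidecar(path, sidecar)
    return path


def read_trace(path: str | Path) -> SignalTrace:
    df = pd.read_csv(path)
    meta = read_sidecar(path) or {}
    return SignalTrace(
        time=df["time_s"].to_numpy(),
        potential=df["potential_mV"].to_numpy(),
        label=meta.get("label", ""),
    )


def write_iv(sweep: IVSweep, path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "voltage_V": sweep.voltage,
            "current_uA": sweep.current,
            "sweep": sweep.sweep_index,
        }
    ).to_csv(path, index=False)
    sidecar = {
        "sample_label": sweep.sample_label,
        "scan_rate_mV_per_s": sweep.scan_rate,
        "units": {"voltage": "V", "current": "uA"},
    }
    if meta:
        sidecar.update(meta)
    write_sidecar(path, sidecar)
    return path


def read_iv(path: str | Path) -> IVSweep:
    df = pd.read_csv(path)
    meta = read_sidecar(path) or {}
    return IVSweep(
        voltage=df["voltage_V"].to_numpy(),
        current=df["current_uA"].to_numpy(),
        sweep_index=df["sweep"].to_numpy(),
        scan_rate=meta.get("scan_rate_mV_per_s"),
        sample_label=meta.get("sample_label", ""),
    )


def write_spectrum(spec: ImpedanceSpectrum, path: str | Path, meta: dict | None = None) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "freq_Hz": spec.frequency,
            "capacitance_F": spec.capacitance,
            "phase_deg": spec.phase_angle,
        }
    ).to_csv(path, index=False)
    sidecar = {
        "signal_level_Vrms": spec.signal_level,
        "units": {"frequency": "Hz", "capacitance": "F", "phase": "deg"},
    }
    if meta:
        sidecar.update(meta)
    write_sidecar(path, sidecar)
    return path


def read_spectrum(path: str | Path) -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    meta = read_sidecar(path) or {}
    return ImpedanceSpectrum(
        frequency=df["freq_Hz"].to_numpy(),
        capacitance=df["capacitance_F"].to_numpy(),
        phase_angle=df["phase_deg"].to_numpy(),
        signal_level=meta.get("signal_level_Vrms", 1.0),
    )


def write_image(image: np.ndarray, path: str | Path, meta: dict | None = None) -> Path:
    """Write a [0, 1] grayscale image as 8-bit PNG with a JSON sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, (np.clip(image, 0, 1) * 255).astype(np.uint8))
    if meta:
        write_sidecar(path, meta)
    return path
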