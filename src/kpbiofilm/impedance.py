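"""Conductivity from impedance spectra via a parallel-RC equivalent circuit.

An LCR meter reports, per frequency, an effective capacitance C and the
phase angle phi between current and voltage.  Modelling the biofilm as a
resistor R in parallel with a capacitor C gives Z = R / (1 + j*omega*R*C)
and tan(phi) = omega*R*C, from which a conductivity-like quantity follows:

    sigma = k * cos(phi) / (omega * C)

with omega = 2*pi*f and k a geometric cell constant (1/cm, default 1)
converting conductance to S/cm.  The printed form of this relation is
typographically ambiguous (the sqrt(1 + tan^2 phi) factor can be read as
multiplying or dividing), so two alternative variants are selectable; all
variants coincide at phi = 0.

Frequency-selective "conduction spikes" -- contiguous bands where sigma
exceeds a fold-change threshold over the baseline quantile -- are detected
on the resulting conductivity spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DomainError, ParameterError

__all__ = [
    "ImpedanceSpectrum",
    "RCModel",
    "ConductivitySpectrum",
    "ConductionSpike",
    "conductivity_from_capacitance",
    "rc_impedance",
    "magnitude_phase",
    "detect_conduction_spikes",
]

FORMULA_VARIANTS = ("cos", "mult_sqrt", "no_sqrt")


@dataclass
class ImpedanceSpectrum:
    """Per-frequency capacitance (F) and phase angle (degrees)."""

    frequency: np.ndarray
    capacitance: np.ndarray
    phase_angle: np.ndarray
    signal_level: float = 1.0  # V RMS, metadata

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.capacitance = np.asarray(self.capacitance, dtype=float)
        self.phase_angle = np.asarray(self.phase_angle, dtype=float)
        if not (self.frequency.size == self.capacitance.size == self.phase_angle.size):
            raise DataError("frequency, capacitance, phase_angle must have equal length")
        if np.any(self.frequency < 0) or np.any(np.diff(self.frequency) <= 0):
            raise DataError("frequency must be strictly increasing and >= 0")
        if np.any(np.abs(self.phase_angle) >= 90):
            raise DomainError("|phase_angle| must be < 90 degrees")


@dataclass
class RCModel:
    """Parallel RC equivalent circuit: R in ohms, C in farads."""

    resistance: float
    capacitance: float

    def __post_init__(self) -> None:
        if self.resistance <= 0 or self.capacitance <= 0:
            raise ParameterError("resistance and capacitance must be > 0")


@dataclass
class ConductivitySpectrum:
    frequency: np.ndarray
    sigma: np.ndarray  # S/cm; NaN marks undefined rows (f = 0)
    cell_constant: float = 1.0

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.frequency.size != self.sigma.size:
            raise DataError("frequency and sigma must have equal length")


@dataclass
class ConductionSpike:
    """A contiguous frequency band of elevated conductivity."""

    f_lo: float
    f_hi: float
    baseline_sigma: float
    peak_sigma: float
    fold_change: float


def conductivity_from_capacitance(
    spec: ImpedanceSpectrum,
    cell_constant: float = 1.0,
    formula_variant: str = "cos",
) -> ConductivitySpectrum:
    """Convert a capacitance/phase spectrum to conductivity.

    Default variant: sigma = k * cos(phi) / (omega * C), the reading
    1/(omega*C*sqrt(1+tan^2 phi)) of the parallel-RC relation, which
    accounts for both resistive and reactive contributions.  Variants
    ``mult_sqrt`` (k*sqrt(1+tan^2 phi)/(omega*C)) and ``no_sqrt``
    (k/(omega*C)) expose the typographic ambiguity of the printed form.

    Rows with f = 0 yield sigma = NaN (undefined, DC has omega = 0).
    """
    if formula_variant not in FORMULA_VARIANTS:
        raise ParameterError(f"formula_variant must be one of {FORMULA_VARIANTS}")
    if np.any(spec.capacitance <= 0):
        raise DataError("capacitance must be > 0 at every frequency")
    omega = 2.0 * np.pi * spec.frequency
    phi = np.deg2rad(spec.phase_angle)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.where(omega > 0, 1.0 / (omega * spec.capacitance), np.nan)
        if formula_variant == "cos":
            sigma = cell_constant * np.cos(phi) * base
        elif formula_variant == "mult_sqrt":
            sigma = cell_constant * np.sqrt(1.0 + np.tan(phi) ** 2) * base
        else:  # no_sqrt
            sigma = cell_constant * base
    return ConductivitySpectrum(
        frequency=spec.frequency.copy(), sigma=sigma, cell_constant=cell_constant
    )


def rc_impedance(model: RCModel, frequency: np.ndarray | float) -> np.ndarray | complex:
    """Complex impedance Z = R / (1 + j*omega*R*C) of the parallel RC circuit."""
    f = np.asarray(frequency, dtype=float)
    if np.any(f < 0):
        raise ParameterError("frequency must be >= 0")
    omega = 2.0 * np.pi * f
    z = model.resistance / (1.0 + 1j * omega * model.resistance * model.capacitance)
    if np.isscalar(frequency):
        return complex(z)
    return z


def magnitude_phase(z: np.ndarray | complex) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude (ohms) and phase (degrees) of a complex impedance."""
    z = np.asarray(z)
    return np.abs(z), np.rad2deg(np.angle(z))


def detect_conduction_spikes(
    cs: ConductivitySpectrum,
    min_fold: float = 100.0,
    baseline_quantile: float = 0.25,
) -> list[ConductionSpike]:
    """Find contiguous frequency bands where sigma >= min_fold * baseline.

    The baseline is the given quantile of the (finite) conductivity values,
    so detection is invariant to uniform rescaling of sigma.  A flat
    spectrum returns an empty list.
    """
    finite = np.isfinite(cs.sigma)
    if finite.sum() < 10:
        raise DataError("need at least 10 finite frequency points")
    if min_fold <= 1:
        raise ParameterError("min_fold must be > 1")
    baseline = float(np.quantile(cs.sigma[finite], baseline_quantile))
    if baseline <= 0:
        raise DataError("baseline conductivity must be > 0 for fold-change detection")
    hot = finite & (cs.sigma >= min_fold * baseline)
    spikes: list[ConductionSpike] = []
    i = 0
    n = cs.sigma.size
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            peak = float(np.nanmax(cs.sigma[i : j + 1]))
            spikes.append(
                ConductionSpike(
                    f_lo=float(cs.frequency[i]),
                    f_hi=float(cs.frequency[j]),
                    baseline_sigma=baseline,
                    peak_sigma=peak,
                    fold_change=peak / baseline,
                )
            )
            i = j + 1
        else:
            i += 1
    return spikes
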