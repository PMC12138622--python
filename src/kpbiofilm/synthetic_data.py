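"""Seeded synthetic instrument outputs for the composite-biofilm pipeline.

The real measurements behind this pipeline -- logger voltage traces,
cyclic-voltammetry sweeps, LCR impedance spectra and electron micrographs
-- are not publicly deposited, so every downstream stage is exercised on
generated data with the same statistical structure:

* sinusoid-driven input/output trace pairs whose output is a gain-scaled,
  phase-lagged copy of the drive plus a composition-dependent chaotic
  component (a logistic-map amplitude jitter, so positive-Lyapunov traces
  are producible on demand);
* I-V sweeps with a pinched hysteresis loop plus moment-shaped noise whose
  pooled mean/SD/skewness/kurtosis converge to requested targets;
* impedance spectra inverse-designed so that the parallel-RC conductivity
  conversion recovers a prescribed conductivity profile exactly;
* sphere-field micrographs with known ground-truth particle geometry.

All randomness flows from one explicit seed per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import fsolve

from .dynamics import SignalTrace
from .errors import ConfigurationError, ParameterError
from .impedance import ImpedanceSpectrum
from .iv_stats import IVSweep
from .sem_morphology import Particle, ParticleSet

__all__ = [
    "CompositionSpec",
    "GeneratorConfig",
    "IVGeneratorParams",
    "SpectrumGeneratorParams",
    "ImageFixtureSpec",
    "default_chaos_level",
    "generate_sinusoid_response",
    "generate_iv_sweeps",
    "generate_impedance_spectrum",
    "design_sigma_profile",
    "generate_sphere_image",
    "fleishman_coefficients",
    "moment_shaped_sample",
]

# device response lag of the output sinusoid relative to the drive, radians
RESPONSE_PHASE_LAG = 0.6
# chaotic-jitter amplitude at chaos_level = 1, as a fraction of the output amplitude
CHAOS_AMPLITUDE_FRACTION = 0.5
# deterministic hysteresis current SD as a fraction of the target pooled SD
DET_SD_FRACTION = 0.4


@dataclass
class CompositionSpec:
    """Volume composition of a sample: pure Kombucha (K), pure proteinoid
    (P), or a composite (KP)."""

    kombucha_fraction: float
    proteinoid_fraction: float
    label: str = "KP"

    def __post_init__(self) -> None:
        if abs(self.kombucha_fraction + self.proteinoid_fraction - 1.0) > 1e-9:
            raise ConfigurationError("fractions must sum to 1")
        if not (0 <= self.kombucha_fraction <= 1):
            raise ConfigurationError("kombucha_fraction must lie in [0, 1]")
        if self.label not in ("K", "P", "KP"):
            raise ConfigurationError("label must be one of K, P, KP")
        if self.label == "K" and self.proteinoid_fraction != 0:
            raise ConfigurationError("label K requires proteinoid_fraction = 0")
        if self.label == "P" and self.kombucha_fraction != 0:
            raise ConfigurationError("label P requires kombucha_fraction = 0")


def default_chaos_level(comp: CompositionSpec) -> float:
    """Composition -> chaos mapping: proteinoid-poor mixes are more chaotic.

    A 40:60 proteinoid:Kombucha composite maps to 0 (regular dynamics) and
    a 25:75 composite to 0.9 (chaotic), linear in the Kombucha fraction
    between those anchors.  The mapping encodes the observed ordering of
    entropy and Lyapunov sign with composition, not a physical mechanism.
    """
    lo, hi = 0.60, 0.75
    x = (comp.kombucha_fraction - lo) / (hi - lo)
    return 0.9 * float(np.clip(x, 0.0, 1.0))


@dataclass
class GeneratorConfig:
    """Sinusoid-drive generator settings.

    Defaults emulate the study's drive: ~5 V amplitude at 0.02 Hz sampled
    at 1 Hz by a 24-bit logger, with an output gain reproducing a ~229 mV
    response.  ``noise_sd`` is additive Gaussian measurement noise; the
    default 0 reflects the negligible quantization noise of a 24-bit logger
    on mV-scale signals (biological variability enters via ``chaos_level``).
    """

    seed: int = 0
    duration: float = 1000.0  # seconds
    sampling_rate: float = 1.0  # Hz
    input_amplitude: float = 5082.71  # mV
    input_frequency: float = 0.02  # Hz
    output_gain: float = 229.08 / 5082.71
    noise_sd: float = 0.0  # mV
    chaos_level: float | None = None  # None -> derived from composition

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * self.input_frequency:
            raise ConfigurationError("sampling_rate must exceed 2 x input_frequency")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.chaos_level is not None and not (0 <= self.chaos_level <= 1):
            raise ConfigurationError("chaos_level must lie in [0, 1]")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        if self.input_amplitude <= 0:
            raise ConfigurationError("input_amplitude must be > 0")


def _logistic_series(rng: np.random.Generator, n: int) -> np.ndarray:
    """Fully chaotic logistic-map iterates x <- 4x(1-x), seeded off the rng."""
    z = np.empty(n)
    z[0] = rng.uniform(0.05, 0.95)
    for i in range(n - 1):
        z[i + 1] = 4.0 * z[i] * (1.0 - z[i])
    return z


def generate_sinusoid_response(
    comp: CompositionSpec, cfg: GeneratorConfig
) -> tuple[SignalTrace, SignalTrace]:
    """Input sinusoid and the biofilm-style response trace.

    The response is the gain-scaled, phase-lagged drive plus a chaotic
    amplitude jitter whose strength rises with ``chaos_level`` plus
    Gaussian noise.  The drive's initial phase is drawn from the seed
    (recordings start at an arbitrary point of the cycle).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    omega = 2.0 * np.pi * cfg.input_frequency
    v_in = cfg.input_amplitude * np.sin(omega * t + phase0)

    chaos = default_chaos_level(comp) if cfg.chaos_level is None else cfg.chaos_level
    out_amp = cfg.output_gain * cfg.input_amplitude
    v_out = out_amp * np.sin(omega * t + phase0 - RESPONSE_PHASE_LAG)
    if chaos > 0:
        z = _logistic_series(rng, n)
        v_out = v_out + chaos * CHAOS_AMPLITUDE_FRACTION * out_amp * (2.0 * z - 1.0)
    if cfg.noise_sd > 0:
        v_out = v_out + rng.normal(0.0, cfg.noise_sd, size=n)
    label = comp.label
    return (
        SignalTrace(time=t, potential=v_in, label=f"{label}-input"),
        SignalTrace(time=t, potential=v_out, label=f"{label}-output"),
    )


# ---------------------------------------------------------------------------
# I-V sweeps with moment-shaped noise
# ---------------------------------------------------------------------------

@dataclass
class IVGeneratorParams:
    """Targets for pooled current moments plus sweep geometry.

    ``noise_scale`` rescales the stochastic component (0 disables it for
    inspecting the bare hysteresis loop; moments then no longer converge
    to the targets).
    """

    target_mean: float  # uA
    target_sd: float  # uA
    target_skewness: float = 0.0
    target_kurtosis: float = 3.0  # non-excess
    v_range: tuple[float, float] = (-1.0, 1.0)  # volts, symmetric about 0
    hysteresis_strength: float = 1.0
    n_sweeps: int = 10
    n_points_per_sweep: int = 400
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.target_sd <= 0:
            raise ParameterError("target_sd must be > 0")
        if self.n_sweeps < 1:
            raise ParameterError("n_sweeps must be >= 1")
        if abs(self.v_range[0] + self.v_range[1]) > 1e-12:
            raise ParameterError("v_range must be symmetric about 0")
        if self.hysteresis_strength < 0:
            raise ParameterError("hysteresis_strength must be >= 0")
        if self.target_kurtosis < 1.0 + self.target_skewness**2:
            raise ParameterError(
                "unattainable moments: kurtosis must be >= 1 + skewness^2"
            )


def fleishman_coefficients(skewness: float, excess_kurtosis: float) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) of the Fleishman cubic X = a + bZ + cZ^2 + dZ^3.

    Z is standard normal; the coefficients are solved so X has zero mean,
    unit variance and the requested skewness and excess kurtosis.  Raises
    ``ParameterError`` when the pair lies outside the family's feasible
    region.
    """

    g1, g2 = float(skewness), float(excess_kurtosis)

    def eqs(p: np.ndarray) -> list[float]:
        b, c, d = p
        f1 = b**2 + 6 * b * d + 2 * c**2 + 15 * d**2 - 1.0
        f2 = 2 * c * (b**2 + 24 * b * d + 105 * d**2 + 2) - g1
        f3 = (
            24
            * (
                b * d
                + c**2 * (1 + b**2 + 28 * b * d)
                + d**2 * (12 + 48 * b * d + 141 * c**2 + 225 * d**2)
            )
            - g2
        )
        return [f1, f2, f3]

    guess = np.array([1.0, g1 / 6.0, 0.01])
    sol, info, ier, _ = fsolve(eqs, guess, full_output=True)
    if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-9:
        raise ParameterError(
            f"moment targets (skew={g1}, excess kurtosis={g2}) are outside the "
            "Fleishman feasible region"
        )
    b, c, d = sol
    return (-c, float(b), float(c), float(d))


def moment_shaped_sample(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    skewness: float,
    kurtosis: float,
) -> np.ndarray:
    """Sample n draws whose population moments match the given targets
    (kurtosis in the non-excess convention)."""
    a, b, c, d = fleishman_coefficients(skewness, kurtosis - 3.0)
    z = rng.standard_normal(n)
    x = a + b * z + c * z**2 + d * z**3
    return mean + sd * x


def _triangle_cycle(v_lo: float, v_hi: float, n_points: int) -> np.ndarray:
    half = n_points // 2
    up = np.linspace(v_lo, v_hi, half, endpoint=False)
    down = np.linspace(v_hi, v_lo, n_points - half, endpoint=False)
    return np.concatenate([up, down])


def generate_iv_sweeps(params: IVGeneratorParams, seed: int) -> IVSweep:
    """Cyclic-voltammetry-style sweeps with a pinched hysteresis loop.

    The deterministic current is i = g * v * (1 + h * w / V_max) where the
    internal charge state w relaxes toward the applied voltage, opening a
    loop through the origin (pinched: i = 0 whenever v = 0); h = 0 collapses
    forward and reverse traces onto each other.  A moment-shaped noise term
    is added whose parameters are solved so that the pooled deterministic +
    stochastic sample converges to the requested mean/SD/skewness/kurtosis
    (independent-sum central-moment identities).
    """
    rng = np.random.default_rng(seed)
    v_lo, v_hi = params.v_range
    cycle = _triangle_cycle(v_lo, v_hi, params.n_points_per_sweep)
    v = np.tile(cycle, params.n_sweeps)
    n = v.size
    sweep_idx = np.repeat(np.arange(params.n_sweeps), params.n_points_per_sweep)

    # charge-state relaxation: w lags v, producing the loop
    alpha = 10.0 / params.n_points_per_sweep
    w = np.empty(n)
    w[0] = 0.0
    for k in range(n - 1):
        w[k + 1] = w[k] + alpha * (v[k] - w[k])
    shape = v * (1.0 + params.hysteresis_strength * w / max(abs(v_lo), abs(v_hi)))
    sd_shape = shape.std()
    if sd_shape > 0:
        i_det = shape * (DET_SD_FRACTION * params.target_sd / sd_shape)
    else:
        i_det = shape

    if params.noise_scale == 0:
        return IVSweep(voltage=v, current=i_det, sweep_index=sweep_idx)

    # residual moments for the noise so the pooled sample hits the targets
    mu_d = i_det.mean()
    cen = i_det - mu_d
    var_d = float(np.mean(cen**2))
    mu3_d = float(np.mean(cen**3))
    mu4_d = float(np.mean(cen**4))
    var_t = params.target_sd**2
    mu3_t = params.target_skewness * params.target_sd**3
    mu4_t = params.target_kurtosis * params.target_sd**4
    var_n = var_t - var_d
    if var_n <= 0:
        raise ParameterError("deterministic loop variance exceeds the target variance")
    mu3_n = mu3_t - mu3_d
    mu4_n = mu4_t - mu4_d - 6.0 * var_d * var_n
    skew_n = mu3_n / var_n**1.5
    kurt_n = mu4_n / var_n**2
    if kurt_n < 1.0 + skew_n**2:
        raise ParameterError("residual noise moments are unattainable")
    noise = moment_shaped_sample(
        rng, n, mean=params.target_mean - mu_d, sd=np.sqrt(var_n),
        skewness=skew_n, kurtosis=kurt_n,
    )
    return IVSweep(voltage=v, current=i_det + params.noise_scale * noise, sweep_index=sweep_idx)


# ---------------------------------------------------------------------------
# impedance spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumGeneratorParams:
    """Inverse-design targets for a conductivity spectrum.

    The off-band baseline declines gently with frequency
    (sigma_base = baseline_sigma * (f/f_min)^-baseline_decay), emulating the
    hindered charge transport seen at higher drive frequencies;
    ``baseline_sigma`` is the baseline at the lowest grid frequency.  A
    raised-cosine resonance bump inside ``spike_band`` lifts the profile to
    ``spike_peak_sigma`` at band center.
    """

    freq_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(1e3, 300e3, 400)
    )
    baseline_sigma: float = 0.03  # S/cm
    spike_band: tuple[float, float] = (74e3, 178e3)  # Hz
    spike_peak_sigma: float = 20.0  # S/cm
    noise_fraction: float = 0.02
    baseline_decay: float = 0.3
    phase_deg: float = 30.0  # designed phase angle, constant over the grid

    def __post_init__(self) -> None:
        self.freq_grid = np.asarray(self.freq_grid, dtype=float)
        if np.any(np.diff(self.freq_grid) <= 0):
            raise ParameterError("freq_grid must be strictly increasing")
        if np.any(self.freq_grid <= 0):
            raise ParameterError("freq_grid must be > 0 (sigma undefined at DC)")
        f_lo, f_hi = self.spike_band
        if not (self.freq_grid[0] <= f_lo < f_hi <= self.freq_grid[-1]):
            raise ParameterError("spike_band must lie within the freq_grid extent")
        if self.baseline_sigma <= 0 or self.spike_peak_sigma <= 0:
            raise ParameterError("non-invertible target: sigma must be > 0")
        if self.spike_peak_sigma <= self.baseline_sigma:
            raise ParameterError("spike_peak_sigma must exceed baseline_sigma")
        if not (0 <= self.noise_fraction < 1):
            raise ParameterError("noise_fraction must lie in [0, 1)")
        if not (abs(self.phase_deg) < 90):
            raise ParameterError("|phase_deg| must be < 90")


def design_sigma_profile(params: SpectrumGeneratorParams) -> np.ndarray:
    """The noiseless conductivity profile the generator encodes (S/cm)."""
    f = params.freq_grid
    base = params.baseline_sigma * (f / f[0]) ** (-params.baseline_decay)
    f_lo, f_hi = params.spike_band
    u = (f - f_lo) / (f_hi - f_lo)
    bump = np.where(
        (u >= 0) & (u <= 1), 0.5 - 0.5 * np.cos(2.0 * np.pi * np.clip(u, 0, 1)), 0.0
    )
    return base + (params.spike_peak_sigma - params.baseline_sigma) * bump


def generate_impedance_spectrum(
    params: SpectrumGeneratorParams, seed: int
) -> ImpedanceSpectrum:
    """Capacitance/phase records inverse-designed from a conductivity target.

    The target profile (optionally perturbed by multiplicative noise) is
    inverted through sigma = cos(phi)/(omega * C), i.e.
    C = cos(phi) / (omega * sigma), so the impedance module's default
    conversion recovers the designed profile exactly when noise is 0.
    """
    rng = np.random.default_rng(seed)
    sigma = design_sigma_profile(params)
    if params.noise_fraction > 0:
        sigma = sigma * np.abs(1.0 + params.noise_fraction * rng.standard_normal(sigma.size))
    omega = 2.0 * np.pi * params.freq_grid
    phi = np.deg2rad(params.phase_deg)
    cap = np.cos(phi) / (omega * sigma)
    phase = np.full(sigma.size, params.phase_deg)
    return ImpedanceSpectrum(
        frequency=params.freq_grid.copy(),
        capacitance=cap,
        phase_angle=phase,
        signal_level=1.0,
    )


# ---------------------------------------------------------------------------
# sphere-field micrographs
# ---------------------------------------------------------------------------

@dataclass
class ImageFixtureSpec:
    """Synthetic micrograph layout: bright disks on a noisy background."""

    canvas_size: tuple[int, int] = (512, 512)  # pixels
    pixel_size: float = 4.34  # nm/pixel
    sphere_diameters: tuple[float, ...] = (1800.0,)  # nm
    sphere_centers: tuple[tuple[float, float], ...] | None = None  # (row, col) px
    background_noise_sd: float = 0.03  # grayscale units
    blur_radius: float = 1.0  # pixels

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.sphere_diameters):
            raise ParameterError("sphere diameters must be > 0")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        h, w = self.canvas_size
        radii_px = [d / 2.0 / self.pixel_size for d in self.sphere_diameters]
        if self.sphere_centers is not None:
            if len(self.sphere_centers) != len(self.sphere_diameters):
                raise ParameterError("one center per diameter required")
            for (r, c), rad in zip(self.sphere_centers, radii_px):
                if not (rad <= r <= h - rad and rad <= c <= w - rad):
                    raise ParameterError("sphere does not fit within the canvas")
        elif any(2 * rad > min(h, w) for rad in radii_px):
            raise ParameterError("sphere does not fit within the canvas")


def generate_sphere_image(
    spec: ImageFixtureSpec, seed: int
) -> tuple[np.ndarray, ParticleSet]:
    """Anti-aliased bright disks on a noisy background, plus ground truth.

    Returns (image in [0, 1], ParticleSet).  Ground-truth particles carry
    the specified diameters and centers; overlapping pairs are flagged
    (``flag='overlap'``) rather than rejected.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.canvas_size
    img = 0.2 + spec.background_noise_sd * rng.standard_normal((h, w))

    radii = np.array([d / 2.0 / spec.pixel_size for d in spec.sphere_diameters])
    if spec.sphere_centers is not None:
        centers = [tuple(map(float, c)) for c in spec.sphere_centers]
    else:
        centers = [
            (rng.uniform(rad, h - rad), rng.uniform(rad, w - rad)) for rad in radii
        ]

    rows, cols = np.mgrid[0:h, 0:w]
    for (cr, cc), rad in zip(centers, radii):
        r = np.hypot(rows - cr, cols - cc)
        # 1-pixel smooth (anti-aliased) edge
        img += 0.7 * np.clip(rad + 0.5 - r, 0.0, 1.0)
    if spec.blur_radius > 0:
        img = ndi.gaussian_filter(img, sigma=spec.blur_radius)
    img = np.clip(img, 0.0, 1.0)

    overlapping = set()
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d_ij = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d_ij < radii[i] + radii[j]:
                overlapping.update((i, j))
    truth = ParticleSet()
    for k, ((cr, cc), diam) in enumerate(zip(centers, spec.sphere_diameters)):
        truth.particles.append(
            Particle(
                centroid=(cr, cc),
                equivalent_diameter=float(diam),
                area=float(np.pi * (diam / 2.0) ** 2),
                circularity=1.0,
                flag="overlap" if k in overlapping else "",
            )
        )
    return img, truth
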