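# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that affect results.

## Conductivity from impedance (`impedance`)

The film is modelled as a resistor R in parallel with a capacitor C:
`Z = R / (1 + jωRC)`, `tan φ = ωRC`. From the LCR meter's per-frequency
capacitance and phase readings, conductivity is computed as

    σ = k · cos φ / (ωC),        ω = 2πf

with a geometric cell constant `k` (1/cm, default 1) converting a
conductance-like quantity to S/cm. The relation can be typeset ambiguously
(the `√(1 + tan²φ)` factor read as multiplying instead of dividing), so
variants `mult_sqrt` (`k·√(1+tan²φ)/(ωC)`) and `no_sqrt` (`k/(ωC)`) are
selectable; all variants coincide at φ = 0, and the default is the
dimensionally sensible reading in which the phase factor accounts for the
resistive vs reactive split. Phase is supplied in degrees (positive =
capacitive, current leads voltage) and converted internally; rows at
f = 0 yield undefined σ (reported as NaN). Whether published S/cm values
for such films include a cell constant is generally unstated; `k = 1` is
the neutral choice and is exposed as a parameter.

Conduction spikes are contiguous runs where σ ≥ `min_fold` (default 100)
times the baseline, defined as the 0.25 quantile of the finite σ values.
Detection is therefore invariant to uniform rescaling of σ. Band edges,
peak and fold change are reported per spike; reported band edges are
data-driven outputs, never constants, since published band limits for
these materials are internally inconsistent across sources of the same
measurements.

## I–V statistics (`iv_stats`)

Pooled CV current samples are summarized by the sample mean, sample SD
(n−1 denominator), and standardized third/fourth central moments with n
denominator. Kurtosis uses the **non-excess** convention (Gaussian → 3)
so that values like 2.80 read directly as "flatter than a normal
distribution". Quantiles use linear interpolation between order
statistics; box whiskers sit on the most extreme points within 1.5×IQR
of the quartiles. The Gaussian profile is the ML fit (σ with n
denominator). Pooling across sweeps is the default; CV oversamples
voltage regions near vertical curve segments, so an optional
density-weighted resampler (equal bootstrap counts per voltage bin) is
provided but **off by default** — the bias is a caveat on pooled
statistics, not a correction applied to them.

## Nonlinear dynamics (`dynamics`)

* **Entropy**: amplitudes are binned into 8 equal-width bins over the
  observed [min, max] by default (`0·log 0 := 0`), making H invariant to
  affine amplitude rescaling; a `fixed` range mode is provided because a
  reported 0 bits for a non-constant trace is only reachable when the
  bin range is an absolute voltage scale much wider than the signal.
  Constant traces return exactly 0 bits.
* **Embedding**: Takens delay vectors with lag τ (samples) and dimension
  m ≥ 2; the point count is always n − (m−1)τ. The default τ estimate is
  the first non-positive lag of the autocorrelation (fallback n/20 when
  it never crosses, e.g. constant traces).
* **Largest Lyapunov exponent**: Rosenstein's method — for each embedded
  point, the nearest neighbor outside a Theiler window (default τ) is
  tracked and the least-squares slope of the mean log divergence over
  `fit_range` steps (default 0–8) is returned, in units of 1/sample
  (multiply by the sampling rate for 1/s). Distances are floored at
  1e-10 of the attractor diameter so exactly recurrent periodic
  trajectories produce a flat curve; slopes below 1e-9 (far below any
  physically meaningful exponent at this sampling) are snapped to 0.
  Note the estimator has a small positive bias on noisy regular signals
  (the initial neighbor distance is selection-biased low and regresses
  up to the noise floor), which is why regular oracles are tested
  against LE ≤ 0.01 rather than strict negativity.
* **Correlation dimension**: Grassberger–Procaccia correlation sum with
  Theiler exclusion; embedded points are decimated to ≤ 1500 to bound the
  O(n²) distance computation. The radius grid defaults to 24 log-spaced
  radii between the 1st and 50th distance percentiles; the scaling
  region is the longest contiguous log–log segment whose local slopes
  vary by less than 10% of their mean (overridable), with the first
  segments as fallback.
* All estimators are deterministic given (trace, config); randomness
  exists only in trace generation.

## Threshold logic (`logic`)

Inputs swept over −5..+5 V DC are encoded to logical levels by a sign
threshold at 0 V (the sweep midpoint; no published rule exists for this
mapping). Outputs are min–max normalized per channel to [0, 1] and
binarized at a strict 0.5 cutoff (the boundary maps to 0); the cutoff is
applied to *normalized* outputs, reconciling a "0.5 V" threshold
statement with outputs plotted on a normalized [0, 1] axis. Gates are
evaluated on steady-state voltage-indexed data, not time series. Two
realization semantics are supported, since published descriptions
conflate them: the default combines the input channels' binarized
outputs with the gate's bitwise operator; `output_id` mode compares a
designated channel's binarized response against the gate table.
Repeated measurements of the same input combination are resolved by
majority vote; unobserved combinations are flagged and excluded from the
match fraction. Duplicate agreement compares the realized tables of a
channel pair and the pair shifted by two channels (pairs 1–2 vs 3–4).

## Temporal coding (`tcnn`)

A recording is an (n, 2) potential matrix over a shared time vector. N
neurons are assigned to contiguous equal-length time blocks, split as
evenly as possible across sample columns (the partition is configurable;
published formulations leave it unstated, and a block partition makes N
meaningful for arbitrary n). The code is the strict indicator
`c = 1 iff p > θ`. Because the published code formula conflates a binary
indicator with a latency multiplier, both are stored: `c` and a latency
weight `clip(T − (tᵢ − t_first), 0, T)` for spiking entries, where
`t_first` is the column's first suprathreshold time. Weight matrices are
bounded in [−1, 1] by construction: `uniform` draws i.i.d. from a seeded
generator; `code_correlation` uses the Pearson correlation of code rows
(zero-variance rows → 0), which produces the structured heatmap patterns
expected when weights are seeded from recorded activity. Heatmaps are
rendered on a fixed [−1, 1] color scale with a JSON sidecar that reloads
bit-identically. No training or spike propagation is implemented — only
encoding and initialization.

## Micrograph morphology (`sem_morphology`)

Grayscale conversion (luminance), contrast-limited adaptive histogram
equalization to [0, 1] (constant images pass through unchanged), then
adaptive thresholding: foreground where intensity > local mean + offset,
with the local mean over an odd window (default: image size / 8, rounded
odd; offset default 0.02 of the intensity range). Bright-on-dark
polarity is assumed (secondary-electron convention); the `invert` flag
flips the comparison so an inverted-contrast image yields the same mask.
**The window must exceed the feature scale to segment filled objects**
— local-mean thresholding hollows out objects larger than its window, so
the micron-scale disk fixtures are segmented with a window comparable to
the image side. Skeletonization uses topology-preserving morphological
thinning (hit-or-miss), which empirically preserves connected-component
counts and leaves no 2×2 foreground block on random blob fixtures.
Particle measurements: equivalent diameter `2·√(area/π)·pixel_size`,
area in nm², circularity `4π·area/perimeter²` clipped to 1 (perimeter
estimates on rasterized disks can overshoot slightly); border-touching
components are flagged rather than dropped.

## Synthetic data (`synthetic_data`)

The generators define the study conditions under which the pipeline is
exercised:

* **Trace pairs**: the drive is a 5082.71 mV, 0.02 Hz sinusoid sampled at
  1 Hz for 1000 s, with a seed-drawn initial phase (recordings start at
  an arbitrary cycle point). The output is the gain-scaled
  (default 229.08/5082.71), phase-lagged (0.6 rad) drive plus a chaotic
  amplitude jitter: fully chaotic logistic-map iterates mapped to
  ±`0.5 · chaos_level · output amplitude`. The composition→chaos mapping
  anchors 40:60 (proteinoid:Kombucha) at chaos 0 and 25:75 at 0.9,
  linear in Kombucha fraction — encoding the observed ordering (regular
  vs chaotic with decreasing proteinoid content), not a mechanism.
  Default measurement noise is 0 mV: a 24-bit logger quantizes mV-scale
  signals at the µV level, so instrument noise is negligible and
  variability enters through the chaos term. The logistic-map jitter is
  a stand-in for the unknown noise process of real films, chosen so that
  positive-Lyapunov traces are producible on demand; it does not claim
  anything about the biofilm's physics.
* **I–V sweeps**: triangular voltage cycles with a phenomenological
  charge-state variable `w` relaxing toward the applied voltage;
  deterministic current `i = g·v·(1 + h·w/V_max)` is pinched at the
  origin and its SD is scaled to 0.4 of the target pooled SD. The
  stochastic component is a Fleishman cubic transform of a standard
  normal whose parameters are solved (fsolve on the closed-form moment
  equations) for the *residual* moments after subtracting the
  deterministic part's exact sample moments via independent-sum
  central-moment identities — so the pooled sample converges to the
  requested mean/SD/skewness/kurtosis. The Fleishman family was chosen
  over sinh-arcsinh because it covers the platykurtic targets
  (kurtosis < 3) that pure-proteinoid samples exhibit. Unattainable
  targets (kurtosis < 1 + skew²) or infeasible residuals raise errors.
* **Impedance spectra**: a target conductivity profile — baseline
  0.03 S/cm at the lowest grid frequency, declining as (f/f_min)^−0.3
  to emulate the hindered charge transport seen at higher frequencies,
  plus a raised-cosine resonance bump to 20 S/cm centered in the
  74–178 kHz band — is inverted through `C = cos φ/(ωσ)` at a constant
  designed phase (30°). With zero noise the conductivity conversion
  recovers the profile to machine precision; the default multiplicative
  noise fraction is 0.02. With the declining baseline, the detected
  spike's fold change over the baseline quantile exceeds 1000×.
* **Micrographs**: anti-aliased bright disks (1-pixel smooth edge) on a
  Gaussian-noise background, optional Gaussian blur; ground truth
  carries exact centers/diameters, with overlapping pairs flagged.

What the generators do **not** emulate: electrode drift, 1/f noise,
electrochemical redox peaks, non-stationary composition changes, SEM
charging artifacts or texture. Passing tests therefore demonstrate
correctness of the estimators and the pipeline's contracts under
controlled statistical structure, not performance on raw laboratory
data.

## Problem sizes and tolerances

Test and acceptance runs use: 1000-sample traces (20 drive cycles) for
composition ordering (100 seeds), 5000-sample logistic-map series for the
Lyapunov oracle (ln 2 ± 0.07), 3000-sample series decimated to 1500
embedded points for correlation dimensions (limit cycle 1 ± 0.1, planar
noise 2 ± 0.2), 10⁵-point pooled CV samples for moment recovery (within
3 Monte-Carlo standard errors, estimated from 20 equal blocks), 10⁶
draws for the Gaussian closed forms (kurtosis 3 ± 0.02, skewness
0 ± 0.01), 400-point spectra for the round trip (≤ 1e-6 relative), and
600–700 px canvases for micron-disk sizing (within 5%, dominated by
edge rasterization and blur). These sizes keep every stage well inside
its statistical tolerance while running the whole suite in well under a
minute per stage.

## Known limitations

* Published Lyapunov magnitudes for these films (−0.026, 0.035 per
  sample) cannot be reproduced without the raw traces; only the sign
  and ordering behavior is testable, and the generator is calibrated to
  reproduce exactly that.
* The entropy values reported for real 40:60 vs 25:75 traces are
  mutually inconsistent across sections of the published record; this
  package fixes the convention to match the Lyapunov ordering
  (proteinoid-poor ⇒ more chaotic ⇒ higher entropy).
* The Rosenstein estimator's positive bias on noisy regular signals
  (documented above) means "LE ≤ 0" should be read as "no detectable
  divergence", not as evidence of contraction.
* Adaptive thresholding requires a window larger than the objects of
  interest for filled segmentation; automatic window selection from a
  size prior is not implemented.
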