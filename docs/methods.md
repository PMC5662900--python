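# Methods

## Signal model

The ongoing (steady-state) part of the ECochG response to a tone of
frequency `f` is treated as the sum of two periodic generators sampled
over exactly one stimulus period of `N = round(fs/f)` points.

**Cochlear microphonic.** Hair-cell transduction is a saturating
nonlinearity; within one cycle its output is approximated as a sinusoid
`A_CM·sin(2π(f·t − φ_CM))` hard-clipped at an upper and a lower cutoff
voltage. Independent cutoffs capture both asymmetric saturation (an
operating point displaced from the midpoint of the transducer function)
and symmetric saturation at high levels. Clipping is idempotent and
keeps the waveform inside `[Lower, Upper]` pointwise. This deliberately
hard-edged description requires no assumption about the underlying
Boltzmann shape or operating point; its known cost is that any CM
waveform feature beyond flat-topped saturation (e.g. a sloping,
adapting peak) will be absorbed by the neural term instead.

**Auditory nerve neurophonic.** Phase-locked population firing is
described by a cycle histogram (CH): zero during the hyperpolarising
half of basilar-membrane motion (firing cannot fall below the
spontaneous floor — half-wave rectification) and a single broad mode
otherwise. The CH is evaluated as a lognormal probability density with
time expressed in units of the unit-potential period T_UP (the printed
form of the density mixes units; measuring time in UP periods with
μ = ln(T_UP/T_UP) = 0 is the parameterisation adopted here, with t = 0
mapped to 1e−6 to avoid the origin singularity). Its width parameter σ
is the spread of excitation (SOE), bounded to [0.35, 0.65] of a
stimulus cycle: narrower would out-sharpen single-fibre vector
strength, wider only adds a DC pedestal with no AC contribution. The
density is renormalised to unit peak.

The ANN is the circular convolution of the CH with the unit potential
(UP) — one cycle of a sinusoid at 1100 Hz, the duration of a single
fibre's spike waveform at the round window — normalised to unit peak
magnitude and scaled by `A_ANN`, so `A_ANN` is in μV and directly
comparable with `A_CM`. The ANN phase is applied as an integer-sample
circular shift `round(φ_ANN·N)`, so phase resolution is 1/N cycles
(1/32 at 500 Hz / 16 kHz). The UP's polarity is a labelling convention
(any sign flip is a half-cycle phase shift); it is chosen positive-first
so that equal CM and ANN phase parameters produce near-aligned
waveforms — constructive interference at zero phase difference,
destructive at half a cycle, the phenomenology that makes single-peak
response magnitudes unreliable in the first place.

## Preprocessing

The fit input is the *average cycle*: the pointwise mean over all whole
stimulus cycles of the ongoing window. By default the onset window
discards the stimulus rise time plus two guard cycles (clearing the
compound action potential, which can be delayed), and the offset window
discards the fall time plus one cycle. Only whole cycles are folded; a
trailing partial cycle is dropped to avoid phase smearing. Folding k
cycles suppresses asynchronous noise by ≈1/√k and is mean-preserving.
Alternating-polarity epochs may be combined as (cond−rare)/2
(polarity-inverting emphasis), (cond+rare)/2 (polarity-invariant), or
analysed single-polarity (the default).

## Fitting

Seven parameters — `A_CM`, `φ_CM`, `Upper`, `Lower`, `A_ANN`, `φ_ANN`,
`SOE` — minimise the sum of squared residuals against the average cycle
under box bounds: amplitudes in [0, 5×max|input|]; phases in [−2, 2]
cycles; `Upper` in [0.5, 5]×max(input) and `Lower` mirrored on the
minimum (the outer bound leaves the clipping branch inactive); SOE in
[0.35, 0.65]. The solver is scipy's trust-region-reflective
`least_squares` with first-order optimality tolerance 1e−6, Jacobian
column scaling, and tight step/function tolerances.

Two features of the residual surface shape the solver design:

* **The shift axis is discrete.** Because `φ_ANN` acts as an
  integer-sample circular shift, the residual is piecewise constant in
  it and finite-difference gradients are identically zero. The shift is
  therefore optimised by exhaustive search over all N circular shifts of
  the current kernel (vectorised, one pass), alternated with
  trust-region passes over the six smooth parameters until the shift is
  stable (at most 6 alternations).
* **Inactive clipping is flat.** While a cutoff does not intersect the
  sinusoid the residual is constant in it, so a start at the no-clipping
  bound can never discover saturation. The multistart therefore runs in
  stages: (1) eight equally spaced initial ANN phases with open cutoffs;
  (2) if no essentially exact fit was found, the same phase multistart
  with both cutoffs engaged at 0.9× the input extrema and the sinusoid
  amplitude inflated 1.5× so the branches stay active; (3) one-sided
  clipped starts at the best phase found. Stages stop early once
  SSE ≤ 1e−8 × input energy — a fit whose r² is within 1e−8 of 1 cannot
  be improved meaningfully. The lowest-SSE solution wins, ties broken by
  start order; the whole procedure is deterministic.

The starting point derives from the cycle's first harmonic (`A_CM`,
`φ_CM` from the fundamental's magnitude and phase; `A_ANN` = 0.2·A_CM in
phase with it; SOE mid-range). Degenerate inputs — all zeros, no energy
at the stimulus frequency, or no zero crossing — are rejected rather
than fitted. Residuals are weighted uniformly (plain least squares).

Goodness of fit: `r` is the maximum normalised cross-correlation over
circular lags (a pure phase offset still scores 1); `r²` is the zero-lag
determination coefficient `1 − SSE/SST`, the headline figure. The
returned SSE is never worse than at the initial guess.

## Spectral analysis

Magnitudes are single-sided amplitude spectra in μV (DC and Nyquist bins
un-doubled, so Parseval's identity holds exactly). The spectrum of an
average cycle is computed on the cycle tiled over an integer number of
periods (default 8), which places every harmonic exactly on an FFT bin
and avoids window-function arbitrariness. A harmonic peak is significant
when it exceeds the mean of the three bins on either side (six bins
pooled, peak excluded) by more than three of their standard deviations,
and also exceeds 1e−9× the spectral maximum — a pure numerical guard so
FFT round-off in a synthetic line spectrum cannot register as a
response; physical noise floors are many orders above it. The *total
response* sums all significant harmonic-1..3 magnitudes across stimulus
frequencies; summing peaks rather than RMS keeps the measure insensitive
to CM/ANN phase interference.

## Metrics

Component magnitudes default to the first-harmonic amplitudes of the
separated CM and ANN waveforms (for an unclipped CM this equals `A_CM`;
clipping strips fundamental energy, so the spectral magnitude is the
faithful basis for spectra-derived ratios); the raw parameter basis is
available by flag. The ANN/CM index `(ANN−CM)/(ANN+CM)` is
antisymmetric, scale-invariant, and maps ratio ρ to (ρ−1)/(ρ+1).
Because the fitter rarely returns an ANN below ~5% of the CM even for
pure-CM inputs, ratios strictly below 0.05 are reported as "no neural
response" (ANN magnitude zeroed, flag set); the ratio and index fields
keep their pre-cutoff values and the cutoff is never applied to the
index. dB conversions are 20·log10.

## Simulated signals

The generator is the forward model itself plus i.i.d. Gaussian noise
(the recordings' noise statistics are uncharacterised; white Gaussian is
the neutral assumption), seeded and reproducible. The reference
conditions mirror the human recording regime: 500 Hz at 16 kHz
(32 samples/cycle), 1 μV CM. The standard validation sweeps vary one
parameter at a time, noise-free: ANN amplitude 0.01–2 μV (SOE 0.65,
no saturation, zero phase difference); CM–ANN phase difference ±0.5
cycles (ANN 0.3 μV); trough saturation 0–15% of A_CM; peak saturation
0–10% with trough saturation held at 15% and ANN 0.43 μV; SOE 0.35–0.65
(ANN 0.3 μV). Each sweep fits 100 signals by default and reports
per-parameter bias, median absolute error, and RMSE.

What the generator does **not** emulate: recording noise spectra and
artifacts, cycle-by-cycle CM adaptation, dendritic (EPSP-driven)
potentials, realistic UP shapes, and stimulus ramps/CAP — only the
average cycle is simulated. Passing recovery tests therefore
demonstrate the estimator's correctness on its own model class, not
that real responses obey the model; on recorded data the known failure
mode is over-reporting ANN when the CM departs from a clipped sinusoid.

## Numerical choices and edge cases

* Cycle length `N = round(fs/f)` must be ≥ 8; the unit potential needs
  ≥ 4 samples per UP cycle.
* Circular convolution runs via the real FFT; kernels longer than the
  period wrap back onto it. Agreement with a direct O(N²) oracle is
  tested to 1e−10 relative error over grid lengths 8–256.
* The small-ratio cutoff uses a strict `<` comparison.
* Phases are reported both raw and wrapped to [0, 1) cycles; solutions
  differing by whole cycles produce identical waveforms.
* Fit problem sizes in the test and validation suites (32-sample
  cycles, 100-signal sweeps, 12-fit noise batteries) are the reference
  study conditions; recovery there is essentially exact for amplitudes
  (≲1e−5 relative, noise-free), half-sample-quantised for the phase
  difference (median ≈ 0.008 cycles at N = 32), and least precise for
  SOE under combined saturation — the same parameter hierarchy the
  validation sweeps document.

## Known limitations

The model cannot distinguish non-sinusoidal CM shapes (e.g. within-cycle
adaptation) from neural contribution, inflating reported ANN for large
pure-CM responses — the motivation for the 5% ratio floor. Conversely,
when the ANN is much larger than the CM, amplitude/saturation trade-offs
appear (trough saturation absorbs part of a large ANN). The ANN phase is
quantised to one sample. Inner and outer hair-cell CM contributions are
not separated, and dendritic potentials are not modelled.
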