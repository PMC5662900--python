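"""Forward model of the ongoing ECochG response over one stimulus cycle.

The ongoing (steady-state) portion of the electrocochleographic response to
a low-frequency tone is modelled as the sum of two phase-locked components:

* the cochlear microphonic (CM) — hair-cell transducer current, represented
  as a sinusoid at the stimulus frequency whose peak and trough may saturate
  independently (hard clipping at an upper and a lower cutoff voltage), and
* the auditory nerve neurophonic (ANN) — the far-field correlate of
  phase-locked auditory-nerve firing, represented as the circular
  convolution of a population cycle histogram (a half-wave-rectified,
  lognormal-shaped firing-probability density) with a unit potential (the
  waveform a single fibre's action potential contributes at the recording
  site, one cycle of a sinusoid, 1100 Hz by default).

All waveforms are evaluated on a :class:`TimeGrid` spanning exactly one
stimulus period, so component phases are expressed in cycles and the ANN
phase acts as a circular (integer-sample) shift of the convolved kernel.
Amplitudes are in microvolts throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError, ResolutionError

__all__ = [
    "TimeGrid",
    "CMParams",
    "ANNParams",
    "ModelParams",
    "cm_waveform",
    "unit_potential",
    "cycle_histogram",
    "ann_waveform",
    "ecochg_model",
    "DEFAULT_UP_FREQUENCY",
    "SOE_MIN",
    "SOE_MAX",
]

DEFAULT_UP_FREQUENCY = 1100.0
SOE_MIN = 0.35
SOE_MAX = 0.65

# Cycle-fraction stand-in for t = 0 when evaluating the lognormal density,
# which is singular at the origin.
_LOGNORMAL_EPS = 1e-6


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sample times covering exactly one stimulus period.

    Parameters
    ----------
    stimulus_frequency
        Tone frequency in Hz.
    sampling_rate
        Sampling rate in Hz. One period must contain at least 8 samples.
    """

    stimulus_frequency: float
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.stimulus_frequency <= 0 or self.sampling_rate <= 0:
            raise ParameterError("frequencies must be positive")
        if self.n_samples < 8:
            raise ParameterError(
                f"only {self.n_samples} samples per stimulus cycle; need >= 8"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate / self.stimulus_frequency))

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class CMParams:
    """Saturating-sinusoid parameters for the cochlear microphonic.

    ``a_cm`` (μV) and ``phi_cm`` (cycles) set the underlying sinusoid;
    ``upper_cutoff`` / ``lower_cutoff`` (μV) clip its peak and trough,
    representing asymmetric saturation of the hair-cell transducer.
    """

    a_cm: float
    phi_cm: float
    upper_cutoff: float
    lower_cutoff: float

    def __post_init__(self) -> None:
        if self.a_cm < 0:
            raise ParameterError("a_cm must be nonnegative")
        if not self.lower_cutoff < self.upper_cutoff:
            raise ParameterError("lower_cutoff must be below upper_cutoff")
        if self.lower_cutoff > 0 or self.upper_cutoff < 0:
            raise ParameterError("cutoffs must bracket zero")


@dataclass(frozen=True)
class ANNParams:
    """Parameters of the neurophonic component.

    ``soe`` (spread of excitation) is the lognormal width of the cycle
    histogram in cycle fractions; it is bounded to [0.35, 0.65] — narrower
    would be sharper than single-fibre vector strength allows, wider adds
    only a DC pedestal that does not contribute to the AC response.
    """

    a_ann: float
    phi_ann: float
    soe: float
    up_frequency: float = DEFAULT_UP_FREQUENCY

    def __post_init__(self) -> None:
        if self.a_ann < 0:
            raise ParameterError("a_ann must be nonnegative")
        if not SOE_MIN <= self.soe <= SOE_MAX:
            raise ParameterError(
                f"soe={self.soe} outside [{SOE_MIN}, {SOE_MAX}]"
            )
        if self.up_frequency <= 0:
            raise ParameterError("up_frequency must be positive")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the two-component model."""

    cm: CMParams
    ann: ANNParams


def cm_waveform(cm: CMParams, grid: TimeGrid) -> np.ndarray:
    """One cycle of the (possibly saturating) cochlear microphonic.

    Evaluates ``a_cm * sin(2π(f t − phi_cm))`` on the grid and clips the
    result to ``[lower_cutoff, upper_cutoff]`` pointwise.
    """
    sine = cm.a_cm * np.sin(
        2.0 * np.pi * (grid.stimulus_frequency * grid.times - cm.phi_cm)
    )
    return np.clip(sine, cm.lower_cutoff, cm.upper_cutoff)


def unit_potential(
    up_frequency: float = DEFAULT_UP_FREQUENCY, sampling_rate: float = 16000.0
) -> np.ndarray:
    """Single-fibre unit potential: one sine cycle, unit peak amplitude.

    The kernel's polarity is a labelling convention (the ANN phase spans
    multiple cycles and absorbs any sign); it is chosen positive-first so
    that equal CM and ANN phase parameters put the two components close to
    waveform alignment — constructive interference at zero phase
    difference, destructive at half a cycle.
    """
    if up_frequency <= 0:
        raise ParameterError("up_frequency must be positive")
    n = int(round(sampling_rate / up_frequency))
    if sampling_rate < 4 * up_frequency:
        raise ResolutionError(
            f"sampling rate {sampling_rate} Hz cannot represent one cycle "
            f"at {up_frequency} Hz (need >= 4 samples/cycle, got {n})"
        )
    kernel = np.sin(2.0 * np.pi * np.arange(n) / n)
    return kernel / np.max(np.abs(kernel))


def cycle_histogram(ann: ANNParams, grid: TimeGrid) -> np.ndarray:
    """Population cycle histogram over one stimulus cycle, unit peak.

    The period-folded firing probability of the phase-locked nerve
    population is shaped as a lognormal density: near zero early in the
    cycle (firing cannot go below the spontaneous floor during the
    hyperpolarising half — half-wave rectification) with a single broad
    mode whose width grows with the spread of excitation.

    Time is expressed in units of the unit-potential period, the density's
    natural scale (``μ = ln 1 = 0`` there), and ``σ`` is the SOE. The
    density is renormalised to unit peak so the downstream amplitude term
    is in μV.
    """
    if ann.up_frequency <= grid.stimulus_frequency:
        raise ParameterError(
            "up_frequency must exceed the stimulus frequency being modelled"
        )
    t_up = 1.0 / ann.up_frequency
    x = grid.times / t_up
    x[x <= 0] = _LOGNORMAL_EPS
    density = stats.lognorm.pdf(x, s=ann.soe, scale=1.0)
    return density / density.max()


def _circular_convolve(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular convolution over the signal's period (kernel wraps)."""
    n = signal.size
    padded = np.zeros(n)
    m = min(kernel.size, n)
    padded[:m] = kernel[:m]
    if kernel.size > n:  # wrap any kernel tail back onto the period
        for i in range(n, kernel.size):
            padded[i % n] += kernel[i]
    return np.fft.irfft(np.fft.rfft(signal) * np.fft.rfft(padded), n)


def ann_waveform(ann: ANNParams, grid: TimeGrid) -> np.ndarray:
    """One cycle of the auditory nerve neurophonic.

    Circularly convolves the cycle histogram with the unit potential,
    normalises the convolved kernel to unit peak magnitude (so ``a_ann``
    is in μV), scales by ``a_ann``, and applies the phase as an
    integer-sample circular shift of ``round(phi_ann * n_samples)``.
    """
    ch = cycle_histogram(ann, grid)
    up = unit_potential(ann.up_frequency, grid.sampling_rate)
    kernel = _circular_convolve(ch, up)
    peak = np.max(np.abs(kernel))
    if peak > 0:
        kernel = kernel / peak
    shift = int(np.round(ann.phi_ann * grid.n_samples))
    return ann.a_ann * np.roll(kernel, shift)


def ecochg_model(params: ModelParams, grid: TimeGrid) -> np.ndarray:
    """Modelled ongoing ECochG: pointwise sum of CM and ANN components."""
    return cm_waveform(params.cm, grid) + ann_waveform(params.ann, grid)
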