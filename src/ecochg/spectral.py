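"""Harmonic spectra, peak significance, and the summed total response.

Magnitudes are single-sided amplitude spectra in μV. A harmonic peak is
called significant when it exceeds the local noise estimate — the mean of
the three FFT bins on either side of the peak (six bins pooled, peak
excluded) — by more than three standard deviations of those bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ParameterError
from .preprocess import AverageCycle

__all__ = [
    "HarmonicRecord",
    "SpectralSummary",
    "harmonic_spectrum",
    "cycle_spectrum",
    "total_response",
]

# Magnitudes below this fraction of the spectral maximum are treated as
# numerically zero when testing significance, so that round-off in an
# otherwise line-free spectrum cannot register as a response.
_NUMERICAL_FLOOR = 1e-9

_NOISE_BINS_PER_SIDE = 3
_SIGNIFICANCE_SD = 3.0


@dataclass(frozen=True)
class HarmonicRecord:
    harmonic: int
    frequency: float
    magnitude: float
    noise_mean: float
    noise_sd: float
    significant: bool


@dataclass(frozen=True)
class SpectralSummary:
    """Per-harmonic magnitudes and significance for one response."""

    harmonics: tuple[HarmonicRecord, ...]
    fft_length: int
    stimulus_frequency: float

    def magnitude(self, harmonic: int) -> float:
        for rec in self.harmonics:
            if rec.harmonic == harmonic:
                return rec.magnitude
        raise KeyError(f"harmonic {harmonic} not analysed")

    def significant_sum(self, max_harmonic: int = 3) -> float:
        return sum(
            rec.magnitude
            for rec in self.harmonics
            if rec.significant and rec.harmonic <= max_harmonic
        )


def harmonic_spectrum(
    samples: np.ndarray,
    sampling_rate: float,
    stimulus_frequency: float,
    n_harmonics: int = 3,
) -> SpectralSummary:
    """Single-sided amplitude spectrum evaluated at stimulus harmonics.

    The series should span an integer number of stimulus cycles so each
    harmonic falls on an FFT bin; the noise statistic at each harmonic is
    taken from the three bins on either side of its peak bin.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n_harmonics < 1:
        raise ParameterError("n_harmonics must be >= 1")
    if n_harmonics * stimulus_frequency >= sampling_rate / 2:
        raise ParameterError(
            f"harmonic {n_harmonics} of {stimulus_frequency} Hz is above "
            f"the Nyquist frequency {sampling_rate / 2} Hz"
        )
    spectrum = np.abs(np.fft.rfft(x)) / n
    # single-sided amplitudes: double everything except DC and (for even
    # lengths) the Nyquist bin, which have no mirror-image counterpart
    if n % 2 == 0:
        spectrum[1:-1] *= 2.0
    else:
        spectrum[1:] *= 2.0
    bin_width = sampling_rate / n
    floor = _NUMERICAL_FLOOR * max(spectrum.max(), np.max(np.abs(x)), 1e-300)

    records = []
    for h in range(1, n_harmonics + 1):
        peak_bin = int(round(h * stimulus_frequency / bin_width))
        if peak_bin >= spectrum.size:
            raise ParameterError(f"harmonic {h} falls outside the spectrum")
        side = np.arange(-_NOISE_BINS_PER_SIDE, _NOISE_BINS_PER_SIDE + 1)
        neighbours = peak_bin + side[side != 0]
        neighbours = neighbours[(neighbours > 0) & (neighbours < spectrum.size)]
        noise = spectrum[neighbours]
        noise_mean = float(noise.mean()) if noise.size else 0.0
        noise_sd = float(noise.std(ddof=0)) if noise.size else 0.0
        magnitude = float(spectrum[peak_bin])
        significant = bool(
            magnitude > noise_mean + _SIGNIFICANCE_SD * noise_sd
            and magnitude > floor
        )
        records.append(
            HarmonicRecord(
                harmonic=h,
                frequency=h * stimulus_frequency,
                magnitude=magnitude,
                noise_mean=noise_mean,
                noise_sd=noise_sd,
                significant=significant,
            )
        )
    return SpectralSummary(
        harmonics=tuple(records),
        fft_length=n,
        stimulus_frequency=stimulus_frequency,
    )


def cycle_spectrum(
    cycle: AverageCycle, n_harmonics: int = 3, n_cycles: int = 8
) -> SpectralSummary:
    """Spectrum of an average cycle tiled over ``n_cycles`` periods.

    Concatenating an integer number of cycles places every harmonic
    exactly on an FFT bin, so no window function is needed.
    """
    tiled = np.tile(cycle.samples, n_cycles)
    return harmonic_spectrum(
        tiled, cycle.sampling_rate, cycle.stimulus_frequency, n_harmonics
    )


def total_response(summaries: Iterable[SpectralSummary]) -> float:
    """Sum of all significant harmonic-1..3 magnitudes across frequencies.

    Summing peak magnitudes (rather than their RMS) weights the distortion
    harmonics more heavily and is insensitive to the CM/ANN phase
    interference that modulates the time-domain peak-to-peak amplitude.
    """
    return float(sum(s.significant_sum(max_harmonic=3) for s in summaries))
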