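"""Windowing and cycle-folding of recorded tone-burst responses.

A tone-burst epoch contains an onset transient (the compound action
potential plus the stimulus rise ramp), the ongoing steady-state response,
and an offset ramp. The model is fitted to the *average cycle*: the
pointwise mean over all whole stimulus cycles of the ongoing region, which
suppresses asynchronous noise by roughly 1/sqrt(cycles) while preserving
everything phase-locked to the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InsufficientDataError, ParameterError, ShapeError

__all__ = ["Waveform", "AverageCycle", "extract_average_cycle", "combine_polarities"]

Polarity = Literal["condensation", "rarefaction", "unknown"]


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled evoked-potential epoch in μV.

    ``rise_time_ms`` / ``fall_time_ms`` describe the stimulus envelope ramps
    and are excluded (together with configurable guard cycles) from the
    ongoing window.
    """

    samples: np.ndarray
    sampling_rate: float
    stimulus_frequency: float
    stimulus_polarity: Polarity = "unknown"
    rise_time_ms: float = 0.0
    fall_time_ms: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not np.all(np.isfinite(samples)):
            raise ParameterError("waveform samples must be finite")
        if self.sampling_rate <= 2 * self.stimulus_frequency:
            raise ParameterError(
                "sampling_rate must exceed twice the stimulus frequency"
            )

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sampling_rate

    @property
    def period_samples(self) -> int:
        return int(round(self.sampling_rate / self.stimulus_frequency))


@dataclass(frozen=True)
class AverageCycle:
    """One stimulus period obtained by folding the ongoing response."""

    samples: np.ndarray
    stimulus_frequency: float
    sampling_rate: float
    n_cycles_folded: int = 1

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.size < 8:
            raise ParameterError("average cycle must hold >= 8 samples")
        if self.n_cycles_folded < 1:
            raise ParameterError("n_cycles_folded must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.samples.size


def extract_average_cycle(
    w: Waveform,
    skip_onset_cycles: int = 2,
    skip_offset_cycles: int = 1,
) -> AverageCycle:
    """Fold the ongoing portion of an epoch into one average cycle.

    The onset window (stimulus rise time plus ``skip_onset_cycles`` whole
    cycles, clearing the CAP region) and the offset window (fall time plus
    ``skip_offset_cycles`` cycles) are discarded; the remaining whole
    cycles are averaged pointwise. A trailing partial cycle is dropped so
    folding never smears phase.
    """
    period = w.period_samples
    onset = int(round(w.rise_time_ms * w.sampling_rate / 1000.0))
    onset += skip_onset_cycles * period
    offset = int(round(w.fall_time_ms * w.sampling_rate / 1000.0))
    offset += skip_offset_cycles * period
    usable = w.samples.size - onset - offset
    n_cycles = usable // period
    if n_cycles < 1:
        raise InsufficientDataError(
            f"epoch of {w.samples.size} samples leaves no whole cycle after "
            f"skipping {onset} onset and {offset} offset samples"
        )
    folded = w.samples[onset : onset + n_cycles * period]
    avg = folded.reshape(n_cycles, period).mean(axis=0)
    return AverageCycle(
        samples=avg,
        stimulus_frequency=w.stimulus_frequency,
        sampling_rate=w.sampling_rate,
        n_cycles_folded=n_cycles,
    )


def combine_polarities(
    cond: Waveform,
    rare: Waveform,
    mode: Literal["difference_half", "sum_half", "single"] = "single",
) -> Waveform:
    """Combine condensation- and rarefaction-phase epochs.

    ``difference_half`` ((cond − rare)/2) emphasises components that invert
    with stimulus polarity (the CM); ``sum_half`` ((cond + rare)/2)
    emphasises polarity-invariant components; ``single`` passes the
    condensation epoch through unchanged.
    """
    if mode == "single":
        return cond
    if cond.samples.shape != rare.samples.shape:
        raise ShapeError("polarity pair differs in length")
    if (
        cond.sampling_rate != rare.sampling_rate
        or cond.stimulus_frequency != rare.stimulus_frequency
    ):
        raise ShapeError("polarity pair differs in rate or stimulus frequency")
    if mode == "difference_half":
        combined = (cond.samples - rare.samples) / 2.0
    elif mode == "sum_half":
        combined = (cond.samples + rare.samples) / 2.0
    else:
        raise ParameterError(f"unknown polarity mode {mode!r}")
    return Waveform(
        samples=combined,
        sampling_rate=cond.sampling_rate,
        stimulus_frequency=cond.stimulus_frequency,
        stimulus_polarity=cond.stimulus_polarity,
        rise_time_ms=cond.rise_time_ms,
        fall_time_ms=cond.fall_time_ms,
    )
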