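"""Summary quantities comparing the fitted CM and ANN components.

The ANN/CM ratio and the ANN/CM index, (ANN − CM)/(ANN + CM), summarise the
neural fraction of the ongoing response: an index of −1 is all CM, 0 equal
amounts, +1 all ANN. Fits rarely report an ANN below ~5% of the CM even
when none is present, so ratios under that floor are treated as "no
neural response" (the ANN magnitude is zeroed); the index is always left
uncensored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import ParameterError
from .fitting import FitResult

__all__ = [
    "DecompositionMetrics",
    "component_magnitudes",
    "ann_cm_ratio",
    "ann_cm_index",
    "decomposition_metrics",
    "apply_small_ratio_cutoff",
    "amplitude_to_db",
    "SMALL_RATIO_THRESHOLD",
]

SMALL_RATIO_THRESHOLD = 0.05

MagnitudeBasis = Literal["parameter", "first_harmonic"]


@dataclass(frozen=True)
class DecompositionMetrics:
    """CM/ANN magnitudes and their derived comparison quantities.

    ``ann_cm_ratio`` and ``ann_cm_index`` always reflect the uncensored
    magnitudes; when the small-ratio cutoff fires, only ``ann_magnitude``
    is zeroed and ``cutoff_applied`` set.
    """

    cm_magnitude: float
    ann_magnitude: float
    ann_cm_ratio: float
    ann_cm_index: float
    ann_re_cm_db: float
    cutoff_applied: bool = False
    basis: MagnitudeBasis = "first_harmonic"


def _first_harmonic_magnitude(series: np.ndarray) -> float:
    n = series.size
    return float(2.0 * np.abs(np.fft.rfft(series)[1]) / n)


def component_magnitudes(
    fit: FitResult, basis: MagnitudeBasis = "first_harmonic"
) -> tuple[float, float]:
    """CM and ANN magnitudes of a fit.

    ``parameter`` returns the fitted amplitude multipliers directly;
    ``first_harmonic`` (default) returns the fundamental's magnitude in
    each separated component waveform, which is what spectral ANN/CM
    ratios compare — for a saturating CM the two differ because clipping
    removes energy from the fundamental.
    """
    if basis == "parameter":
        return fit.params.cm.a_cm, fit.params.ann.a_ann
    if basis == "first_harmonic":
        return (
            _first_harmonic_magnitude(fit.cm_component),
            _first_harmonic_magnitude(fit.ann_component),
        )
    raise ParameterError(f"unknown magnitude basis {basis!r}")


def ann_cm_ratio(ann_magnitude: float, cm_magnitude: float) -> float:
    if cm_magnitude <= 0:
        raise ParameterError("cm_magnitude must be positive for a ratio")
    return ann_magnitude / cm_magnitude


def ann_cm_index(ann_magnitude: float, cm_magnitude: float) -> float:
    """(ANN − CM)/(ANN + CM): −1 all CM, 0 equal, +1 all ANN."""
    if ann_magnitude < 0 or cm_magnitude < 0:
        raise ParameterError("magnitudes must be nonnegative")
    total = ann_magnitude + cm_magnitude
    if total == 0:
        raise ParameterError("index undefined when both magnitudes are zero")
    return (ann_magnitude - cm_magnitude) / total


def amplitude_to_db(value: float, reference: float = 1.0) -> float:
    """Amplitude ratio in dB: 20·log10(value/reference)."""
    if value <= 0 or reference <= 0:
        raise ParameterError("dB conversion needs positive amplitudes")
    return 20.0 * np.log10(value / reference)


def decomposition_metrics(
    fit: FitResult,
    basis: MagnitudeBasis = "first_harmonic",
    small_ratio_threshold: float | None = SMALL_RATIO_THRESHOLD,
) -> DecompositionMetrics:
    """Full metric record for a fit, with the small-ratio cutoff applied."""
    cm_mag, ann_mag = component_magnitudes(fit, basis)
    ratio = ann_cm_ratio(ann_mag, cm_mag)
    index = ann_cm_index(ann_mag, cm_mag)
    db = amplitude_to_db(ann_mag, cm_mag) if ann_mag > 0 else -np.inf
    m = DecompositionMetrics(
        cm_magnitude=cm_mag,
        ann_magnitude=ann_mag,
        ann_cm_ratio=ratio,
        ann_cm_index=index,
        ann_re_cm_db=float(db),
        cutoff_applied=False,
        basis=basis,
    )
    if small_ratio_threshold is not None:
        m = apply_small_ratio_cutoff(m, small_ratio_threshold)
    return m


def apply_small_ratio_cutoff(
    m: DecompositionMetrics, threshold: float = SMALL_RATIO_THRESHOLD
) -> DecompositionMetrics:
    """Zero the reported ANN when the ANN/CM ratio is strictly below threshold.

    The ratio and index fields keep their pre-cutoff values for reporting;
    the cutoff is never applied to the index.
    """
    if m.ann_cm_ratio < threshold:
        return replace(m, ann_magnitude=0.0, cutoff_applied=True)
    return m
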