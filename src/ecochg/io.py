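"""Reading delimited-text recordings and writing analysis reports.

The interchange format is plain delimited text: either a single voltage
column, or a time column followed by a voltage column. Metadata (sampling
rate, stimulus frequency, units, ramp times) comes from ``# key: value``
header lines, with explicit overrides taking precedence. Voltages are
coerced to μV. Reports are JSON; series exports are CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from . import __version__
from .errors import ConfigurationError, DataError
from .fitting import FitResult
from .metrics import DecompositionMetrics
from .preprocess import Waveform
from .spectral import SpectralSummary

__all__ = ["read_recording", "write_report", "write_series_csv", "read_report"]

_UNIT_SCALE_TO_UV = {
    "uv": 1.0,
    "μv": 1.0,
    "µv": 1.0,
    "microvolt": 1.0,
    "microvolts": 1.0,
    "mv": 1000.0,
    "millivolt": 1000.0,
    "millivolts": 1000.0,
    "v": 1e6,
    "volt": 1e6,
    "volts": 1e6,
}

_METADATA_ALIASES = {
    "sampling_rate": "sampling_rate",
    "fs": "sampling_rate",
    "sample_rate": "sampling_rate",
    "stimulus_frequency": "stimulus_frequency",
    "f0": "stimulus_frequency",
    "frequency": "stimulus_frequency",
    "units": "units",
    "unit": "units",
    "polarity": "stimulus_polarity",
    "stimulus_polarity": "stimulus_polarity",
    "rise_time_ms": "rise_time_ms",
    "fall_time_ms": "fall_time_ms",
}


def _parse_header(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            for sep in (":", "="):
                if sep in body:
                    key, _, value = body.partition(sep)
                    key = key.strip().lower().replace(" ", "_")
                    if key in _METADATA_ALIASES:
                        meta[_METADATA_ALIASES[key]] = value.strip()
                    break
    return meta


def read_recording(
    path: str | Path, overrides: Mapping[str, Any] | None = None
) -> Waveform:
    """Load a delimited-text recording as a :class:`Waveform` in μV.

    ``overrides`` may supply or replace any metadata field (CLI flags win
    over file headers). With a two-column file the sampling rate is
    derived from the time column and must be uniform.
    """
    path = Path(path)
    meta: dict[str, Any] = dict(_parse_header(path))
    if overrides:
        meta.update({k: v for k, v in overrides.items() if v is not None})

    try:
        data = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    except Exception:
        try:
            data = np.loadtxt(path, comments="#", delimiter=",", ndmin=2)
        except Exception as exc:
            raise DataError(f"could not parse {path} as delimited text: {exc}")

    if data.shape[1] == 1:
        voltages = data[:, 0]
    elif data.shape[1] == 2:
        times, voltages = data[:, 0], data[:, 1]
        dt = np.diff(times)
        if dt.size == 0 or np.any(dt <= 0):
            raise DataError("time column must be strictly increasing")
        if np.max(np.abs(dt - dt.mean())) > 1e-6 * dt.mean():
            raise DataError("time column is not uniformly sampled")
        fs_from_time = 1.0 / dt.mean()
        declared = meta.get("sampling_rate")
        if declared is not None and abs(float(declared) - fs_from_time) > 1e-3 * fs_from_time:
            raise DataError(
                f"declared sampling rate {declared} Hz disagrees with the "
                f"time column ({fs_from_time:.6g} Hz)"
            )
        meta.setdefault("sampling_rate", fs_from_time)
    else:
        raise DataError(f"expected 1 or 2 data columns, found {data.shape[1]}")

    for required in ("sampling_rate", "stimulus_frequency"):
        if required not in meta:
            raise ConfigurationError(
                f"missing required metadata field '{required}' "
                f"(supply it in the file header or as a flag)"
            )

    units = str(meta.get("units", "uV")).strip().lower()
    if units not in _UNIT_SCALE_TO_UV:
        raise ConfigurationError(f"unrecognised voltage units '{units}'")
    voltages = voltages * _UNIT_SCALE_TO_UV[units]

    return Waveform(
        samples=voltages,
        sampling_rate=float(meta["sampling_rate"]),
        stimulus_frequency=float(meta["stimulus_frequency"]),
        stimulus_polarity=str(meta.get("stimulus_polarity", "unknown")),
        rise_time_ms=float(meta.get("rise_time_ms", 0.0)),
        fall_time_ms=float(meta.get("fall_time_ms", 0.0)),
    )


def _fit_to_dict(fit: FitResult) -> dict[str, Any]:
    p = fit.params
    return {
        "parameters": {
            "a_cm": p.cm.a_cm,
            "phi_cm": p.cm.phi_cm,
            "upper_cutoff": p.cm.upper_cutoff,
            "lower_cutoff": p.cm.lower_cutoff,
            "a_ann": p.ann.a_ann,
            "phi_ann": p.ann.phi_ann,
            "soe": p.ann.soe,
        },
        "phi_cm_canonical": fit.phi_cm_canonical,
        "phi_ann_canonical": fit.phi_ann_canonical,
        "up_frequency": p.ann.up_frequency,
        "r": fit.r,
        "r_squared": fit.r_squared,
        "sse": fit.sse,
        "converged": fit.converged,
        "n_evaluations": fit.n_evaluations,
    }


def write_report(
    fit: FitResult,
    metrics: DecompositionMetrics,
    spectra: SpectralSummary | None,
    path: str | Path,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> None:
    """Serialise one analysis to a JSON report."""
    report: dict[str, Any] = {
        "tool": {"name": "ecochg", "version": __version__},
        "seed": seed,
        "config": dict(config) if config else {},
        "fit": _fit_to_dict(fit),
        "metrics": asdict(metrics),
    }
    if spectra is not None:
        report["spectrum"] = {
            "fft_length": spectra.fft_length,
            "stimulus_frequency": spectra.stimulus_frequency,
            "harmonics": [asdict(h) for h in spectra.harmonics],
        }
    def _coerce(obj):
        if isinstance(obj, np.generic):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"cannot serialise {type(obj)!r}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_coerce)
        fh.write("\n")


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


def write_series_csv(
    fit: FitResult, observed: Sequence[float], path: str | Path
) -> None:
    """Observed, modelled, and separated component series as CSV."""
    obs = np.asarray(observed, dtype=float)
    header = "observed,modeled,cm,ann"
    table = np.column_stack([obs, fit.modeled, fit.cm_component, fit.ann_component])
    np.savetxt(path, table, delimiter=",", header=header, comments="")
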