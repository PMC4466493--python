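"""Ca2+ waveform feature extraction.

Four features summarize a single-layer transient: peak amplitude above the
pre-stimulus baseline, time to peak from stimulation, wave width at half
maximum, and the concentration at the end of the recording window (90 s).
A trace is flagged *typical* when it shows exactly one contiguous excursion
above the half-maximum level — multi-bump or flat responses are atypical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .simulator import TraceSet

__all__ = ["WaveFeatures", "extract_features", "extract_feature_table", "compare_features"]

FEATURE_NAMES = ("peak_amplitude", "time_to_peak", "width_half_max", "end_concentration")


@dataclass(frozen=True)
class WaveFeatures:
    peak_amplitude: float  # peak minus baseline, trace units
    time_to_peak: float  # s from stimulation
    width_half_max: float  # s between half-maximum crossings
    end_concentration: float  # trace value at the end of the window
    is_typical_waveform: bool
    units: str = "uM"

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _crossings(time: np.ndarray, v: np.ndarray, level: float):
    """(first up-crossing, last down-crossing) of ``level``, interpolated."""
    above = v >= level
    t_up = time[0] if above[0] else None
    t_down = time[-1] if above[-1] else None
    for i in range(len(v) - 1):
        if not above[i] and above[i + 1]:
            t = time[i] + (level - v[i]) / (v[i + 1] - v[i]) * (time[i + 1] - time[i])
            if t_up is None:
                t_up = t
        elif above[i] and not above[i + 1]:
            t_down = time[i] + (v[i] - level) / (v[i] - v[i + 1]) * (time[i + 1] - time[i])
    return t_up, t_down


def _n_excursions(above: np.ndarray) -> int:
    """Number of contiguous True runs."""
    padded = np.concatenate(([False], above, [False]))
    return int(np.sum(~padded[:-1] & padded[1:]))


def extract_features(
    time: np.ndarray,
    values: np.ndarray,
    baseline: float,
    end_time: Optional[float] = None,
    units: str = "uM",
) -> WaveFeatures:
    """Extract the four wave features from one layer's series.

    ``end_time`` defaults to 90 s, or to the end of the trace when the trace
    is shorter.  A flat trace (amplitude <= 0) yields NaN features and the
    atypical flag rather than an error; the end concentration is always
    defined.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if end_time is None:
        end_time = min(90.0, float(time[-1]))
    end_conc = float(np.interp(end_time, time, values))

    amplitude = float(np.max(values) - baseline)
    if amplitude <= 0:
        return WaveFeatures(
            peak_amplitude=amplitude,
            time_to_peak=math.nan,
            width_half_max=math.nan,
            end_concentration=end_conc,
            is_typical_waveform=False,
            units=units,
        )
    i_peak = int(np.argmax(values))
    ttp = float(time[i_peak])
    level = baseline + amplitude / 2.0
    t_up, t_down = _crossings(time, values, level)
    width = float(t_down - t_up) if t_up is not None and t_down is not None else math.nan
    typical = _n_excursions(values >= level) == 1
    return WaveFeatures(
        peak_amplitude=amplitude,
        time_to_peak=ttp,
        width_half_max=width,
        end_concentration=end_conc,
        is_typical_waveform=typical,
        units=units,
    )


def extract_feature_table(
    traces: TraceSet, baseline: Optional[float] = None, end_time: Optional[float] = None
) -> pd.DataFrame:
    """Features for every layer of a trace set, one row per layer.

    The default baseline is 1.0 for NF traces and the basal 0.12 μM
    otherwise.
    """
    if baseline is None:
        baseline = 1.0 if traces.units == "NF" else 0.12
    rows = []
    for j, n in enumerate(traces.layer_indices):
        f = extract_features(
            traces.time, traces.ca[:, j], baseline, end_time=end_time, units=traces.units
        )
        rows.append({"layer": n, **f.as_dict(), "is_typical_waveform": f.is_typical_waveform})
    return pd.DataFrame(rows)


def compare_features(a: WaveFeatures, b: WaveFeatures) -> dict:
    """Percent change of each feature from ``a`` to ``b``: 100 (b - a) / a.

    Entries whose reference is zero (or NaN) are returned as NaN rather than
    raising — callers flag them as undefined.  Unit tags must agree.
    """
    if a.units != b.units:
        raise ValueError(f"unit mismatch: {a.units} vs {b.units}")
    out = {}
    for name in FEATURE_NAMES:
        ref, new = getattr(a, name), getattr(b, name)
        if not np.isfinite(ref) or not np.isfinite(new) or ref == 0:
            out[name] = math.nan
        else:
            out[name] = 100.0 * (new - ref) / ref
    return out
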