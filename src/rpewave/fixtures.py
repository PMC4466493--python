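"""Synthetic trace generation.

Two generators stand in for the experimental recordings, which are not
published:

* :func:`generate_model_truth` runs the mechanistic simulator at known
  parameters, converts to normalized fluorescence, resamples to the
  experimental 1-s grid and adds Gaussian noise — the ground-truth fixture
  for parameter-recovery tests.
* :func:`generate_phenomenological` builds purely descriptive single-peak
  transients (amplitude decaying and latency growing with ring index) so
  the feature and fitting plumbing can be exercised independently of the
  ODE model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CellGeometry, layer_distances
from .params import ModelParams
from .simulator import TraceSet, simulate, to_normalized_fluorescence
from .stimulus import StimulusParams

__all__ = [
    "FixtureSpec",
    "PhenomShape",
    "generate_model_truth",
    "generate_phenomenological",
]


@dataclass(frozen=True)
class FixtureSpec:
    generator: str = "model_truth"  # "model_truth" | "phenomenological"
    noise_sd: float = 0.02  # additive Gaussian noise, NF units
    sampling_step: float = 1.0  # s, the experimental sampling rate
    seed: int = 0
    scenario: str = "GA_treated"
    t_end: float = 90.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_step <= 0:
            raise ValueError("sampling_step must be positive")


@dataclass(frozen=True)
class PhenomShape:
    """Shape constants of the phenomenological pulse.

    Per ring at distance x: an NF baseline of 1 plus a log-normal-shaped
    pulse of amplitude ``amp0 · exp(-amp_decay · x)`` starting after an
    onset delay ``onset0 + onset_slope · x``.  Defaults give ring-1
    responses of about one NF unit that fall to roughly a tenth of that at
    the outermost ring, with latencies growing from a few seconds to ~20 s
    — the qualitative shape of the recorded waves.
    """

    amp0: float = 1.2  # NF units at x = 0
    amp_decay: float = 0.02  # 1/μm
    onset0: float = 2.0  # s
    onset_slope: float = 0.15  # s/μm
    rise_time: float = 6.0  # s, peak delay after onset
    log_sd: float = 0.6  # log-normal shape width


def _resample(traces: TraceSet, step: float) -> TraceSet:
    t_new = np.arange(0.0, traces.time[-1] + step / 2, step)
    ca = np.column_stack(
        [np.interp(t_new, traces.time, traces.ca[:, j]) for j in range(traces.n_layers)]
    )
    return TraceSet(
        time=t_new,
        ca=ca,
        units=traces.units,
        scenario=traces.scenario,
        layer_indices=traces.layer_indices,
        metadata=dict(traces.metadata),
    )


def generate_model_truth(
    spec: FixtureSpec,
    params: ModelParams = ModelParams(),
    geometry: CellGeometry = CellGeometry(),
    stim: StimulusParams = StimulusParams(),
) -> tuple[TraceSet, dict]:
    """Simulate at known parameters and dress the output as experimental data.

    Returns the noisy NF trace set and a truth record containing the
    generating parameters and the fixture spec, so recovery tests can close
    the loop.
    """
    sim = simulate(spec.scenario, params, geometry, stim, t_end=spec.t_end)
    nf = to_normalized_fluorescence(sim)
    out = _resample(nf, spec.sampling_step)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        out.ca = out.ca + rng.normal(0.0, spec.noise_sd, size=out.ca.shape)
    out.metadata.update({"generator": "model_truth", "seed": spec.seed,
                         "noise_sd": spec.noise_sd})
    truth = {
        "params": params.to_dict(),
        "spec": {
            "generator": spec.generator,
            "noise_sd": spec.noise_sd,
            "sampling_step": spec.sampling_step,
            "seed": spec.seed,
            "scenario": spec.scenario,
            "t_end": spec.t_end,
        },
    }
    return out, truth


def generate_phenomenological(
    spec: FixtureSpec,
    geometry: CellGeometry = CellGeometry(),
    shape: PhenomShape = PhenomShape(),
) -> TraceSet:
    """Descriptive NF traces with the qualitative shape of the recordings."""
    x = layer_distances(geometry)
    t = np.arange(0.0, spec.t_end + spec.sampling_step / 2, spec.sampling_step)
    rng = np.random.default_rng(spec.seed)
    ca = np.ones((len(t), len(x)))
    for j, xn in enumerate(x):
        amp = shape.amp0 * np.exp(-shape.amp_decay * xn)
        onset = shape.onset0 + shape.onset_slope * xn
        tau = np.clip(t - onset, 0.0, None)
        pulse = np.zeros_like(t)
        pos = tau > 0
        pulse[pos] = np.exp(
            -((np.log(tau[pos]) - np.log(shape.rise_time)) ** 2) / (2.0 * shape.log_sd**2)
        )
        ca[:, j] += amp * pulse
    if spec.noise_sd > 0:
        ca += rng.normal(0.0, spec.noise_sd, size=ca.shape)
    return TraceSet(
        time=t,
        ca=ca,
        units="NF",
        scenario=spec.scenario,
        metadata={"generator": "phenomenological", "seed": spec.seed,
                  "noise_sd": spec.noise_sd},
    )
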