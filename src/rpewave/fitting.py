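"""Least-squares calibration against per-layer traces.

The calibration mirrors the staged protocol used to parameterize the model:

1. core release/clearance parameters (k_IP3R3, k_RyR, V_Pump, K_Pump,
   J_Leak) on ring 5 of the gap-junction-blocked recordings — the largest
   response among rings that feel no stretch;
2. the stretch-channel block (k_SSCC, k_f, k_b, k_theta) on ring 1 of the
   same recordings;
3. the gap-junction block (D_Ca, D_IP3, In_Ca, In_IP3) on ring 1 of the
   control recordings, everything else frozen;
4. per-ring K1 and k_p on the suramin recordings.

Objectives are unweighted sums of squared residuals between the simulated
Ca2+ series and the target series on the data's own time grid (constant
error model); the optimizer is bounded trust-region least squares with a
configurable iteration cap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .geometry import CellGeometry, layer_distance
from .params import ModelParams
from .simulator import Scenario, SimulationError, TraceSet, simulate, to_micromolar
from .stimulus import ScenarioName, StimulusParams

__all__ = [
    "FitTask",
    "FitResult",
    "fit",
    "staged_calibration",
    "fit_location_law",
    "STAGE_PARAMS",
]

STAGE_PARAMS = {
    "core": ("k_IP3R3", "k_RyR", "V_Pump", "K_Pump", "J_Leak"),
    "sscc": ("k_SSCC", "k_f", "k_b", "k_theta"),
    "gj": ("D_Ca", "D_IP3", "In_Ca", "In_IP3"),
    "suramin": ("K1", "k_p"),
}

#: Residual value substituted when a perturbed simulation fails; large but
#: finite so the optimizer backs away instead of crashing.
_PENALTY = 1e3


@dataclass
class FitTask:
    """One bounded least-squares problem.

    ``free`` lists parameter names; ``bounds`` optionally overrides the
    default box, which spans 0.2–5x the starting value (sign-preserving,
    and symmetric about zero for the sign-free In_Ca).
    """

    free: Sequence[str]
    target: TraceSet
    scenario: str
    layers: Sequence[int]
    max_iterations: int = 100
    bounds: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.free:
            raise ValueError("free parameter list must be non-empty")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class FitResult:
    values: dict
    r2: dict  # per objective layer
    residual_norm: float
    converged: bool
    n_evals: int
    message: str = ""


def _default_bounds(name: str, x0: float) -> tuple:
    if name == "In_Ca" or x0 == 0.0:
        w = max(abs(x0), 1e-3)
        return (-5.0 * w, 5.0 * w)
    lo, hi = sorted((0.2 * x0, 5.0 * x0))
    return (lo, hi)


def fit(
    task: FitTask,
    params: ModelParams = ModelParams(),
    geometry: CellGeometry = CellGeometry(),
    stim: StimulusParams = StimulusParams(),
) -> FitResult:
    """Minimize the squared residuals of the free parameters.

    The target trace set must be in μM (convert NF data first).  When gap
    junctions are off the objective simulates only the target rings, which
    are exactly decoupled from the rest of the monolayer.
    """
    if task.target.units != "uM":
        raise ValueError("fit target must be in μM; convert NF data explicitly")
    scen_name = ScenarioName.parse(task.scenario)
    scenario = Scenario.from_name(scen_name, geometry)
    if scen_name is ScenarioName.GA_SURAMIN and set(task.free) & {"K1", "k_p"}:
        # the per-ring overrides are exactly what is being fitted here
        scenario = Scenario(name=scen_name, gap_junctions_on=False)
    layer_subset = None if scenario.gap_junctions_on else list(task.layers)

    t_data = task.target.time
    data = np.column_stack([task.target.layer(n) for n in task.layers])
    t_end = float(t_data[-1])

    names = list(task.free)
    x0 = np.array([getattr(params, n) for n in names], dtype=float)
    bounds = [task.bounds.get(n, _default_bounds(n, v)) for n, v in zip(names, x0)]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def simulate_at(x: np.ndarray) -> np.ndarray:
        p = params.replace(**dict(zip(names, x)))
        traces = simulate(
            scenario, p, geometry, stim, t_end=t_end, layer_subset=layer_subset,
            keep_states=False,
        )
        sim = np.column_stack(
            [np.interp(t_data, traces.time, traces.layer(n)) for n in task.layers]
        )
        return sim

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            sim = simulate_at(x)
        except SimulationError:
            return np.full(data.size, _PENALTY)
        return (sim - data).ravel()

    max_nfev = task.max_iterations * (len(names) + 1)
    res = least_squares(
        residuals,
        x0,
        bounds=(lo, hi),
        max_nfev=max_nfev,
        x_scale=np.maximum(np.abs(x0), 1e-6),
        method="trf",
    )
    values = dict(zip(names, (float(v) for v in res.x)))
    try:
        sim = simulate_at(res.x)
        r2 = {}
        for j, n in enumerate(task.layers):
            ss_res = float(np.sum((sim[:, j] - data[:, j]) ** 2))
            ss_tot = float(np.sum((data[:, j] - data[:, j].mean()) ** 2))
            r2[n] = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    except SimulationError:
        r2 = {n: math.nan for n in task.layers}
    return FitResult(
        values=values,
        r2=r2,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.status > 0),
        n_evals=int(res.nfev),
        message=str(res.message),
    )


def _as_micromolar(traces: TraceSet, baseline: float) -> TraceSet:
    if traces.units == "NF":
        return to_micromolar(traces, baseline=baseline)
    return traces


def staged_calibration(
    datasets: Mapping[str, TraceSet],
    geometry: CellGeometry = CellGeometry(),
    stim: StimulusParams = StimulusParams(),
    initial: ModelParams = ModelParams(),
    max_iterations: int = 100,
    suramin_layers: Optional[Sequence[int]] = None,
    nf_baseline: Optional[float] = None,
) -> tuple[ModelParams, dict]:
    """Run the staged protocol and return (calibrated params, stage results).

    ``datasets`` maps scenario names to trace sets (NF traces are converted
    to μM with the basal 0.12 μM reference, or ``nf_baseline``).  Missing
    scenarios skip their stage with a warning.  The suramin stage fits K1
    and k_p ring by ring; its per-ring values are reported in the results
    dict, not folded into the returned scalar parameter set.
    """
    b = initial.Ca0 if nf_baseline is None else nf_baseline
    params = initial
    results: dict = {}

    ga = datasets.get(ScenarioName.GA_TREATED.value)
    if ga is not None:
        ga = _as_micromolar(ga, b)
        for stage, layers in (("core", [5]), ("sscc", [1])):
            task = FitTask(
                free=STAGE_PARAMS[stage], target=ga,
                scenario=ScenarioName.GA_TREATED.value, layers=layers,
                max_iterations=max_iterations,
            )
            res = fit(task, params, geometry, stim)
            params = params.replace(**res.values)
            results[stage] = res
    else:
        warnings.warn("no GA-treated traces: core and SSCC stages skipped")

    ctrl = datasets.get(ScenarioName.CONTROL.value)
    if ctrl is not None:
        ctrl = _as_micromolar(ctrl, b)
        task = FitTask(
            free=STAGE_PARAMS["gj"], target=ctrl,
            scenario=ScenarioName.CONTROL.value, layers=[1],
            max_iterations=max_iterations,
        )
        res = fit(task, params, geometry, stim)
        params = params.replace(**res.values)
        results["gj"] = res
    else:
        warnings.warn("no control traces: gap-junction stage skipped")

    sur = datasets.get(ScenarioName.GA_SURAMIN.value)
    if sur is not None:
        sur = _as_micromolar(sur, b)
        layers = list(suramin_layers) if suramin_layers is not None else list(sur.layer_indices)
        per_layer = {}
        for n in layers:
            task = FitTask(
                free=STAGE_PARAMS["suramin"], target=sur,
                scenario=ScenarioName.GA_SURAMIN.value, layers=[n],
                max_iterations=max_iterations,
                # antagonist effects can raise K1/k_p far above their drug-free
                # values, so this stage gets wide pharmacological bounds
                bounds={"K1": (0.5, 50.0), "k_p": (0.003, 1.0)},
            )
            per_layer[n] = fit(task, params, geometry, stim)
        results["suramin"] = per_layer

    return params, results


def fit_location_law(
    per_layer_values: Mapping[int, float],
    law: str = "exp_decay",
    geometry: CellGeometry = CellGeometry(),
) -> tuple:
    """Fit ``value = c · exp(b x)`` over the layers' distances.

    Returns (prefactor c, rate b, R²) with R² computed on the original
    scale; the sign of ``b`` is free, so a decaying law comes back with
    b < 0.  Positive values are fitted log-linearly first and refined by a
    nonlinear pass; non-positive entries force a direct nonlinear fit whose
    initial rate sign follows ``law`` (``exp_decay`` or ``exp_rise``).
    """
    if law not in ("exp_decay", "exp_rise"):
        raise ValueError("law must be 'exp_decay' or 'exp_rise'")
    layers = sorted(per_layer_values)
    if len(layers) < 3:
        raise ValueError("need values for at least 3 layers")
    x = np.array([layer_distance(n, geometry) for n in layers])
    y = np.array([per_layer_values[n] for n in layers], dtype=float)

    model = lambda x, c, b: c * np.exp(b * x)
    if np.all(y > 0):
        slope, intercept = np.polyfit(x, np.log(y), 1)
        p0 = (math.exp(intercept), slope)
    else:
        sign = -1.0 if law == "exp_decay" else 1.0
        p0 = (max(np.max(np.abs(y)), 1e-12), sign * 0.01)
    try:
        popt, _ = curve_fit(model, x, y, p0=p0, maxfev=10000)
    except RuntimeError:
        popt = p0
    c, bcoef = float(popt[0]), float(popt[1])
    resid = y - model(x, c, bcoef)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else math.nan
    return c, bcoef, r2
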