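"""Local sensitivity analysis by one-at-a-time parameter perturbation.

Each selected parameter is scaled by a set of fractions (default −25%,
−10%, +10%, +25%), the monolayer is re-simulated, and the percent change of
every wave feature relative to the unperturbed run is tabulated at the
reporting layers (default rings 1, 5 and 10).  Three entries are fields
rather than scalar constants — ``theta``, ``L`` and ``alpha4`` — and are
scaled uniformly over space, which for these exponential laws is the same
as scaling the prefactor.

Special cases:

* ``xi`` is the mobile fraction of surface receptors; its perturbation
  regenerates the initial surface pool ``R_S(0) = xi · R_T`` so that the
  perturbed model remains internally consistent (the receptor occupancy is
  normalized by the mobile pool).
* a perturbed run that fails to integrate, or a feature whose reference is
  ~0, is recorded as a flagged row instead of raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, extract_features
from .geometry import CellGeometry
from .params import ModelParams
from .simulator import Scenario, SimulationError, simulate
from .stimulus import ScenarioName, StimulusParams

__all__ = [
    "SensitivitySpec",
    "apply_perturbation",
    "run_sensitivity",
    "p2y2_suramin_screen",
    "max_abs_change",
    "insensitive_parameters",
]

#: Field names resolved against StimulusParams scale factors instead of
#: ModelParams constants.
FIELD_SCALES = {"theta": "theta_scale", "L": "ligand_scale", "alpha4": "alpha4_scale"}

#: Parameter set screened for the suramin mechanism: receptor regulation
#: plus the G-protein cascade.
SURAMIN_SCREEN_PARAMS = ("K1", "K2", "k_r", "k_p", "k_e", "xi", "k_a", "k_d", "delta")


@dataclass(frozen=True)
class SensitivitySpec:
    parameters: Sequence[str] = (
        "k_IP3R3", "k_RyR", "V_Pump", "K_Pump", "J_Leak",
        "theta", "L", "alpha4", "In_IP3", "In_Ca", "D_IP3", "D_Ca",
    )
    perturbations: Sequence[float] = (-0.25, -0.10, 0.10, 0.25)
    layers: Sequence[int] = (1, 5, 10)
    scenario: str = "control"

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("parameter list must be non-empty")


def apply_perturbation(
    params: ModelParams, stim: StimulusParams, name: str, fraction: float
) -> tuple[ModelParams, StimulusParams]:
    """Return (params, stimulus) with ``name`` scaled by ``1 + fraction``."""
    scale = 1.0 + fraction
    if name in FIELD_SCALES:
        key = FIELD_SCALES[name]
        return params, stim.scaled(**{key: getattr(stim, key) * scale})
    if not hasattr(params, name):
        raise ValueError(f"unknown parameter {name!r}")
    changes = {name: getattr(params, name) * scale}
    if name == "xi":
        changes["R_S0"] = changes["xi"] * params.R_T
    return params.replace(**changes), stim


def _feature_rows(traces, layers, baseline):
    out = {}
    for n in layers:
        f = extract_features(traces.time, traces.layer(n), baseline)
        out[n] = f
    return out


def run_sensitivity(
    spec: SensitivitySpec,
    params: ModelParams = ModelParams(),
    geometry: CellGeometry = CellGeometry(),
    stim: StimulusParams = StimulusParams(),
    t_end: float = 90.0,
    baseline: Optional[float] = None,
) -> pd.DataFrame:
    """Long-format sensitivity table.

    Columns: parameter, perturbation, layer, feature, reference, value,
    percent_change, exceeds_50pct, atypical_waveform, undefined, failed.
    The unperturbed model is simulated exactly once and is the reference
    for every row; a 0 entry in ``spec.perturbations`` therefore reports
    exact zeros.
    """
    scen_name = ScenarioName.parse(spec.scenario)
    scenario = Scenario.from_name(scen_name, geometry)
    if baseline is None:
        baseline = params.Ca0
    ref_traces = simulate(scenario, params, geometry, stim, t_end=t_end)
    ref = _feature_rows(ref_traces, spec.layers, baseline)

    rows = []
    for name in spec.parameters:
        for frac in spec.perturbations:
            if frac == 0:
                pert = ref
                failed = False
            else:
                p2, s2 = apply_perturbation(params, stim, name, frac)
                try:
                    traces = simulate(scenario, p2, geometry, s2, t_end=t_end)
                    pert = _feature_rows(traces, spec.layers, baseline)
                    failed = False
                except SimulationError:
                    pert = None
                    failed = True
            for n in spec.layers:
                for feat in FEATURE_NAMES:
                    r = getattr(ref[n], feat)
                    if failed:
                        v = math.nan
                        pct = math.nan
                        atypical = True
                    else:
                        v = getattr(pert[n], feat)
                        atypical = not pert[n].is_typical_waveform
                        if not np.isfinite(r) or r == 0 or not np.isfinite(v):
                            pct = math.nan
                        else:
                            pct = 100.0 * (v - r) / r
                    rows.append({
                        "parameter": name,
                        "perturbation": frac,
                        "layer": n,
                        "feature": feat,
                        "reference": r,
                        "value": v,
                        "percent_change": pct,
                        "exceeds_50pct": bool(np.isfinite(pct) and abs(pct) > 50.0),
                        "atypical_waveform": atypical,
                        "undefined": not np.isfinite(pct),
                        "failed": failed,
                    })
    return pd.DataFrame(rows)


def p2y2_suramin_screen(
    params: ModelParams = ModelParams(),
    geometry: CellGeometry = CellGeometry(),
    stim: StimulusParams = StimulusParams(),
    perturbations: Sequence[float] = (-0.25, 0.25),
    layers: Sequence[int] = (1, 5, 10),
) -> pd.DataFrame:
    """±25% screen of the receptor/G-protein parameters, uncoupled scenario.

    Used for mechanism triage of the suramin effect: the synthetic feature
    deltas of each candidate parameter are compared against the observed
    differences between the drug-treated and untreated recordings.
    """
    spec = SensitivitySpec(
        parameters=SURAMIN_SCREEN_PARAMS,
        perturbations=tuple(perturbations),
        layers=tuple(layers),
        scenario=ScenarioName.GA_TREATED.value,
    )
    return run_sensitivity(spec, params, geometry, stim)


def max_abs_change(table: pd.DataFrame, parameters: Optional[Sequence[str]] = None) -> float:
    """Largest |percent change| over the (optionally restricted) table."""
    t = table if parameters is None else table[table.parameter.isin(parameters)]
    vals = t["percent_change"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    return float(np.max(np.abs(vals))) if len(vals) else math.nan


def insensitive_parameters(table: pd.DataFrame, threshold_pct: float = 5.0) -> list:
    """Parameters whose every feature change stays below the threshold."""
    out = []
    for name, grp in table.groupby("parameter", sort=False):
        m = max_abs_change(grp)
        if np.isfinite(m) and m < threshold_pct and not grp.failed.any():
            out.append(name)
    return out
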