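"""Run configuration loading.

A run configuration is a YAML (or JSON) document with optional blocks
``geometry``, ``stimulus``, ``params``, ``scenario`` and ``solver``; any
omitted entry falls back to the frozen defaults.  Example::

    geometry:
      side_length_um: 7.0
      cell_height_um: 12.0
      cytoplasm_fraction: 0.7
      n_layers: 10
    stimulus:
      L0: 1310.0
    params:
      k_RyR: 16.04
    scenario:
      name: control
    solver:
      t_end: 90.0
      output_step: 0.1
      rtol: 1.0e-6
      atol: 1.0e-9
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .geometry import CellGeometry
from .params import ModelParams
from .simulator import Scenario
from .stimulus import StimulusParams

__all__ = ["RunConfig", "load_config"]

_GEOMETRY_KEYS = {
    "side_length_um": "side_length",
    "cell_height_um": "cell_height",
    "cytoplasm_fraction": "cytoplasm_fraction",
    "n_layers": "n_layers",
}

_DEFAULT_SOLVER = {"t_end": 90.0, "output_step": 0.1, "rtol": 1e-6, "atol": 1e-9,
                   "method": "RK45"}


@dataclass
class RunConfig:
    geometry: CellGeometry
    stimulus: StimulusParams
    params: ModelParams
    scenario: Scenario
    solver: dict = field(default_factory=lambda: dict(_DEFAULT_SOLVER))


def load_config(path: str, scenario: str | None = None) -> RunConfig:
    """Load a run configuration, optionally overriding the scenario name."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}

    geo_block = doc.get("geometry", {})
    geometry = CellGeometry(**{_GEOMETRY_KEYS.get(k, k): v for k, v in geo_block.items()})
    stim = StimulusParams(**doc.get("stimulus", {}))
    params = ModelParams(**doc.get("params", {}))

    scen_block = dict(doc.get("scenario", {}))
    name = scenario or scen_block.get("name", "control")
    scen = Scenario.from_name(name, geometry)
    if "K1_per_layer" in scen_block or "k_p_per_layer" in scen_block:
        scen = Scenario(
            name=scen.name,
            gap_junctions_on=scen.gap_junctions_on,
            K1_per_layer=tuple(scen_block.get("K1_per_layer", scen.K1_per_layer or ())) or None,
            k_p_per_layer=tuple(scen_block.get("k_p_per_layer", scen.k_p_per_layer or ())) or None,
        )

    solver = {**_DEFAULT_SOLVER, **doc.get("solver", {})}
    return RunConfig(geometry=geometry, stimulus=stim, params=params,
                     scenario=scen, solver=solver)
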