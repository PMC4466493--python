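"""Assembly and integration of the multicellular ODE system.

Each of the ``n_layers`` concentric rings carries eight state variables
(SSCC open fraction, stretch, two receptor pools, active G protein, IP3,
PIP2, Ca2+).  The rings are coupled only through the gap-junction fluxes,
which are present in the control scenario and absent when gap junctions are
pharmacologically blocked.  The intracellular Ca2+ balance per ring is

    dCa/dt = J_SSCC + J_IP3R3 + J_RyR - J_Pump + J_Leak + J_GJ,Ca

with the stretch component restricted to the rings nearest the stimulus.
Integration uses an adaptive Dormand–Prince 5(4) pair with dense output on
a uniform reporting grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import fluxes
from .geometry import CellGeometry, interface_areas, layer_distances
from .params import STATE_FIELDS, ModelParams, count_to_um
from .stimulus import (
    ScenarioName,
    StimulusParams,
    initial_stretch,
    ip3r_phosphorylation_rate,
    ligand_concentration,
)

__all__ = [
    "Scenario",
    "TraceSet",
    "SimulationError",
    "assemble_rhs",
    "initial_state",
    "simulate",
    "to_normalized_fluorescence",
    "to_micromolar",
]

#: Endpoints of the per-layer suramin refit of the receptor parameters:
#: (value at ring 1, value at the outermost ring).  Intermediate rings are
#: interpolated linearly in distance.
SURAMIN_K1_ENDPOINTS = (8.83, 5.15)  # μM
SURAMIN_KP_ENDPOINTS = (0.19, 0.05)  # 1/s


class SimulationError(RuntimeError):
    """Raised when the ODE integration fails or produces non-finite state."""


@dataclass(frozen=True)
class Scenario:
    """Which experimental condition to simulate.

    ``gap_junctions_on`` switches component VI (including the constant
    MS-cell input fluxes into ring 1).  ``K1_per_layer``/``k_p_per_layer``
    override the receptor parameters ring by ring; they are used by the
    GA+suramin condition, whose refit touches only these two parameters.
    """

    name: ScenarioName
    gap_junctions_on: bool
    K1_per_layer: Optional[tuple] = None
    k_p_per_layer: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.name is ScenarioName.CONTROL and not self.gap_junctions_on:
            raise ValueError("control scenario requires gap junctions on")
        if self.name is not ScenarioName.CONTROL and self.gap_junctions_on:
            raise ValueError(f"{self.name.value} scenario requires gap junctions off")
        if self.name is not ScenarioName.GA_SURAMIN and (
            self.K1_per_layer is not None or self.k_p_per_layer is not None
        ):
            raise ValueError("per-layer K1/k_p overrides are specific to the suramin scenario")

    @classmethod
    def from_name(
        cls,
        name: "str | ScenarioName",
        geometry: CellGeometry = CellGeometry(),
    ) -> "Scenario":
        name = ScenarioName.parse(name)
        if name is ScenarioName.CONTROL:
            return cls(name=name, gap_junctions_on=True)
        if name is ScenarioName.GA_TREATED:
            return cls(name=name, gap_junctions_on=False)
        x = layer_distances(geometry)
        frac = (x - x[0]) / (x[-1] - x[0]) if len(x) > 1 else np.zeros(1)
        K1 = SURAMIN_K1_ENDPOINTS[0] + frac * (SURAMIN_K1_ENDPOINTS[1] - SURAMIN_K1_ENDPOINTS[0])
        k_p = SURAMIN_KP_ENDPOINTS[0] + frac * (SURAMIN_KP_ENDPOINTS[1] - SURAMIN_KP_ENDPOINTS[0])
        return cls(
            name=name,
            gap_junctions_on=False,
            K1_per_layer=tuple(K1),
            k_p_per_layer=tuple(k_p),
        )


@dataclass
class TraceSet:
    """Per-layer time series on a uniform grid.

    ``ca`` has shape (n_times, n_layers); ``states``, when present, has
    shape (n_times, 8, n_layers) in :data:`~rpewave.params.STATE_FIELDS`
    order.  ``units`` is ``"uM"`` for concentrations or ``"NF"`` for
    normalized fluorescence (trace divided by its pre-stimulus baseline).
    """

    time: np.ndarray
    ca: np.ndarray
    units: str = "uM"
    scenario: str = ""
    layer_indices: tuple = ()
    states: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        if self.ca.shape[0] != self.time.shape[0]:
            raise ValueError("ca series length must match the time grid")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not self.layer_indices:
            self.layer_indices = tuple(range(1, self.ca.shape[1] + 1))

    @property
    def n_layers(self) -> int:
        return self.ca.shape[1]

    def layer(self, n: int) -> np.ndarray:
        """Ca series of ring ``n`` (1-based experiment numbering)."""
        return self.ca[:, self.layer_indices.index(n)]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.time}
        for j, n in enumerate(self.layer_indices):
            cols[f"ca_nb{n}"] = self.ca[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.to_dataframe().to_csv(path, index=False)
        if sidecar:
            meta = {
                "units": self.units,
                "scenario": self.scenario,
                "layer_indices": list(self.layer_indices),
                **self.metadata,
            }
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=2, default=str)

    @classmethod
    def from_csv(cls, path, units: str = "uM", scenario: str = "") -> "TraceSet":
        df = pd.read_csv(path)
        layer_cols = [c for c in df.columns if c.startswith("ca_nb")]
        idx = tuple(int(c.removeprefix("ca_nb")) for c in layer_cols)
        return cls(
            time=df["time_s"].to_numpy(),
            ca=df[layer_cols].to_numpy(),
            units=units,
            scenario=scenario,
            layer_indices=idx,
        )


def initial_state(
    params: ModelParams,
    geometry: CellGeometry,
    stim: StimulusParams,
    layer_subset: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Flattened initial state (8 x n_layers) at stimulation time.

    All pools start at their basal values; the stretch variable starts from
    its location law on the rings within reach of the mechanical wave and at
    zero beyond them.
    """
    x = layer_distances(geometry)
    n_idx = np.arange(1, geometry.n_layers + 1)
    if layer_subset is not None:
        sel = np.array([n - 1 for n in layer_subset])
        x, n_idx = x[sel], n_idx[sel]
    theta0 = initial_stretch(x, stim, n=n_idx)
    nl = len(x)
    y0 = np.empty((8, nl))
    y0[0] = 0.0  # O_SSCC
    y0[1] = theta0
    y0[2] = params.R_S0
    y0[3] = params.R_Sp0
    y0[4] = params.G0
    y0[5] = params.IP3_0
    y0[6] = params.PIP2_0
    y0[7] = params.Ca0
    return y0.ravel()


def assemble_rhs(
    scenario: Scenario,
    params: ModelParams,
    geometry: CellGeometry,
    stim: StimulusParams,
    ligand_epsilon: float = 0.1,
    layer_subset: Optional[Sequence[int]] = None,
):
    """Build the flat right-hand side f(t, y) of the coupled system.

    ``layer_subset`` restricts the system to the named rings (1-based);
    this is only admissible when gap junctions are off, in which case the
    rings are exactly decoupled and a single ring can be integrated alone.
    The ligand forcing, singular at t = 0, is evaluated at ``max(t,
    ligand_epsilon)``.
    """
    nl_full = geometry.n_layers
    if layer_subset is None:
        layer_subset = range(1, nl_full + 1)
    layer_subset = list(layer_subset)
    if any(not 1 <= n <= nl_full for n in layer_subset):
        raise ValueError("layer_subset entries out of range")
    if scenario.gap_junctions_on and len(layer_subset) != nl_full:
        raise ValueError("layer subsets require gap junctions off (decoupled rings)")

    sel = np.array([n - 1 for n in layer_subset])
    x = layer_distances(geometry)[sel]
    n_idx = np.arange(1, nl_full + 1)[sel]
    nl = len(sel)
    areas = interface_areas(geometry)
    alpha4 = np.asarray(ip3r_phosphorylation_rate(x, scenario.name, stim), dtype=float).reshape(nl)
    sscc_mask = (n_idx <= stim.stretch_max_layer).astype(float)

    if scenario.K1_per_layer is not None:
        K1 = np.asarray(scenario.K1_per_layer, dtype=float)[sel]
    else:
        K1 = np.full(nl, params.K1)
    if scenario.k_p_per_layer is not None:
        k_p = np.asarray(scenario.k_p_per_layer, dtype=float)[sel]
    else:
        k_p = np.full(nl, params.k_p)

    p = params
    c2u = count_to_um(p)
    gj_on = scenario.gap_junctions_on

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        if y.size != 8 * nl:
            raise ValueError(f"state vector length {y.size}, expected {8 * nl}")
        s = y.reshape(8, nl)
        O, theta, R_S, R_Sp, G, IP3, PIP2, Ca = s

        te = max(t, ligand_epsilon)
        L = ligand_concentration(x, te, stim)

        dO, dtheta = fluxes.sscc_rates(O, theta, p)
        dR_S, dR_Sp = fluxes.p2y2_receptor_rates(R_S, R_Sp, L, p, K1=K1, k_p=k_p)
        dG = fluxes.gprotein_rate(G, R_S, L, p, K1=K1)
        r_h = fluxes.plc_hydrolysis_rate(Ca, G, p)
        dIP3 = r_h * PIP2 * c2u - p.k_deg * IP3
        dPIP2 = -(r_h + p.r_r) * PIP2 - p.r_r * IP3 / c2u + p.r_r * p.PIP2_T

        dCa = (
            fluxes.sscc_flux(O, p) * sscc_mask
            + fluxes.ip3r3_flux(Ca, IP3, alpha4, p)
            + fluxes.ryr_flux(Ca, p)
            - fluxes.pump_flux(Ca, p)
            + p.J_Leak
        )
        if gj_on:
            j_ca, j_ip3 = fluxes.gj_fluxes(Ca, IP3, areas, p)
            dCa = dCa + j_ca
            dIP3 = dIP3 + j_ip3

        out = np.empty_like(s)
        out[0], out[1], out[2], out[3] = dO, dtheta, dR_S, dR_Sp
        out[4], out[5], out[6], out[7] = dG, dIP3, dPIP2, dCa
        return out.ravel()

    return rhs


def simulate(
    scenario: "Scenario | str",
    params: ModelParams = ModelParams(),
    geometry: CellGeometry = CellGeometry(),
    stim: StimulusParams = StimulusParams(),
    t_end: float = 90.0,
    output_step: float = 0.1,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "RK45",
    layer_subset: Optional[Sequence[int]] = None,
    keep_states: bool = True,
) -> TraceSet:
    """Integrate the monolayer from stimulation to ``t_end`` seconds.

    Returns a :class:`TraceSet` in μM on the uniform grid ``0, output_step,
    …, t_end``.  The solver is the adaptive Dormand–Prince 5(4) pair
    (``RK45``); the reporting grid is dense output, not the integration
    step.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if isinstance(scenario, (str, ScenarioName)):
        scenario = Scenario.from_name(scenario, geometry)
    rhs = assemble_rhs(scenario, params, geometry, stim,
                       ligand_epsilon=output_step, layer_subset=layer_subset)
    y0 = initial_state(params, geometry, stim, layer_subset=layer_subset)
    t_eval = np.arange(0.0, t_end + output_step / 2, output_step)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method=method, t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed for scenario {scenario.name.value}: {sol.message}"
        )
    nl = y0.size // 8
    states = sol.y.T.reshape(-1, 8, nl)
    if not np.isfinite(states).all():
        raise SimulationError("non-finite state encountered during integration")
    layers = tuple(layer_subset) if layer_subset is not None else tuple(
        range(1, geometry.n_layers + 1)
    )
    return TraceSet(
        time=sol.t,
        ca=states[:, 7, :].copy(),
        units="uM",
        scenario=scenario.name.value,
        layer_indices=layers,
        states=states if keep_states else None,
        metadata={
            "rtol": rtol,
            "atol": atol,
            "method": method,
            "params_sha1": hashlib.sha1(
                json.dumps(dataclasses.asdict(params), sort_keys=True).encode()
            ).hexdigest(),
        },
    )


def to_normalized_fluorescence(traces: TraceSet, baseline: Optional[float] = None) -> TraceSet:
    """Convert a μM trace set to normalized-fluorescence units.

    Each series is divided by the pre-stimulus baseline (default: the basal
    Ca2+ of 0.12 μM), so the resting level maps to 1.0 — the convention used
    for experimental fura-2 recordings.
    """
    if traces.units != "uM":
        raise ValueError("expected a μM trace set")
    b = ModelParams().Ca0 if baseline is None else baseline
    if b == 0:
        raise ValueError("baseline must be nonzero")
    return TraceSet(
        time=traces.time.copy(),
        ca=traces.ca / b,
        units="NF",
        scenario=traces.scenario,
        layer_indices=traces.layer_indices,
        metadata={**traces.metadata, "nf_baseline_uM": b},
    )


def to_micromolar(traces: TraceSet, baseline: Optional[float] = None) -> TraceSet:
    """Inverse of :func:`to_normalized_fluorescence`."""
    if traces.units != "NF":
        raise ValueError("expected an NF trace set")
    b = traces.metadata.get("nf_baseline_uM", ModelParams().Ca0) if baseline is None else baseline
    return TraceSet(
        time=traces.time.copy(),
        ca=traces.ca * b,
        units="uM",
        scenario=traces.scenario,
        layer_indices=traces.layer_indices,
        metadata={k: v for k, v in traces.metadata.items() if k != "nf_baseline_uM"},
    )
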