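"""Model constants and the per-cell dynamical state.

:class:`ModelParams` is the single source of truth for every kinetic constant
of the six subcellular components.  Default values are the published
calibration for the ARPE-19 monolayer; they are frozen here and all
downstream modules receive them by injection.

Unit system: concentrations in μM, time in s, distances in μm.  Membrane
receptor pools (P2Y2 receptors, G proteins, PIP2) are molecule *counts*; the
single bridge between counts and concentration is :func:`count_to_um`, which
converts one molecule in the cytoplasmic volume ``v`` to μM.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "CellState", "count_to_um"]


@dataclass(frozen=True)
class ModelParams:
    # --- I Stretch-sensitive Ca2+ channels (SSCC) ---
    k_SSCC: float = 1.025  # maximal SSCC flux rate, μM/s
    k_f: float = 0.1382  # SSCC opening rate constant, 1/s
    k_b: float = 0.04027  # SSCC closing rate constant, 1/s
    k_theta: float = 0.08105  # stretch-relaxation rate, 1/s

    # --- II P2Y2 receptor / G-protein cascade ---
    R_T: float = 2e4  # total surface P2Y2 receptors, count
    K1: float = 5.0  # dissociation constant, unphosphorylated receptor, μM
    K2: float = 100.0  # dissociation constant, phosphorylated receptor, μM
    k_r: float = 1.75e-4  # receptor recycling rate, 1/s
    k_p: float = 0.03  # receptor phosphorylation rate, 1/s
    k_e: float = 6e-3  # receptor endocytosis rate, 1/s
    xi: float = 0.85  # fraction of mobile receptors
    G_T: float = 1e5  # total G-protein molecules, count
    k_deg: float = 1.25  # IP3 degradation rate, 1/s
    k_a: float = 0.017  # G-protein activation rate, 1/s
    k_d: float = 0.15  # G-protein deactivation rate, 1/s
    PIP2_T: float = 5e4  # total PIP2 molecules, count
    r_r: float = 0.015  # PIP2 replenishment rate, 1/s
    delta: float = 1.238e-3  # intrinsic (ligand-free) G-protein activity
    K3: float = 0.4  # Ca2+ binding to PLC, μM
    alpha: float = 2.781e-5  # effective signal gain, 1/s
    N_a: float = 6.02252e23  # Avogadro's number, 1/mol
    v: float = 1.07e-15  # cytoplasmic volume, m³

    # --- III IP3 receptor type 3 ---
    alpha1: float = 40.0  # maximum of the Ca-dependent opening rate k1, μM/s
    beta1: float = 0.8  # Ca for half-maximal k1, μM
    k_m1: float = 0.88  # open -> shut rate, 1/s
    k2: float = 0.5  # open -> inactivated-1 rate, 1/s
    k3: float = 0.5  # inactivated-1 -> shut rate, 1/s
    beta4: float = 0.01  # IP3 for half-maximal k4, μM
    k5: float = 0.02  # inactivated-2 -> shut rate, 1/s
    k_IP3R3: float = 155.8  # maximum IP3R3 flux rate, μM/s

    # --- IV Ryanodine receptor ---
    Ka: float = 0.37224  # activation dissociation constant, μM
    Kb: float = 0.63601  # activation dissociation constant, μM
    Kc: float = 0.05714  # inactivation dissociation constant, μM
    k_RyR: float = 16.04  # maximum RyR flux rate, μM/s

    # --- V Pumps (SERCA + PMCA) and leak ---
    V_Pump: float = 5.341  # maximal pump rate, μM/s
    K_Pump: float = 0.5030  # Ca for half-maximal pumping, μM
    J_Leak: float = 0.1450  # constant leak into the cytoplasm, μM/s

    # --- VI Gap junctions ---
    D_Ca: float = 512.7  # effective GJ diffusion coefficient of Ca2+, μm²/s
    D_IP3: float = 913.9  # effective GJ diffusion coefficient of IP3, μm²/s
    In_Ca: float = -0.003320  # Ca2+ input flux MS -> NB1, μM/s
    In_IP3: float = 0.5771  # IP3 input flux MS -> NB1, μM/s
    Out_Ca: float = 0.0  # Ca2+ outflow from the last ring, μM/s
    Out_IP3: float = 0.0  # IP3 outflow from the last ring, μM/s

    # --- Initial conditions (time of mechanical stimulation) ---
    R_S0: float = 17000.0  # unphosphorylated surface receptors, count
    R_Sp0: float = 0.0  # phosphorylated surface receptors, count
    G0: float = 14.0  # active G proteins, count
    IP3_0: float = 0.01  # basal IP3, μM
    PIP2_0: float = 49997.0  # PIP2 molecules, count
    Ca0: float = 0.12  # basal cytoplasmic Ca2+, μM

    def replace(self, **changes: float) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "ModelParams":
        return cls.from_dict(json.loads(s))


def count_to_um(p: ModelParams) -> float:
    """Concentration (μM) of one molecule in the cytoplasmic volume.

    ``1e6 / (N_a · v)``: dividing a count by Avogadro's number and the
    volume gives moles per volume; the factor 1e6 rescales to μM.  The
    numerical value of ``v`` is used as litres here, matching the unit
    system of the original calibration (whose simulation environment
    defaults to litre volumes): only this reading produces μM-scale IP3 and
    the ligand-driven transients in the distal rings.  Taking the printed
    volume as m³ instead would scale IP3 production down a thousandfold and
    silence the receptor pathway entirely.  This is the single bridge
    between molecule counts (PIP2, receptors, G proteins) and
    concentrations; audit it here.
    """
    return 1e6 / (p.N_a * p.v)


#: Order of the per-cell state variables in flattened state vectors.
STATE_FIELDS = ("O_SSCC", "theta", "R_S", "R_Sp", "G", "IP3", "PIP2", "Ca")


@dataclass
class CellState:
    """Dynamical state of one cell layer.

    ``O_SSCC`` is the open fraction of stretch-sensitive channels, ``theta``
    the instantaneous stretch, ``R_S``/``R_Sp`` the unphosphorylated and
    phosphorylated surface-receptor counts, ``G`` the active G-protein count,
    ``IP3`` and ``Ca`` cytoplasmic concentrations in μM and ``PIP2`` the
    substrate count for IP3 production.
    """

    O_SSCC: float = 0.0
    theta: float = 0.0
    R_S: float = 17000.0
    R_Sp: float = 0.0
    G: float = 14.0
    IP3: float = 0.01
    PIP2: float = 49997.0
    Ca: float = 0.12

    @classmethod
    def initial(cls, p: ModelParams, theta: float = 0.0) -> "CellState":
        return cls(
            O_SSCC=0.0,
            theta=theta,
            R_S=p.R_S0,
            R_Sp=p.R_Sp0,
            G=p.G0,
            IP3=p.IP3_0,
            PIP2=p.PIP2_0,
            Ca=p.Ca0,
        )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray) -> "CellState":
        return cls(**{f: float(v) for f, v in zip(STATE_FIELDS, a)})
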