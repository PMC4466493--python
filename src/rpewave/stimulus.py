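"""Location-dependent driver fields.

A single mechanical poke of the central cell reaches the neighbour rings
through three location-dependent fields:

* an initial mechanical stretch ``theta(x)`` that decays exponentially with
  distance and is present only in the rings nearest the stimulus,
* an extracellular ligand (ATP/UTP) bolus released by the stimulated cell
  that spreads by free diffusion (thin-film kernel), and
* an IP3-receptor phosphorylation rate ``alpha4(x)`` that *rises*
  exponentially with distance, desensitizing distal cells.

The fields are evaluated per ring at that ring's radial distance; the
``*_scale`` multipliers exist for the local sensitivity analysis, which
scales a whole field uniformly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ScenarioName",
    "StimulusParams",
    "initial_stretch",
    "ligand_concentration",
    "peak_ligand",
    "ip3r_phosphorylation_rate",
]


class ScenarioName(str, enum.Enum):
    """Experimental condition being simulated.

    ``GA_TREATED``: gap junctions blocked with 18α-glycyrrhetinic acid.
    ``CONTROL``: untreated monolayer, gap junctions open.
    ``GA_SURAMIN``: gap junctions blocked plus the P2-receptor antagonist
    suramin (modelled through per-layer ``K1``/``k_p`` overrides).
    """

    GA_TREATED = "GA_treated"
    CONTROL = "control"
    GA_SURAMIN = "GA_suramin"

    @classmethod
    def parse(cls, name: "str | ScenarioName") -> "ScenarioName":
        if isinstance(name, cls):
            return name
        try:
            return cls(name)
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise ValueError(f"unknown scenario {name!r}; expected one of: {valid}")


@dataclass(frozen=True)
class StimulusParams:
    theta_amplitude: float = 0.3426  # stretch at x = 0, dimensionless
    theta_decay: float = 0.105  # spatial decay rate of the stretch, 1/μm
    L0: float = 1310.0  # bolus ligand above the stimulated cell, μM
    D_ATP: float = 236.0  # extracellular ATP diffusion coefficient, μm²/s
    # alpha4 location laws, fitted separately for the uncoupled (GA) and
    # coupled (control) monolayers
    alpha4_prefactor_ga: float = 0.0357  # 1/s
    alpha4_growth_ga: float = 0.0121  # 1/μm
    alpha4_prefactor_control: float = 0.0282  # 1/s
    alpha4_growth_control: float = 0.0138  # 1/μm
    stretch_max_layer: int = 4  # stretch is absent beyond this ring
    # uniform field multipliers used by the sensitivity analysis
    theta_scale: float = 1.0
    ligand_scale: float = 1.0
    alpha4_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("theta_amplitude", "theta_decay", "L0", "D_ATP",
                     "alpha4_prefactor_ga", "alpha4_growth_ga",
                     "alpha4_prefactor_control", "alpha4_growth_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.stretch_max_layer < 0:
            raise ValueError("stretch_max_layer must be >= 0")

    def scaled(self, **scales: float) -> "StimulusParams":
        return replace(self, **scales)


def initial_stretch(x, p: StimulusParams = StimulusParams(), n: "int | None" = None):
    """Stretch imposed on a ring at distance ``x`` (μm) at stimulus time.

    The amplitude envelope of a damped membrane wave:
    ``theta = theta_amplitude · exp(-theta_decay · x)``.  If the ring index
    ``n`` is given, rings beyond ``stretch_max_layer`` get exactly zero (the
    stretch component is absent there).
    """
    theta = p.theta_scale * p.theta_amplitude * np.exp(-p.theta_decay * np.asarray(x, dtype=float))
    if n is not None:
        theta = np.where(np.asarray(n) <= p.stretch_max_layer, theta, 0.0)
    if theta.ndim == 0:
        return float(theta)
    return theta


def ligand_concentration(x, t, p: StimulusParams = StimulusParams()):
    """Extracellular ligand concentration L(x, t) in μM.

    Thin-film solution of Fick's law for an instantaneous bolus ``L0``
    deposited at the origin at t = 0:
    ``L = L0 / sqrt(4 π D t) · exp(-x² / (4 D t))``.
    Singular at t = 0; callers must pass t > 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("ligand_concentration requires t > 0 (kernel is singular at t = 0)")
    x = np.asarray(x, dtype=float)
    L = p.ligand_scale * p.L0 / np.sqrt(4.0 * math.pi * p.D_ATP * t) * np.exp(
        -(x**2) / (4.0 * p.D_ATP * t)
    )
    if L.ndim == 0:
        return float(L)
    return L


def peak_ligand(x, p: StimulusParams = StimulusParams()):
    """Maximum over time of L(x, t) at fixed distance ``x`` > 0 (μM).

    The kernel peaks at ``t* = x² / (2 D)``, where it equals
    ``L0 · e^{-1/2} / (x · sqrt(2 π))`` — independent of D.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("peak_ligand requires x > 0 (unbounded at the origin)")
    L = p.ligand_scale * p.L0 * math.exp(-0.5) / (x * math.sqrt(2.0 * math.pi))
    if L.ndim == 0:
        return float(L)
    return L


def ip3r_phosphorylation_rate(x, scenario, p: StimulusParams = StimulusParams()):
    """IP3R3 phosphorylation rate alpha4(x) in 1/s for the given scenario.

    A shallowly rising exponential in distance.  The GA-treated law also
    covers the GA+suramin condition, whose refit touches only the receptor
    parameters K1 and k_p, not the alpha4 field.
    """
    scenario = ScenarioName.parse(scenario)
    x = np.asarray(x, dtype=float)
    if scenario is ScenarioName.CONTROL:
        c, b = p.alpha4_prefactor_control, p.alpha4_growth_control
    else:
        c, b = p.alpha4_prefactor_ga, p.alpha4_growth_ga
    a4 = p.alpha4_scale * c * np.exp(b * x)
    if a4.ndim == 0:
        return float(a4)
    return a4
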