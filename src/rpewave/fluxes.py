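"""The six subcellular flux components as pure functions.

Each function maps state variables and :class:`~rpewave.params.ModelParams`
to fluxes (μM/s) or state derivatives.  All functions accept scalars or
numpy arrays (one entry per cell layer) and are free of side effects — the
simulator assembles them into the coupled right-hand side.

Components
----------
I    stretch-sensitive Ca2+ channels (SSCC): first-order gating driven by a
     relaxing stretch variable.
II   P2Y2 receptor / G-protein / PLC cascade producing IP3 from PIP2.
III  IP3 receptor type 3: quasi-steady four-subunit gating with
     Ca-dependent activation and phosphorylation-dependent inactivation.
IV   ryanodine receptor: Keizer–Levine quasi-steady open probability
     (calcium-induced calcium release).
V    combined SERCA/PMCA Hill-type clearance plus a constant leak.
VI   gap-junctional exchange of Ca2+ and IP3 between adjacent layers.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams, count_to_um

__all__ = [
    "sscc_rates",
    "sscc_flux",
    "p2y2_receptor_rates",
    "receptor_occupancy",
    "gprotein_rate",
    "plc_hydrolysis_rate",
    "ip3_production_rates",
    "ip3r3_open_probability",
    "ip3r3_flux",
    "ryr_open_probability",
    "ryr_flux",
    "pump_flux",
    "gj_fluxes",
]


# --- I SSCC -----------------------------------------------------------------

def sscc_rates(O_SSCC, theta, p: ModelParams):
    """(dO/dt, dtheta/dt) of the stretch-gated channel.

    Opening is driven by the stretch, closing is spontaneous:
    ``dO/dt = theta k_f - (theta k_f + k_b) O``; the stretch itself relaxes
    exponentially, ``dtheta/dt = -k_theta theta``.
    """
    dO = theta * p.k_f - (theta * p.k_f + p.k_b) * O_SSCC
    dtheta = -p.k_theta * theta
    return dO, dtheta


def sscc_flux(O_SSCC, p: ModelParams):
    """Ca2+ influx through open stretch-sensitive channels, μM/s."""
    return p.k_SSCC * O_SSCC


# --- II P2Y2 / G protein / PLC ----------------------------------------------

def p2y2_receptor_rates(R_S, R_Sp, L, p: ModelParams, K1=None, k_p=None):
    """(dR_S/dt, dR_Sp/dt) for the surface receptor pools.

    Ligand-bound receptors are phosphorylated irreversibly at rate ``k_p``
    (desensitization), phosphorylated receptors are internalized at ``k_e``
    and recycled back unphosphorylated at ``k_r``.  ``K1``/``k_p`` may be
    supplied per layer (the suramin condition overrides them).
    """
    K1 = p.K1 if K1 is None else K1
    k_p = p.k_p if k_p is None else k_p
    dR_S = p.k_r * p.R_T - (p.k_r + k_p * L / (K1 + L)) * R_S - p.k_r * R_Sp
    dR_Sp = L * (k_p * R_S / (K1 + L) - p.k_e * R_Sp / (p.K2 + L))
    return dR_S, dR_Sp


def receptor_occupancy(R_S, L, p: ModelParams, K1=None):
    """Fraction p_r of mobile receptors that are ligand-bound."""
    K1 = p.K1 if K1 is None else K1
    return L * R_S / (p.xi * p.R_T * (K1 + L))


def gprotein_rate(G, R_S, L, p: ModelParams, K1=None):
    """dG/dt for active G proteins.

    Activation is proportional to the intrinsic activity ``delta`` plus the
    receptor occupancy; deactivation is first order at ``k_d``.
    """
    p_r = receptor_occupancy(R_S, L, p, K1=K1)
    return p.k_a * (p.delta + p_r) * (p.G_T - G) - p.k_d * G


def plc_hydrolysis_rate(Ca, G, p: ModelParams):
    """PIP2 hydrolysis rate coefficient r_h (1/s).

    PLC activity scales with active G protein and saturably with Ca2+:
    ``r_h = alpha · Ca/(K3 + Ca) · G``.
    """
    return p.alpha * (Ca / (p.K3 + Ca)) * G


def ip3_production_rates(IP3, PIP2, Ca, G, p: ModelParams):
    """(dIP3/dt without the gap-junction term, dPIP2/dt).

    PIP2 is a molecule count; its hydrolysis products appear in the IP3
    concentration balance through the single count→μM bridge, and the PIP2
    replenishment term converts cytoplasmic IP3 back to counts with the same
    bridge.
    """
    c2u = count_to_um(p)
    r_h = plc_hydrolysis_rate(Ca, G, p)
    dIP3 = r_h * PIP2 * c2u - p.k_deg * IP3
    dPIP2 = -(r_h + p.r_r) * PIP2 - p.r_r * IP3 / c2u + p.r_r * p.PIP2_T
    return dIP3, dPIP2


# --- III IP3 receptor type 3 -------------------------------------------------

def ip3r3_open_probability(Ca, IP3, alpha4, p: ModelParams):
    """Quasi-steady open fraction O of one IP3R3 subunit.

    ``k1`` is the Ca-dependent shut→open rate (Hill coefficient 3), ``k4``
    the phosphorylation-dependent inactivation rate whose maximum ``alpha4``
    varies with location.  ``phi`` collects the inactivation pathway and sets
    the receptor's sensitivity to IP3.
    """
    k1 = p.alpha1 * Ca**3 / (p.beta1**3 + Ca**3)
    k4 = alpha4 * IP3 / (p.beta4 + IP3)
    phi = 1.0 / (1.0 + (p.k2 / (p.k3 + k4)) * (1.0 + k4 / p.k5))
    return phi * IP3 / (((p.k_m1 + p.k2) / k1) * phi + IP3)


def ip3r3_flux(Ca, IP3, alpha4, p: ModelParams):
    """ER Ca2+ release through IP3R3, μM/s.

    All four subunits must be open for the channel to conduct, hence the
    fourth power of the subunit open fraction.
    """
    O = ip3r3_open_probability(Ca, IP3, alpha4, p)
    return p.k_IP3R3 * O**4


# --- IV Ryanodine receptor ---------------------------------------------------

def ryr_open_probability(Ca, p: ModelParams):
    """Keizer–Levine quasi-steady RyR open probability, requires Ca > 0."""
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca <= 0):
        raise ValueError("ryr_open_probability requires Ca > 0")
    u = (p.Ka / Ca) ** 4
    q = (Ca / p.Kb) ** 3
    w_inf = (1.0 + u + q) / (1.0 + 1.0 / p.Kc + u + q)
    P = w_inf * (1.0 + q) / (1.0 + u + q)
    if P.ndim == 0:
        return float(P)
    return P


def ryr_flux(Ca, p: ModelParams):
    """ER Ca2+ release through ryanodine receptors, μM/s."""
    return p.k_RyR * ryr_open_probability(Ca, p)


# --- V Pumps and leak --------------------------------------------------------

def pump_flux(Ca, p: ModelParams):
    """Combined SERCA + PMCA clearance, Hill coefficient 2, μM/s."""
    Ca2 = np.asarray(Ca, dtype=float) ** 2
    J = p.V_Pump * Ca2 / (p.K_Pump**2 + Ca2)
    if J.ndim == 0:
        return float(J)
    return J


# --- VI Gap junctions --------------------------------------------------------

def gj_fluxes(ca: np.ndarray, ip3: np.ndarray, areas: np.ndarray, p: ModelParams):
    """Per-layer gap-junctional fluxes (J_Ca, J_IP3), each μM/s.

    ``areas[n-1]`` is the membrane area between ring n and ring n+1.  Each
    interior ring receives from the previous ring and delivers to the next
    down the concentration gradient, with conductance D/A per interface so
    the flux per unit cytoplasm falls with distance as the shared wall
    grows.  Ring 1's inbound term is the constant MS-cell input (In_Ca,
    In_IP3); the outermost ring's outbound term is the boundary outflow
    (Out_Ca, Out_IP3, zero by default: no transport beyond the simulated
    patch).
    """
    ca = np.asarray(ca, dtype=float)
    ip3 = np.asarray(ip3, dtype=float)
    n = ca.shape[0]
    j_ca = np.empty(n)
    j_ip3 = np.empty(n)
    # exchange across interface i (between ring i+1 and ring i+2), μM/s
    if n > 1:
        ex_ca = (p.D_Ca / areas[: n - 1]) * (ca[:-1] - ca[1:])
        ex_ip3 = (p.D_IP3 / areas[: n - 1]) * (ip3[:-1] - ip3[1:])
    else:
        ex_ca = np.empty(0)
        ex_ip3 = np.empty(0)
    j_ca[0] = p.In_Ca
    j_ip3[0] = p.In_IP3
    j_ca[1:] = ex_ca
    j_ip3[1:] = ex_ip3
    j_ca[: n - 1] -= ex_ca
    j_ip3[: n - 1] -= ex_ip3
    j_ca[n - 1] -= p.Out_Ca
    j_ip3[n - 1] -= p.Out_IP3
    return j_ca, j_ip3
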