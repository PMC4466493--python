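# Methods

## Model structure and assumptions

The monolayer is radially symmetric by construction: cells are idealized as
regular hexagonal prisms (side s = 7 μm, so the corner-to-corner width is
14 μm; height h = 12 μm), and the neighbours of the stimulated cell are
grouped into ten concentric rings, each a single well-mixed compartment.
Ring *n* sits at distance x = 2na from the stimulated cell's centre
(a = s/(2 tan π/6) is the hexagon apothem), and shares a wall of area
A(n→n+1) = (3 + 2(n−1))·6·s·h with the next ring. The cytoplasm occupies
70% of the cell volume, giving v ≈ 1.07·10⁻¹⁵ m³.

Each ring carries eight states: the SSCC open fraction, the stretch θ, the
unphosphorylated and phosphorylated surface-receptor counts, the active
G-protein count, [IP₃], the PIP₂ count and [Ca²⁺]ᵢ. The stimulated cell is
*not* a dynamical unit: it appears only as the ligand point source at x = 0
and as the constant input fluxes (In_Ca, In_IP3) into ring 1. There is no
explicit ER pool (release fluxes are source terms), no P₂X receptors,
voltage-gated channels, Na⁺/Ca²⁺ exchange or mitochondrial buffering, and
no spatial resolution within a ring.

Because the underlying recordings are normalized fluorescence with no
absolute calibration, the model's μM outputs are meaningful only relatively.

## Location-dependent drivers

* Stretch: θ(x) = 0.3426·e^(−0.105x), applied at stimulus time to rings
  1–4 and zero beyond (the mechanical wave does not reach further); it then
  relaxes exponentially inside the state.
* Ligand: the thin-film diffusion kernel L(x,t) = L₀/√(4πD_ATP t)·
  e^(−x²/(4 D_ATP t)) with L₀ = 1310 μM and D_ATP = 236 μm²/s, evaluated
  per ring as a time-varying forcing (it is not a state variable). Its peak
  over time at distance x is L₀e^(−1/2)/(x√(2π)), reached at t* = x²/(2D).
* IP₃R₃ phosphorylation rate: α₄(x) = 0.0357·e^(0.0121x) s⁻¹ for the
  uncoupled (gap-junction-blocked) monolayer and 0.0282·e^(0.0138x) s⁻¹
  for the control monolayer. The suramin scenario reuses the uncoupled law:
  the drug's effect is carried entirely by the per-ring K₁/k_p overrides.

## Units and the count→concentration bridge

Concentrations are in μM, time in s, distances in μm; receptor, G-protein
and PIP₂ pools are molecule counts. The single bridge between the two is
`count_to_um = 1e6/(N_a·v)`, where the numeric value of v is used as
litres. This follows the unit system of the original calibration (whose
simulation environment defaults to litre volumes): with the bridge read
this way IP₃ reaches the μM scale needed to gate the IP₃R₃ and the distal
rings respond, whereas reading v in m³ scales IP₃ production down a
thousandfold and silences the receptor pathway everywhere beyond the
stretched rings. A consequence, documented rather than hidden, is that the
basal IP₃ balance does not close exactly at the tabulated initial state:
from [IP₃]₀ = 0.01 μM the unstimulated model drifts toward ≈0.006 μM.
Simulations start from the tabulated initial conditions regardless.

The printed In_Ca is negative (−0.00332 μM/s) and is applied at face value
as a constant flux into ring 1 for the whole window, as is In_IP3
(0.5771 μM/s); the boundary outflow from ring 10 is zero (no transport
beyond the simulated patch).

Gap-junction dialect: the inter-ring flux is D/A·Δc (diffusivity divided by
wall area). This is the only dimensionally consistent reading
((μm²/s)/μm²·μM = μM/s), it makes fluxes fall with distance as the shared
wall grows, and it reproduces the tabulated flux magnitude at the first
interface (512.7/1512·0.1445 ≈ 0.049 μM/s).

## Numerical integration

The coupled system (8 × n_layers states) is integrated with the adaptive
Dormand–Prince 5(4) pair (`scipy.integrate.solve_ivp`, method `RK45`) at
rtol = 1e-6, atol = 1e-9, with dense output interpolated to a uniform
0.1-s reporting grid over 0–90 s. The ligand kernel is singular at t = 0,
so the forcing is evaluated at max(t, 0.1 s); at ring 1's distance the
kernel's exponent suppresses earlier times anyway, so the choice is
immaterial to the waveform. Halving the tolerances changes terminal states
by well under 0.1% (checked in the test suite). When gap junctions are off
the rings decouple exactly, and a single ring can be integrated alone; the
calibration code exploits this.

## Wave features

Four features summarize a transient: peak amplitude above the pre-stimulus
baseline; time of the (first) peak from stimulation; width at half maximum,
measured between the first up-crossing and last down-crossing of
baseline + amplitude/2 with linear interpolation between samples; and the
value at the 90-s endpoint. The half-maximum level is referenced to the
baseline (not absolute half of peak) because normalized-fluorescence traces
rest at 1, not 0. A trace is flagged *typical* when it has exactly one
contiguous excursion above the half-maximum level; the flag has no formal
definition in the source material, so this multi-excursion test is the
package's documented choice. Flat traces yield NaN features plus the flag
rather than an error.

## Sensitivity analysis

One parameter at a time is scaled by −25/−10/+10/+25%, the monolayer is
re-simulated, and percent feature changes are tabulated at rings 1, 5 and
10; changes beyond 50% and atypical waveforms are flagged. The field
entries θ, L and α₄ are scaled uniformly over space (equivalent to scaling
their prefactors). A parameter is reported insensitive at a threshold when
*all* its feature changes at all report rings and perturbation sizes stay
below it — the strictest aggregation.

One perturbation needs care: ξ is the mobile fraction of surface
receptors, and the receptor occupancy is normalized by the mobile pool
ξ·R_T, which is also the initial surface pool (17000 = 0.85·2·10⁴).
Perturbing ξ alone would rescale the occupancy directly and, near the
marginal outermost ring, produce spurious ~60% feature swings; the
internally consistent perturbation regenerates R_S(0) = ξ·R_T, leaving the
initial occupancy invariant. With that tie the ξ screen lands below 0.3%,
in line with the other non-triaged receptor parameters.

## Calibration

Fitting is bounded trust-region least squares (`scipy.optimize
.least_squares`) on unweighted residuals between the simulated Ca²⁺ series
and the target series on the data's own time grid (a constant error
model), with an iteration cap (default 100) mapped to a function-evaluation
budget. The staged protocol fits, in order: the core release/clearance
block on ring 5 of the uncoupled recordings (the largest stretch-free
response); the SSCC block on ring 1 (the largest stretch); the gap-junction
block on ring 1 of the control recordings; and per-ring K₁/k_p on the
suramin recordings, the latter with wide pharmacological bounds
(K₁ ∈ [0.5, 50] μM, k_p ∈ [0.003, 1] s⁻¹) since antagonist effects can
raise both far above their drug-free values. Default boxes for the other
stages span 0.2–5× the starting value (symmetric about zero for the
sign-free In_Ca). Normalized-fluorescence targets are converted to μM with
the 0.12 μM basal reference — the exact inverse of the fixture
normalization — before fitting; an as-is comparison of NF numbers against
μM simulations differs from this by one fixed scale factor.

`fit_location_law` recovers the exponential location laws (prefactor,
rate, R² on the original scale) from per-ring values, via a log-linear fit
refined by a nonlinear pass, falling back to a direct nonlinear fit when
values are non-positive.

## Synthetic data

Two generators stand in for the unpublished recordings. The *model-truth*
generator runs the simulator at known parameters, converts to normalized
fluorescence (baseline 0.12 μM → 1), resamples to the experimental 1-s
grid, and adds independent Gaussian noise (default SD 0.02 NF — small
relative to the ring-1 response of ~2 NF, so recovery tests stay
informative; the recordings themselves are averages with no published
noise model). The *phenomenological* generator builds log-normal-shaped
pulses whose amplitude decays and onset grows linearly with ring distance
(defaults: ~1 NF amplitude and ~4 s onset at ring 1, falling to ~0.1 NF
and ~20 s at ring 10) — used to exercise features and fitting independently
of the ODE model. Neither generator emulates pipette artefacts,
photobleaching or fura-2 ratio nonlinearity, so passing recovery tests
demonstrate identifiability under idealized noise, not robustness to those
systematics.

Every fixture is reproducible from its spec and seed; one tiny committed
CSV (3 rings, 10 s, phenomenological) guards file-format stability.

## Problem sizes and runtimes

A full 10-ring, 90-s simulation takes ~0.1 s on one CPU; the complete
sensitivity screens run in a few seconds. The recovery tests in the
acceptance suite use 10% perturbed-truth starts, noise-free fixtures for
the 1%-recovery checks, one noisy fixture (SD 0.02, seed fixed) for the
noise-limited check (15% band, established from the spread over several
seeds), and rings 1 and 10 for the per-ring suramin stage.

## Known limitations

* The basal state is not an exact fixed point (IP₃ drift, above).
* The ±25% receptor-parameter screen at the outermost ring sits near a
  regenerative threshold; conclusions drawn there are sensitive to small
  modelling choices.
* Absolute concentrations are uncalibrated; only relative comparisons
  between scenarios are meaningful.
* The suramin per-ring K₁/k_p defaults interpolate linearly in distance
  between the two published endpoint values; intermediate rings are a
  modelling convention, overridable per ring in the scenario.
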