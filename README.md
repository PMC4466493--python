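# rpewave

Mechanistic simulation of mechanically induced intercellular Ca²⁺ waves in a
retinal-pigment-epithelium-like (ARPE-19) cell monolayer, with the waveform
feature extraction, local sensitivity analysis, drug-scenario machinery and
staged least-squares calibration built around the model.

## The problem

When a single cell in a confluent RPE-like epithelium is mechanically
stimulated, a Ca²⁺ transient sweeps outward across the monolayer, its
amplitude falling and its latency growing with distance. `rpewave` models
this wave on an idealized hexagonal tiling: the stimulated (MS) cell sits at
the origin and its neighbours are grouped into ten concentric rings
(NB₁–NB₁₀), each treated as one well-mixed compartment carrying eight state
variables. The package is aimed at epithelial-physiology modellers who want
to simulate the wave under control and drug conditions (gap-junction block,
P₂-receptor block), interrogate parameter sensitivity, or calibrate the
model against per-ring fluorescence recordings.

## The model

Per ring *n*, the cytoplasmic Ca²⁺ balance is

    d[Ca²⁺]ᵢ/dt = J_SSCC + J_IP3R3 + J_RyR − J_Pump + J_Leak + J_GJ,Ca

with six components:

* **I — SSCC.** Stretch-sensitive Ca²⁺ channels, gated by a stretch
  variable θ that starts from θ(x) = 0.3426·e^(−0.105x) (rings 1–4 only)
  and relaxes as dθ/dt = −k_θ θ; influx J_SSCC = k_SSCC·O with first-order
  gating dO/dt = θk_f − (θk_f + k_b)O.
* **II — P₂Y₂ / G protein / PLC.** The MS cell releases a ligand bolus
  (ATP/UTP) that spreads by free diffusion, L(x,t) = L₀/√(4πDt)·e^(−x²/4Dt).
  Ligand binding drives receptor phosphorylation/recycling, G-protein
  activation, and Ca²⁺-dependent PIP₂ hydrolysis producing IP₃.
* **III — IP₃R₃.** Quasi-steady four-subunit gating, J = k_IP3R3·O⁴, with
  Ca²⁺-dependent activation and a phosphorylation-dependent inactivation
  whose maximal rate α₄(x) rises exponentially with distance — the field
  that desensitizes distal rings.
* **IV — RyR.** Keizer–Levine quasi-steady open probability
  (calcium-induced calcium release).
* **V — Pumps and leak.** Combined SERCA/PMCA Hill-type clearance
  J_Pump = V_Pump·Ca²/(K²+Ca²) plus a constant leak.
* **VI — Gap junctions.** Inter-ring exchange of Ca²⁺ and IP₃ down the
  concentration gradient with conductance D/A per shared wall (A grows
  with ring index, attenuating the coupling). Active in the control
  scenario; absent when gap junctions are blocked.

Three scenarios are built in: `GA_treated` (gap junctions blocked),
`control` (coupled), and `GA_suramin` (gap junctions blocked plus a P₂
antagonist, modelled through per-ring K₁/k_p overrides).

## Worked example

```python
import rpewave as rw
from rpewave.features import extract_feature_table

traces = rw.simulate("control")                       # 90 s, 10 rings, default constants
table = extract_feature_table(traces, baseline=0.12)  # μM features per ring
print(table.round(3).to_string(index=False))
```

prints

```
 layer  peak_amplitude  time_to_peak  width_half_max  end_concentration  is_typical_waveform
     1           0.303          10.0          83.312              0.266                 True
     2           0.241           9.0          50.690              0.200                 True
     3           0.194           9.7          39.885              0.167                 True
     4           0.159          11.1          38.139              0.146                 True
     5           0.133          12.9          39.063              0.134                 True
     6           0.112          15.2          41.212              0.130                 True
     7           0.095          18.0          43.249              0.128                 True
     8           0.080          21.5          44.201              0.128                 True
     9           0.068          26.0          43.528              0.128                 True
    10           0.059          30.3          41.435              0.128                 True
```

Each row is one neighbour ring: the Ca²⁺ peak above the 0.12 μM baseline
(decaying from 0.30 μM at the first ring to 0.06 μM at the tenth), the time
from stimulation to the peak (growing from ~10 s to ~30 s), the transient's
width at half maximum, and the concentration remaining at 90 s. The pattern
— attenuating amplitude, growing latency, single-peaked transients — is the
hallmark of the mechanically induced wave.

The same operations are available from a shell:

```bash
rpewave simulate --scenario control --out traces.csv
rpewave features --in traces.csv --baseline 0.12 --out features.csv
rpewave sensitivity --scenario control --out sens.csv
rpewave fixtures --generator model_truth --seed 1 --out fixture.csv
```

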