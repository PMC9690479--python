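# bioheatsim

A multi-segment human bioheat simulator for **asymmetric high-temperature
environments** — the exposure conditions faced by firefighters and workers
in steel plants, power grids and construction, where intense radiant heat
arrives from one side and local skin temperature, not just the whole-body
mean, decides the risk of local heat stress and burns.

## The model

The body is 15 cylindrical segments (head, chest, abdomen and paired upper
arms, forearms, hands, thighs, calves, feet).  Each segment carries a core
node, an arterial and a venous blood node, and — to resolve angular
asymmetry — **four skin sectors** (anterior, exterior, posterior,
inferior): 105 temperature nodes in total.

**Passive system.**  Per segment, energy balances couple the nodes:

- core:  `C_cr dT_cr/dt = (M_cr − W_cr) − Σᵢ Q_cr−sk,i − Σᵢ Q_perf,cr−sk,i
  − Q_perf,a−cr − Q_cr−a − Q_cr−v − RES` (respiration on the chest only,
  `RES = 0.0014·M_cr(34 − T_air) + 0.0173·M_cr(5.87 − P_air)`);
- artery/vein: convective exchange with the core (`h_a`, `h_v`) plus blood
  advection along an anatomical tree rooted at the heart, closed through
  the heart so that advection conserves enthalpy exactly;
- skin sector *i*:  angular conduction
  `(K_sk L_n th_sk / r²) ∂²T_sk/∂θ²` around the four-sector ring, plus
  metabolism, core coupling, and the boundary terms
  `CON = A h_c (T_sk − T_air)`, `EVA = w A h_e (P_sat(T_sk) − P_air)` and
  `RAD = A h_r (T_sk − T_mrt)(1 − ΣF) + A σ ε F_vf [(T_sk+273.15)⁴ −
  (T_r+273.15)⁴]` per radiant panel, with purely geometric view factors
  `F_vf` computed by exact contour integration.

Sector skin blood flow follows the hot sectors:
`ṁ_sk,i = (ṁ_perf/4)(1 + δᵢ/Σmax(0,δᵢ))` with `δᵢ` the sector's deviation
from the segment mean — conserving the segment total.

**Active system.**  Error signals against per-segment skin set points and
the 36.9 °C head-core reference drive Stolwijk-form vasomotion (clamped to
the tabulated flow limits), sweating distributed by per-segment
coefficients, and shivering.  Three high-temperature extensions:

- metabolic rise: `M = M₀(1 + 0.13(T_cr − 39))` once ambient air reaches
  39 °C;
- heart-rate strain: `ΔHR = 4.75·D` beats/min, with `D` the cumulative
  sweat loss as % of a 74.30 kg body;
- dehydration-modified sweating:
  `Sweat = (0.2898 − 0.068·D)(T_head − 37 − 0.06·D) + 0.03364·Wrms − Clds`
  kg/h — each 1 % of dehydration raises the sweating threshold by 0.06 °C
  and lowers its sensitivity by 0.068 kg/(h·°C).

The system integrates with a fixed-step classical Runge–Kutta scheme
(Δt = 1 s); runs are deterministic.

## Worked example

Two staged exposure protocols ship as fixtures.  The first alternates a
resting, nearly unclothed body between 29 °C and 45 °C chambers every
30 min:

```bash
$ bioheatsim run uniform-fourstage --out out/
completed uniform-fourstage: 7200 s, head core 37.39 °C, mean skin 37.00 °C, D 0.21 %
wrote out/trajectory.csv
wrote out/manifest.json
```

Starting from the pre-equilibrated neutral state (head core 36.86 °C, mean
skin 33.88 °C), the first 45 °C stage drives the mean skin temperature to
37.0 °C and the head core to 37.25 °C; by the end of the second hot stage
the core reaches 37.39 °C with 0.21 % of body mass lost as sweat (a ~1
beat/min heart-rate rise).  Returning to 29 °C pulls the skin back toward
35 °C — the hot/neutral contrast the protocol was designed to expose.

The second fixture places the body 0.5 m from a heated wall on its left
side (one unheated hour at 23 °C, then the wall steps through 32.6…70.1 °C
while air temperature is lowered to hold operative temperature):

```
t= 60 min: head core 36.49, mean skin 32.28, L-arm ext 32.56, R-arm ext 32.56
t=120 min: head core 36.59, mean skin 32.71, L-arm ext 34.82, R-arm ext 31.99
t=210 min: head core 36.97, mean skin 34.22, L-arm ext 37.99, R-arm ext 31.71
```

The wall-facing (left) arm's exterior sector ends 6.3 °C warmer than the
contralateral one while the whole-body mean moves only ~2 °C — the local
signal a single-node-per-segment model cannot produce.

Scenario files are plain YAML (`bioheatsim fixtures export fanger-warmwall`
prints one); `bioheatsim run scenario.yaml --out dir` writes a tidy
long-format CSV and a JSON manifest with the resolved configuration.

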