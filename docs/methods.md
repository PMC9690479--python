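# Methods

This note documents the model equations as implemented, the parameter
choices that were genuinely open, the numerical scheme, and what the
packaged scenarios do and do not demonstrate.

## Node structure and state

Fifteen cylindrical segments, each with a core, an arterial and a venous
blood node and four angular skin sectors (anterior, exterior, posterior,
inferior) — 105 temperature nodes.  The integrated state adds one
auxiliary: cumulative sweat mass (kg), from which the dehydration
percentage `D = 100·m_sweat/74.30` and the heart-rate increment
`ΔHR = 4.75·D` derive.  All temperatures are °C; radiation converts to K
internally.

## Passive system

### Sign convention and conservation

Every internal flow is defined as heat leaving the core — conduction
`K_cr−sk/4·(T_cr − T_sk,i)` per sector, skin-perfusion exchange
`ṁ_sk,i c_bl (T_cr − T_sk,i)`, vessel convection `h_a(T_cr − T_bl,a)` and
`h_v(T_cr − T_bl,v)` — subtracted in the core balance and added in the
receiving node.  Advection runs upwind along the vessel tree (chest =
heart = root; chains chest→head, chest→upper arm→forearm→hand,
chest→abdomen→thigh→calf→foot per side), with the root artery fed from
the root vein (the heart exchanges no heat).

**Perfusion routing.**  The stream consumed by a segment
(`ṁ_cr + ṁ_sk`) equilibrates in the core (one artery→core term at the
full local flow), the skin loop exchanges pairwise with the core, and the
full stream returns to the local vein at core temperature.  This is the
unique routing that keeps both perfusion terms in the core balance *and*
makes the network exactly conservative: with boundary exchange and
metabolism disabled, `Σ C·dT/dt = 0` holds identically for any state, so
any Runge–Kutta scheme preserves total enthalpy to round-off (the
invariant is linear in the state).  Routing the skin return to the vein at
skin temperature instead — while also charging the core for the skin
exchange — double-counts the skin-transit enthalpy by `ṁ_sk c (T_cr −
T_sk)` (~45 W on physiological states) and was therefore rejected.

### Angular conduction

The continuum term `(K_sk L_n th_sk / r²) ∂²T/∂θ²` is discretized as a
periodic central second difference over the four sectors with Δθ = π/2.
The stencil sums to zero around the ring (conservation) and vanishes for
equal sectors, so angularly uniform environments preserve exact sector
symmetry — spread stays at floating-point zero through a full staged
protocol.

### Boundary exchange

Per sector (area A/4), with clothing scaling applied per segment:

- convection `A h_c (T_sk − T_air)`;
- evaporation `w · A h_e (P_sat(T_sk) − P_air)`, floored at 0.  The
  wettedness is `w = 0.06 + 0.94·E_dem/E_max` clipped to [0.06, 1], where
  `E_dem` is the latent power of the sector's allocated sweat (λ = 2426
  kJ/kg) and `E_max` the fully-wet capacity.  The insensible floor
  w = 0.06 yields the physiological ~20 W whole-body diffusion loss in
  temperate air; without it a conservative 83 W resting budget forces the
  mean skin temperature above 35 °C.  Saturation pressure uses an
  Antoine-form fit (kPa; ≈5.61 kPa at 35 °C).
- radiation `A h_r (T_sk − T_mrt)(1 − ΣF) + Σ_panels A σ ε F [(T_sk +
  273.15)⁴ − (T_r + 273.15)⁴]`.  By view-factor additivity the enclosure
  remainder subtends `1 − ΣF` of the sector's view; treating the panel
  term as purely additional instead double-counts its solid angle and
  (for a wall slightly cooler than the skin) cools the facing side — the
  opposite of the observed asymmetry.  ε is a single configurable factor
  (skin emissivity × panel emissivity).

**View factors** are geometric only.  Each sector is modelled as a flat
vertical strip (height `L_n`, width `r·π/2`, offset `r` along its outward
normal at a standard standing height); panels are vertical rectangles.
The per-element view factor uses the exact contour-integral (Stokes) form
with horizon clipping — additive over panel subdivisions by construction
and verified against direct quadrature of the kernel to 1e-6 — averaged
over the strip by midpoint quadrature (8×12 points; the classical
opposed-unit-squares benchmark 0.19982 reproduces to 2e-4).  Curvature of
the real sector and body self-shadowing are not modelled; for the
warm-wall geometry the contralateral arm's medial sector therefore sees
the wall unshaded, a known simplification that does not affect the
exterior-sector asymmetry.

**Clothing** is a serial resistance: dry flux × `1/(1 + (h_c+h_r)·I_cl)`,
evaporative flux × `1/(1 + h_e·R_e,cl)`; bare segments unchanged.

**Respiration** `RES = 0.0014·M_cr(34 − T_air) + 0.0173·M_cr(5.87 −
P_air)` applies to the chest core with the chest's (multiplier-scaled)
core metabolic rate; it can turn negative in hot humid air, a physical
heat gain.

### Circulation parameters not tabulated

- `h_a`, `h_v` (lumped core–vessel conductances): κ·C_bl with κ = 0.01
  W/K per J/K — a calibration constant chosen with the neutral-state
  targets below; per-segment overrides accepted.
- Core perfusion: tabulated data give skin flows only.  Core flows are
  distributed proportionally to basal core metabolic rate from a 267 L/h
  whole-body total (≈ resting cardiac output 290 L/h minus 23 L/h basal
  skin flow), giving ~62 L/h to the head and ~156 L/h to the abdominal
  viscera — physiologically sensible magnitudes.  Blood: c_bl = 4000
  J/(kg·K), ρ = 1059 kg/m³.

### Geometry defaults

Segment length `L_n` from canonical anthropometry (0.2–0.4 m), skin
radius `r = A/(2π L_n)`, skin thickness 1 mm, skin conductivity 0.47
W/(m·K), emissivity 0.95.  All overridable per segment.

## Active system

Signals: per-segment error `T_sk,mean − T_sk0` split into warm/cold
parts, aggregated with the sensitivity weights α_sk into `Wrms`/`Clds`;
head-core error against 36.9 °C.  The per-side α columns sum to ≈1 over
the fifteen segments (pairs counted per side).

- **Vasomotion** (Stolwijk form):
  `ṁ = (ṁ_basal + α_sk·DL)/(1 + α_sk·ST)` clamped to the tabulated
  [min, max], with `DL = g_dil_cr·(T_head − 36.9)₊ + g_dil_sk·Wrms`
  (cm³/h) and `ST = g_con_cr·(36.9 − T_head)₊ + g_con_sk·Clds`.
  Defaults g_dil_cr = 117 000, g_dil_sk = 7 500 cm³/(h·K) (Stolwijk's
  117 L/(h·K) central dilation scale), g_con_cr = 400, g_con_sk = 20 per
  K.  Calibration target (fixed once): the resting shorts-clad body at
  29 °C/40 % RH equilibrates at head core 36.6–37.1 °C and mean skin
  33–35 °C; achieved values 36.86 °C and 33.88 °C.
- **Sweating**: total rate
  `(0.2898 − 0.068·D)(T_head − 37 − 0.06·D) + 0.03364·Wrms − Clds` kg/h,
  floored at 0; distributed by α_sw, each segment's share split equally
  over its four sectors, then capped by wettedness 1 at evaporation.
  The sensitivity factor is floored at 0 beyond D ≈ 4.26 % with a warning
  (behaviour there is outside the model's validated range).  The `−Clds`
  term is kept exactly as the controller states it (units absorbed into
  the gain).
- **Shivering**: `g_sh·(36.9 − T_head)₊·Clds` W (g_sh = 24.4 W/K²,
  JOS-scale), distributed to cores by α_sh.  Inactive in all heat
  protocols.
- **Metabolic multiplier**: 1 below 39 °C ambient (sector-averaged stage
  air temperature); `max(1, 1 + 0.13(T_cr − 39))` at or above, evaluated
  at the head core.  Applied to core and skin metabolic rates and to the
  RES metabolic rate.
- `ΔHR` is reported only; it does not feed back into flows.

Controller outputs are continuous in the state; the only discontinuity is
the documented 39 °C ambient branch, which switches at stage boundaries.

## Numerics

- Fixed-step classical RK4, Δt = 1 s (vessel time constants are a few
  seconds at full vasodilation; Δt·λ ≈ 0.45 is well inside the stability
  region).  Halving/doubling the step changes a two-hour protocol's final
  state by < 1e-3 K.  Output sampled every 60 s by default; stage
  boundaries fall on the grid (cadence must divide stage durations).
- State sanity band [0, 60] °C and finiteness are enforced at every
  output sample; violations abort with the time stamp and node index.
- **Equilibration**: the pre-exposure state is the steady state of the
  first stage's environment, with the sweat accumulator frozen at zero.
  In angularly uniform environments the equilibrium is solved by Newton
  (scipy `root`/hybr) on the reduced sector-symmetric manifold — the
  sector perfusion redistribution has an O(1) derivative discontinuity
  exactly at sector equality, which defeats Newton in the full space but
  is smooth (equal-split branch) in the reduced one.  Non-uniform first
  stages fall back to integration with Newton polishing; the convergence
  criterion is max |dT/dt| < 1e-7 K/s within a 10⁴ model-second budget.
- Perfusion redistribution conserves the segment total exactly; negative
  sector shares (possible for extreme sector contrasts) are clipped to
  zero with the deficit removed proportionally from the positive sectors.
- Determinism: no randomness anywhere in the simulation path; repeated
  runs are bit-identical.

## Packaged scenarios

- `uniform-fourstage`: 30 min each at 29/45/29/45 °C, 40 % RH (chamber
  humidity is not part of the protocol record; 40 % is a moderate
  assumption), shorts only (thin clothing on abdomen and thighs),
  h_c = 3.0, h_r = 4.7 W/(m²K), h_e = 16.5·h_c (Lewis relation).
- `fanger-warmwall`: 60 min at 23 °C, then five 30-min stages with the
  wall at 32.6/42/51.6/61.1/70.1 °C and air lowered to
  21.9/20.7/19.3/17.9/16.7 °C; the wall is a 2 m × 2.5 m vertical panel
  0.5 m to the body's left, included only in the heated stages (at 23 °C
  the wall is part of the uniform enclosure).  KSU-uniform clothing
  (0.093 m²K/W) on trunk and limbs, light footwear, head and hands bare.

These fixtures emulate the protocol *structure* of the two validation
exposures: staging, temperatures, clothing and geometry.  They do not
reproduce inter-subject variability, the unrecorded chamber humidity, or
posture; passing the packaged trend checks therefore demonstrates the
model's qualitative response (direction, asymmetry, monotone radiant
gap), not agreement with any specific measured trace.

## Known limitations

- Four angular sectors per segment; no radial skin discretization.
- No counter-current artery–vein exchange beyond the lumped conductances;
  no pulsatility; cardiac output does not couple back from ΔHR.
- No body self-shadowing or inter-segment radiation.
- Single standard body; no anthropometric scaling or acclimatization.
- Controller gains are calibration constants, not measurements; sweating
  behaviour beyond D ≈ 4.26 % is undefined upstream and floored here.
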