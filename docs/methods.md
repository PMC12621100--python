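# Methods

## Scope and model structure

`leafwind` simulates heat and gas exchange of a single broad leaf coupled
to the air through its boundary layer.  Three dynamic states — net
assimilation A, total stomatal conductance to water g_s, and leaf
temperature T_leaf — evolve as

    dA/dt      = (A* − A)/τ_A          (τ_A picked by the sign of A* − A)
    dg_s/dt    = (g_s* − g_s)/τ_g
    dT_leaf/dt = (H_lw + H_sw − H_conv − H_latent)/k

with the targets A* and g_s* and all algebraic variables (C_s, C_i, C_c,
E, D_s, fluxes) closed at every evaluation from the instantaneous state.
The leaf is treated as symmetrically amphistomatous: one-sided
boundary-layer conductances are doubled, heat is exchanged by both faces,
and shortwave is received on one face.

### Photosynthesis

FvCB with A* = min(A_c, A_j) and no smoothing between limitations;
triose-phosphate limitation, cuticular conductance and adaxial/abaxial
asymmetry are deliberately out of scope.  Finite mesophyll conductance is
handled with the quadratic formulation: A_c (and A_j with V → J/4,
K → 2Γ*) is the lower root of

    −A²/g_m + A[(V − R_d)/g_m + C_i + K] + [R_d(C_i + K) − V(C_i − Γ*)] = 0,

equivalent to the rectangular form evaluated at C_c = C_i − A/g_m (the
g_m → ∞ limit recovers the rectangular expression; a brute-force
root-bracketing oracle checks the root selection in the tests).
Electron transport J is the lower root of the non-rectangular hyperbola
in I₂ = PPFD · Abs_PAR · (1 − f)/2 with f = 0.15 and curvature Θ.
g_m is carried on a pressure basis (µmol m⁻² s⁻¹ Pa⁻¹, as usually
reported) and converted to a mole-fraction basis by multiplying by ambient
pressure.

Temperature responses: K_c, K_o, Γ*, R_d follow Arrhenius functions and
g_m a peaked Arrhenius function with the tobacco-calibrated in-vivo
constant sets standard in the FvCB literature; all constants live in the
editable preset YAML, not in code.  V_cmax and J_max default to the plain
Arrhenius form of those same calibrations (E_a = 65 330 and 43 540
J mol⁻¹), which is how they were fitted over 10–40 °C; an optional
H_d/ΔS slot in `PhotoParams` switches on a peaked (deactivating) response
for users who prefer it.  With the peaked variant the simulated midday
depression at low g_bw roughly doubles, which places the diurnal gain
curve far above the reference behaviour this package reproduces — the
Arrhenius default is therefore both the cited form and the validated one.

### Stomata

Leuning form g_s* = g₀ + g₁ A/[(C_s − Γ)(1 + D_s/D₀)] on a total
(two-sided) water basis, using the *instantaneous* A and the leaf-surface
variables C_s and D_s, so the boundary layer feeds back on stomatal
behaviour.  Γ is the compensation point including respiration,
Γ = (Γ* V_cmax + R_d K_m)/(V_cmax − R_d).  Degenerate guard: if
C_s ≤ Γ (or A < 0) the target is pinned at g₀ (scalar calls warn).

### Transport and energy balance

CO₂ drawdowns use the boundary-layer factor 1.37 and stomatal factor 1.6
(water:CO₂ diffusivity ratios to the 2/3 and 1st power respectively):
C_s = C_a − 1.37 A/g_bw,total, C_i = C_s − 1.6 A/g_sw.  Transpiration
E = g_t (e_i − e_a)/P with g_t the series water conductance and
e_i = e_sat(T_leaf) by the Tetens formula over water; ambient e_a is an
input (2.4 kPa ≙ 50% relative humidity at 32 °C in the greenhouse
scenario).  The leaf-surface deficit is D_s = (e_i − e_a)(1 − g_t/g_b),
floored at zero.  Energy balance per unit (one-sided) leaf area:
H_sw = Abs_SW · k_sun · PPFD on the lit face;
H_lw = 2 ε σ (T_refl⁴ − T_leaf⁴) over both faces, with the radiative
background T_refl defaulting to air temperature; H_conv = c_p g_bh,total
(T_leaf − T_air) with g_bh = g_bw/1.08206; H_latent = λ(T_leaf) E.

## Boundary-layer physics

Air properties are anchored at 25 °C (D_w = 24.6, D_h = 21.85,
D_c = D_w/1.37^{3/2} ≈ 15.34, ν = 15.5 mm² s⁻¹) and scaled as
(T/298.15)^{1.75} × (101.325/P); the anchors were chosen from the standard
tables so that (D_w/D_h)^{2/3} reproduces the 1.08206 heat→water factor
and the forced-laminar formula reproduces the 0.196/0.506 mol m⁻² s⁻¹
reference conductances, and they live in a single editable table.  Tying
D_c to D_w through the 1.37 factor makes direct CO₂-conductance
computation and water→CO₂ conversion exactly consistent.  Conversions to
molar conductance use the ideal gas law.  Only laminar forced convection
is used in the simulations (turbulence corrections are out of scope); the
free-convection operator returns the upper-surface value, and mixed-regime
blending (max, parallel sum, or a power-mean with k = 3.5) is left to the
caller since no single convention dominates.

Canopy wind: neutral log profile above the canopy with preset
(d, z_m) fractions per canopy (dense wheat 0.7h/0.07h at LAI 5.30; sparse
0.65h/0.10h at LAI 2.65; the station preset 0.7h/0.1h at h = 0.475 m); no
attempt is made to model d and z_m continuously from LAI.  Within the
canopy u = u_top exp[a(z/h − 1)] with a = (0.2 LAI h/m)^{1/2},
m = (4wh/π LAI)^{1/2}.  The fetch-validity rule (z ≤ 0.01 × fetch) is a
warning, not an error.  The wind→g_bw climatology filters to daytime
records (PPFD > 0 when available, else a clock window) and
temperature-corrects air properties per record (grouped to 0.5 °C for
speed; the tests verify equivalence with per-record brute force).

## Solvers and numerics

* **Dynamic:** fixed step (default dt = 2 s), exact exponential-relaxation
  updates for A and g_s against frozen targets, explicit Euler for
  T_leaf.  The leaf thermal time constant k/(∂net/∂T_leaf) is ~5–10 s for
  k = 280 J m⁻² K⁻¹, so dt = 2 s is comfortably stable; halving dt moves
  the diurnal integrals by < 0.1%.  The stepping core is vectorised over a
  batch of (g_bw, C_a) pairs, which is how the 11 × 9 sweep runs as a
  single integration.
* **Steady state:** outer Brent root on T_leaf closing the energy balance
  (tolerance 10⁻⁴ °C on a ±(20, 30) K bracket around air temperature),
  inner damped fixed point (damping 0.5 on both A and g_s) on the
  algebraic loop, converged at 10⁻⁶ µmol mol⁻¹ on C_i.  The infinite-g_b
  mode is an explicit code path: T_leaf = T_air (convection pins it),
  C_s = C_a, D_s = e_i − e_a; no infinities enter the arithmetic.
* **Cross-validation:** the two solvers are independent routes to the same
  fixed point; the suite verifies ≤ 1% agreement in A over a
  3 × 3 × 3 (PPFD × T_air × g_bw) grid, Fick consistency
  C_a − C_c = A(1.37/g_bw + 1.6/g_sw + 1/g_m) to 10⁻⁶ relative, and
  energy closure |net| < 0.1 W m⁻² at steady state.

## Parameters

Two shipped presets (YAML, fully editable):

| block | tomato_greenhouse | wheat_field |
|---|---|---|
| V_cmax25 / J_max25 (µmol m⁻² s⁻¹) | 141 / 186 | 140 / 220 |
| g_m25 (µmol m⁻² s⁻¹ Pa⁻¹) | 3.2 | 5 |
| R_d25 (µmol m⁻² s⁻¹) | 1.5 | 0.9 |
| Abs_PAR / Abs_SW | 0.84 / 0.50 | 0.86 / 0.50 |
| Θ (J curvature) | 0.70 | 0.70 |
| g₀ (mol m⁻² s⁻¹), g₁, D₀ (kPa) | 0.05, 11, 1.5 | 0.02, 7.38, 2 |
| τ_A rise/fall (s) | 300 / 1 | — (steady state) |
| τ_g rise/fall (s) | 900 / 450 | — |

Values not reported with these sets required choices: k_sun = 1/(4.57 ×
0.47) ≈ 0.466 W m⁻² per µmol m⁻² s⁻¹ (PAR quantum-to-energy 4.57
µmol J⁻¹, PAR fraction 0.47 of total shortwave — i.e. PPFD 1500 ≙ ~700
W m⁻² shortwave); areal heat capacity k = 280 J m⁻² K⁻¹ (a thin,
water-dominated leaf); emissivity 0.95; oxygen 210 mmol mol⁻¹.  The wheat
preset keeps the tobacco Michaelis constants — wheat-specific K_c/K_o can
be entered in its YAML but no reliable printed pair was available.  The
diurnal gain percentages are sensitive to k_sun at roughly −1 percentage
point on the 0.10→0.15 gain per 10% reduction in k_sun (less shortwave →
cooler leaf → weaker low-g_bw penalty).

## Synthetic forcings

The generators define the study conditions rather than fitting data:

* the diurnal forcing is a 16 h photoperiod, half-sine PPFD peaking at
  1500 µmol m⁻² s⁻¹, constant T_air 32 °C, e_a 2.4 kPa, C_a 425
  µmol mol⁻¹ (the light-curve shape is not uniquely determined by a
  smooth unimodal day; a trapezoid option exists, and with it the gain
  percentages rise by ~1–2 points since more time is spent at high load);
* the wheat profile spans 0.1h–h over h = 0.8 m with C_a 366 → 380
  µmol mol⁻¹ (top → bottom, exponential approach), PPFD 1600 µmol m⁻²
  s⁻¹ at the top with Beer–Lambert decay (k = 0.5, LAI 5.3 uniform),
  u_top = 1 m s⁻¹ attenuated by the canopy law, and mild (−1 °C, −0.3
  kPa) bottom offsets for temperature and VPD;
* the wind series has an exactly Weibull marginal (shape 2, scale
  3 m s⁻¹ by default) with AR(1) Gaussian-copula persistence.

These emulate the *structure* of greenhouse and field microclimates, not
any measured record: constant greenhouse air state, no sunflecks or
windflecks, no vertical nitrogen/water-status gradients, single-day
snapshots.  Passing tests therefore demonstrate internal consistency and
the qualitative/quantitative behaviour of the coupled model under
controlled conditions — not agreement with any particular field dataset,
and the profile experiment in particular is property-based (monotone g_bw
with depth, leaf-size ordering of temperature ranges, infinite-g_b
flattening) rather than a point-by-point reproduction.

## Scenario conventions

Daily integrals and means are computed over the photoperiod (lights-on
samples) by trapezoidal quadrature; a 24 h convention would dilute all
percentages with a constant nocturnal respiration term.  Percent gains are
always reported against the named lowest-g_bw baseline; "additional" gains
between intermediate levels are expressed relative to that same baseline.
WUE_INST is the ratio of photoperiod means, mean(A)/mean(E); a
pointwise-mean variant is also emitted since the averaging order is a
convention.  Sweep optima are grid argmaxima (no interpolation), and the
95%-of-max curve picks the smallest grid g_bw reaching 0.95 × the column
maximum.  Profile runs are independent steady-state snapshots per height;
there is no radiative or aerodynamic coupling between layers, and canopy
totals are deliberately not computed.

## Known limitations

Laminar forced convection only (no turbulence enhancement); symmetric
amphistomaty; no triose-phosphate limitation or A_c/A_j smoothing; no
cuticular conductance; Tetens saturation curve (≤ 0.1% error below
45 °C); the greenhouse scenario holds air state constant, which overstates
leaf-to-air coupling feedbacks at the canopy scale; the within-canopy wind
law is calibrated for natural crop canopies, not fan-driven flow in
controlled environments.
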