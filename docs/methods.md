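# Methods

## Model overview

The simulator treats one seed as a shrinking sphere of uniform
temperature. Three sub-models close the problem: a sorption isotherm
(water activity as a function of moisture and temperature), a moisture
diffusivity, and external transfer correlations. Assumptions: (a) a
single lumped seed temperature (Biot number below ~0.4 for the baseline
geometry and air speed, checked by `compute_biot`); (b) perfect
spherical symmetry; (c) one homogeneous material (with a two-material
embryo/coat variant); (d) ideal shrinkage — seed volume is the sum of
component volumes, so the volume lost equals the volume of water
evaporated.

## Sorption isotherm

Water activity follows Flory–Huggins theory with the effective
interaction parameter interpolating between the concentrated-regime
value χ_ws and the semi-dilute value 0.5:

    χ_eff = χ_ws                        for χ_ws ≤ 0.5
    χ_eff = χ_ws − (χ_ws − 0.5) φ_w²    for χ_ws > 0.5

The water volume fraction φ_w is computed over water plus hygroscopic
solids only; oil does not sorb water and is excluded from both numerator
and denominator. Glass transition of the water/solid mixture follows
the Couchman–Karasz mixing rule; its derivative ∂T_g/∂y_w is analytic
(not numeric) so the free-volume term stays smooth for the solver.

Two glassy-state additions are available below T_g (both vanish
continuously at the transition, so a_w is continuous there by
construction):

* **Free volume (`FH_FV`)**:
  μ_FV = M_w ΔC_p,s/(R T) · (1 − y_w)² · (1 − T/T_g) · ∂T_g/∂y_w.
  Since ∂T_g/∂y_w < 0 (water plasticizes), μ_FV < 0 in the glassy
  state: the material holds more water than plain FH predicts.
* **Leibler–Sekimoto elastic (`FH_LS`)**:
  μ_LS = ν_w K_g/(R T) · ln((1 − φ_w,Tg)/(1 − φ_w)) for φ_w < φ_w,Tg.
  This is negative in the glassy state, again increasing retention; the
  large prefactor ν_w K_g/(R T) ≈ 24 for K_g = 3.3 GPa pins the
  predicted equilibrium moisture just below the glass-transition
  moisture content, which is the mechanism behind the
  "non-equilibrium" isotherm: stresses that cannot relax during fast
  drying hold water in the matrix.

**Sign convention.** The elastic term is sometimes written with the
reciprocal logarithm argument, which flips its sign. The
positive-in-glassy form makes a_w *rise* as the material dries below
the transition (equilibrium MC ~10⁻⁶ at 30 % RH instead of ~0.13,
i.e. *less* retention, contradicting both the physics the term is meant
to express and the observed final moisture contents) and renders the
evaporating surface shell stiff far beyond what an explicit integrator
can follow. This package therefore uses the retention (negative) sign
by default; `IsothermParams.ls_literal_sign=True` switches to the
opposite convention for comparison studies.

a_w > 1 can legitimately occur for χ_ws > 1 at intermediate moisture
(it drives the fast early drying phase); it raises a diagnostic warning
rather than an error, and `clip_aw_at_unity` (default off) is available
because silent clipping would change fluxes.

`equilibrium_moisture` returns the smallest moisture root of
a_w(y_w) = RH (log-spaced scan plus Brent), which is the final moisture
content a drying run converges to.

### Fitting

χ_ws is fitted by least squares with residuals in moisture content at
the table's a_w values (isotherms are plotted and judged as MC vs a_w,
so this matches how agreement is assessed); each model evaluation
inverts the isotherm. Only rows above the glass transition at their own
moisture content are used (plain FH holds only there); at least three
such rows are required. K_g is fitted the same way (on log₁₀ K_g, for
conditioning) to observed final moisture contents, using only points in
the glassy region — rubbery points carry no information about K_g.

## Diffusivity

D_w = (a log₁₀ y_w + b)·exp(−E_a/R (1/T − 1/298.15 K)), clamped below
at `floor` = 10⁻¹² m²/s *after* the full evaluation, so the Arrhenius
factor cannot lift a clamped value. The unit of the floor is m²/s
(dimensional consistency with the rest of the expression). The mutual
diffusivity of the transport equation is identified with the measured
water diffusivity; a configurable multiplier (default 1) documents that
assumption. (a, b) are a linear least-squares fit against log₁₀ y_w at
the 25 °C reference (clamped points excluded with a warning); E_a is
fitted on the ratio to the reference-temperature model and reduces to a
closed form for a single point.

## Numerical scheme

* **Discretisation**: N equal-volume shells at t = 0 (default N = 10);
  cell-centred concentrations; interface flux
  −D·(c_{k+1} − c_k)/(r_{c,k+1} − r_{c,k})·A_k between shell *volume
  centroids*; zero-flux centre; surface a_w evaluated at the outer
  shell's centred moisture (a good surface approximation at this
  resolution). Interface diffusivity at the arithmetic mean of the
  adjacent shell moistures.
* **Shrinkage**: after every step, shell volume = solid mass /
  dry-matter density + water mass / water density at the current
  temperature (zero excess mixing volume); radii re-derived from
  cumulative volumes. Solid mass per shell is constant by construction
  (Lagrangian frame).
* **Time step** (explicit Euler, adaptive): the minimum of
  0.25·min_k(Δr_k²/(2 D_k)) (diffusive stability), a cap so no shell
  loses more than 10 % of its water per step, a 0.5 K temperature-change
  cap, and a linear-stability bound 0.5/λ on the surface evaporation
  term with λ = ∂(J A)/∂m_w of the outer shell. The last bound matters
  where the activity curve is steep (glassy pinning); without it the
  surface oscillates around equilibrium at coarse shell counts.
* **Two-material variant**: the outermost shell is coat material
  (χ_ws = 0.465), the rest embryo (χ_ws = 1.302); the embryo→coat flux
  is activity-driven, β_int·A·(c_avg/a_avg)·(a_embryo − a_coat).
  The default β_int converts the activity difference back to an
  equivalent concentration difference via the secant slope of the
  embryo isotherm, so the two-material model with identical materials
  reproduces the one-material fluxes exactly; a plain numeric β_int can
  be set in configuration. Evaporation always uses the coat a_w in this
  mode.
* **Heat balance**: ρ_eff c_p,eff V dT/dt = [h_eff (T_air − T) − L(T)
  J_evap] A with L(T) = ΔH_evap,0 + (c_p,v − c_p,w)(T − T₀). The
  convective term is written so heat flows from hot air into a cooler
  seed (the transcribed ordering h_eff(T − T_air) with a positive
  right-hand side would cool the seed indefinitely below air
  temperature; figures of seed temperature approaching air temperature
  support the physical sign). `strict_heat_sign=True` restores the
  literal ordering for comparison. Both saturation-pressure factors in
  the evaporative flux are evaluated at the seed temperature as stated;
  `airside_psat_at_Tair` switches the air-side term to T_air for
  sensitivity studies (default off).
* **Linear test mode**: constant D, frozen geometry, isothermal, zero
  surface concentration — the configuration in which the solver can be
  compared with the closed-form Fickian-sphere series
  (6/π²)Σ n⁻² exp(−n²π²Dt/R²); agreement is within 1 % of initial
  water content at N = 20.

## Material properties

Component densities and specific heats use the Choi–Okos temperature
polynomials (water, protein, carbohydrate, fat, fibre, ash); fibre and
sugar use the carbohydrate density (complex/simple carbohydrates, same
density class). Saturation pressure uses the Arden Buck correlation, a
Magnus-type form accurate to ~0.05 % over 0–100 °C (it reproduces
101.325 kPa at the normal boiling point, which the plain Magnus
constants miss by ~3 %). Air viscosity and conductivity are low-order
fits to dry-air tables (0–80 °C), vapour diffusivity follows
2.262·10⁻⁵ (T/273.15)^1.81, and air properties are evaluated at the
boundary-layer average temperature (T_air + 2T)/3. λ_eff is the
volume-fraction-weighted mean of λ_w and λ_s with the *total* water
volume fraction (oil counts as solid here, unlike in the isotherm).

## Parameter defaults (configuration, with provenance)

| Parameter | Default | Why |
|---|---|---|
| χ_ws | 1.244 whole / 1.302 embryo / 0.465 coat | fitted values for cabbage seed material |
| χ_0 | 0.5 | semi-dilute limit, fixed by theory |
| N_s | 10³ | polymeric solute: (1 − 1/N_s) ≈ 1; not separately identifiable |
| K_g | 3.3·10⁹ Pa | fitted elastic modulus; same order as reported glassy biopolymers (~10⁹ Pa) |
| T_g,w, ΔC_p,w | 136 K, 1.94·10³ J/(kg·K) | literature water values |
| T_g,s, ΔC_p,s | 420 K, 450 J/(kg·K) | substitute values for seed solids, chosen once so the 25 °C transition sits near 15 % MC, consistent with glassy-pinned final MCs of 10–13 % |
| a, b | 3·10⁻¹¹, 9·10⁻¹¹ m²/s | fitted at 25 °C |
| E_a | 14.18·10³ J/mol | fitted at 40 °C |
| D floor | 10⁻¹² m²/s | mobility levels off in the glassy state |
| R₀ | 1.0·10⁻³ m | ~2 mm seed diameter |
| MC₀ | 0.367 wb | hydrated-seed moisture after 4-day priming |
| U | 0.235 m/s | air speed of the transfer-coefficient closure |
| λ_w, λ_s | 0.60, 0.20 W/(m·K) | substitute conductivities (water / dry biopolymer) |
| dry composition | oil 0.35, protein 0.28, carb 0.12, fibre 0.14, sugar 0.05, ash 0.06 | oil fraction from whole-seed measurement; the split of hygroscopic classes is a documented placeholder typical of Brassica proximate analyses |

Entries marked substitutes/placeholders stand in for material constants
that are not published with the model; they live in configuration and
can be overridden wholesale (`SimulationConfig.from_yaml`).

## Synthetic data

The fixtures module generates every input format from the model itself:
sorption tables (equilibrium inversion at the stepwise humidity program
95→10 % RH), diffusivity tables, drying "experiments" (solver output
sampled at a balance-like cadence), measured-like air schedules
(set point plus smooth bounded sensor wobble), and black/white seed-bed
rasters (segregated, mixed, or an intermediate blend). Noise is
multiplicative Gaussian on moisture content, truncated to (0, 1),
because balance noise scales with signal; every generator takes its own
seed so adding one fixture never perturbs another. What passing tests
on these fixtures show is internal consistency (parameter recovery,
conservation, oracle agreement) — they cannot show that the model fits
real seeds, which requires measured drying curves; they also omit
instrument artefacts such as balance drift and sensor lag.

## Mixing entropy

Images are binarized (Otsu threshold by default, fixed threshold and
crop box available), divided into a 5×5 grid, and scored with the
particle-count-weighted binary mixing entropy

    S = Σ_j (n_j/Σn) s_j / s_max,  s_j = −(x_j ln x_j + (1−x_j) ln(1−x_j)),

normalized by s_max at the overall white fraction, with 0·ln 0 = 0.
S = 1 is a fully mixed bed, S = 0 fully segregated. This expression is
a reconstruction of the standard grid-based binary mixing entropy (the
primary description does not print a formula); the cell weighting is by
seed-pixel count, which reduces to area weighting when seeds cover the
frame uniformly.

## Known limitations

* Validity is limited to drying temperatures up to ~40 °C — the
  diffusivity and isotherm parameters were fitted at 25/40 °C.
* No pore/bubble mechanics: air pockets that form in the embryo during
  drying are not modelled; the fitted diffusivity absorbs their effect.
* No intra-seed temperature gradients, no hysteresis (sorption and
  desorption are separate fits), no multi-seed bed model — a well-mixed
  fluidised bed is represented by a single seed seeing the averaged air
  conditions (inlet/outlet averaging is provided).
* Percent error uses the model value in the denominator and is
  asymmetric by design; it diverges as the model MC approaches zero.

## Test problem sizes

The long property checks run at reduced problem sizes chosen for quick
convergence while staying in the asymptotic regime: the equilibrium
consistency and Monte-Carlo noise checks use a 0.5-mm seed, N = 5 and a
10⁻¹¹ m²/s diffusivity floor; the grid-sensitivity check runs the full
24-h baseline at N = 5/10/20; the Fickian-series comparison uses N = 20
with D = 10⁻¹⁰ m²/s over two diffusion time scales.
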