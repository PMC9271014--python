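# Methods

## Model

`oysterdeb` implements an individual-level Dynamic Energy Budget model
of the `asj` family for two oyster species. The state is
(E, V, E_H, E_R) — reserve (J), structure (cm³), maturity (J),
reproduction buffer (J) — plus the ageing pair (q, h) of the
Weibull–Gompertz module. Assimilated energy enters the reserve; the
mobilised power p_C is split by the κ-rule: a fixed fraction κ pays
volume-linked somatic maintenance [p_M]·V (plus an optional
surface-linked term {p_T}·V^(2/3), zero for both species here) and
funds growth at cost E_G per cm³ of new structure; the remaining 1−κ
pays maturity maintenance k_J·E_H and accumulates as maturity (before
puberty) or in the reproduction buffer (after). Maturity thresholds
E_Hb ≤ E_Hr ≤ E_Hs ≤ E_Hj ≤ E_Hp mark birth (first feeding), larval
release from the brooding mother (flat oyster only), settlement, the
end of metamorphosis and puberty. Before birth the embryo lives on the
initial reserve of its egg; between settlement and the end of
metamorphosis the surface-specific assimilation {p_Am} and the energy
conductance v are multiplied by the acceleration factor s = L/L_s
(L_s = structural length at settlement on the running trajectory),
frozen at s_M = L_j/L_s afterwards. All rates are multiplied by the
5-parameter Arrhenius factor

    TC(T) = exp(T_A/T_ref − T_A/T) · s(T_ref)/s(T),
    s(T)  = 1 + exp(T_AL/T − T_AL/T_L) + exp(T_AH/T_H − T_AH/T),

so TC(T_ref) = 1 exactly. An optional decoupled mode applies a separate
temperature block to the feeding fluxes only (`ThermalResponse`,
`SimOptions.feeding_temp`); the default is the coupled response. Food
is either a directly supplied scaled functional response f ∈ [0, 1] or
a chlorophyll-a concentration converted through the Holling type-II
response f = X/(X + K_X).

## Parameter convention

Species files carry the tabulated symbol vocabulary (T_ref … K_X) plus
an `aux` block with composition constants and the reference
acceleration factor `s_M_ref` (5.9 flat oyster, 4.8 Pacific oyster,
1 for the standard-model set). The tabulated {p_Am} and v are
interpreted as the **fully accelerated** (juvenile/adult) values; the
embryo/larval base values are {p_Am}/s_M_ref and v/s_M_ref. This
reading is forced by internal consistency: κ·{p_Am}/[p_M] then matches
the tabulated post-acceleration zoom factor for the Pacific oyster to
1% (0.26·372/17.35 = 5.57 vs 5.62) and gives ultimate physical lengths
of ~13 cm (flat) and ~28 cm (Pacific), in line with observed maxima;
the alternative (pre-acceleration) reading implies ~80 cm flat oysters.
The reserve capacity [E_m] = {p_Am}/v is invariant to the convention.
The emergent lifecycle factor s_M = L_j/L_s computed from the full
larval solution at f = 1 reproduces the reference values to 1%
(5.96 and 4.81); simulations started post-metamorphosis use `s_M_ref`
for the frozen factor, while trajectories that pass through
metamorphosis freeze the factor at their own emergent value
(continuity). The tabulated zoom factor `z` is stored for reference
but never used in computation — the derived value κ·{p_Am}_base/[p_M]
is reported by `compound_parameters` instead.

Composition constants default to the conventional generalised-animal
values (d_V = d_E = 0.09 g/cm³, mu_E = 550 kJ/mol,
w_E = w_V = 23.9 g/mol); the dry/wet tissue ratio is species-specific
(0.015 / 0.018). Dry weight is d_V·V + w_E(E + E_R)/mu_E; wet weight
divides by the dry/wet ratio; the structure/reserve/buffer partition
sums to the total exactly.

## Life events

* **Initial reserve.** E_0 is solved by bisection (80 iterations,
  relative bracket 1e-11) on the embryo initial-value problem
  (E, V, E_H) from (E_0, 1e-12 cm³, 0) to E_H = E_Hb, targeting a
  prescribed scaled reserve density at birth e_b (default 1). The egg
  volume 1e-12 cm³ is far below the birth volume (~2e-6 cm³); results
  are insensitive to it.
* **Spawning.** Unspecified in the source material; implemented as a
  configurable daily-evaluated trigger, default: buffer density
  E_R/V above 0.5·[E_m] (roughly a full reserve-equivalent of gonad)
  AND water warmer than 15 °C. A spawn empties κ_R of the buffer; the
  egg count divides the released energy by the egg cost at the
  spawner's current reserve density (rounded to 0.01 in e to reuse the
  cached egg-cost solution). For the flat oyster a spawning event
  starts brooding.
* **Brooding.** Feeding of the brooding mother is multiplied by 0.8
  until the brood reaches the release maturity E_Hr — the default
  duration integrates the brooded embryo at ambient temperature; a
  fixed-duration mode (default 10 d) is available.
* **Starvation.** When κ·p_C < p_S, the shortfall is paid first from
  the reproduction buffer, then by shrinking structure at E_G per cm³;
  maturity never decreases; death when the scaled reserve density
  falls below 1e-4. These rules are standard DEB practice; the source
  material does not specify them.
* **Ageing.** dq = (q·(V/V_m)·s_g + h_a·TC)·e·(v_eff/L − r) − r·q,
  dh = q − r·h, with V_m the fully accelerated maximum structural
  volume. Deterministic survival bookkeeping S = exp(−∫h) is the
  default; expected lifespan is ∫S dt (trapezoid on a 2001-point grid
  over 60 000 d, returned as infinite when S fails to fall below 1e-3,
  e.g. as h_a → 0).

## Simulation

`simulate` integrates the augmented state
[E, V, E_H, E_R, q, h, ∫p_A, ∫(p_S+p_J), ∫p_J, ∫h] with LSODA
(default rtol 1e-8; component-wise absolute tolerances scale the base
atol 1e-10 down by 1e-6 for V and 1e-2 for E_H, which live on much
smaller scales during the larval phase). Maturity thresholds,
starvation death and buffer exhaustion are terminal solver events;
integration restarts at each event, which also switches the
acceleration context. Daily chunking applies only once the individual
is an adult with spawning enabled. The accumulated assimilation and
maintenance integrals let any stored window verify the full budget

    ΔE + ΔE_R + ΔE_H + E_G·ΔV + ∫(p_S + p_J) + spawned = ∫p_A,

which closes to ~1e-16…1e-8 relative in practice (the acceptance check
requires 1e-6). The balance is exact under the implemented starvation
rules except in the pathological regime where maturity maintenance is
unpayable (the p_R < 0 clamp), which the shipped parameter sets do not
reach under the tested conditions.

`init_from_weight` inverts the weight model in closed form under the
field-initialisation convention: fit animals (e = 0.8), empty buffer,
fully mature.

## Estimation

The loss is the root of the weighted mean of squared relative errors
(MRE). Default weighting makes the dataset, not the point, the unit:
β = 1 per zero-variate datum, β = 1/m per point of an m-point series.
A symmetric-relative-error variant (|Y−Ŷ|/((|Y|+|Ŷ|)/2), mean of
absolute values) is available for cross-checking against parameter
sets estimated under that convention. Predictions dispatch on trait
name (ab, Lb, Wd0, Wwp, Wdi, Li, am, Ri, rB) or series kind (growth,
age_length, respiration_vs_T, fecundity_vs_length) to the lifecycle,
simulator and observable routines.

Minimisation is Nelder–Mead with the standard coefficients
(reflection 1, expansion 2, contraction 0.5, shrink 0.5), free
parameters transformed to log10 (logit for the fractions κ, κ_X, κ_R)
to enforce their domains, box bounds (if given) enforced by an
infinite loss, convergence at a simplex loss spread below 1e-6 or the
iteration budget, and up to three restarts from the best vertex. The
procedure is deterministic given the starting point. K_X calibration
is a bounded one-dimensional minimisation over log10 K_X.

Identifiability: growth data alone leave (κ, [p_M], {p_Am}) nearly
collinear along the ultimate-size ridge κ{p_Am}/[p_M]; with κ = 0.92
the reproductive stream (1−κ) is the sharpest constraint on κ, and
maintenance-dominated observables (starvation weight loss, oxygen
consumption) pin [p_M]. The closed-loop recovery experiments therefore
use the data-type mix of a realistic estimation compilation: growth at
two food levels and two temperatures, a starvation trial, a
respiration-versus-temperature series, a fecundity-versus-length
series with a known (measured) per-egg cost, and three trait values —
38 observations in all. With that design, noise-free recovery of
{p_Am, v, κ, [p_M]} from ±20% perturbed starts is exact to ~1e-8, and
under 5% multiplicative lognormal noise the worst parameter error over
ten seeded replicates is ~9%.

## Synthetic data

The generator emulates the study designs: a constant-condition
laboratory replica (3, 8, 15, 20, 25, 30 °C × 2 and 10 µg chl a L⁻¹,
42 d, spat of 0.87 g (flat) / 1.13 g (Pacific) wet weight, weekly
observations) and a two-year seasonal aquaculture replica (sinusoidal
temperature 11 ± 7 °C and chlorophyll 4 ± 3 µg/L, monthly wet
weights). Observation noise is multiplicative lognormal
(Y = truth·e^ε, ε ~ N(0, σ²)) because all observables are positive and
the loss is relative; σ defaults to 0. All randomness flows from a
single integer seed. What the generator does **not** emulate: serial
correlation of field forcing, measurement-protocol biases (e.g. shell
vs tissue allometry drift), size-selective mortality, and
between-individual parameter variation — so passing recovery tests
demonstrate estimator correctness, not field identifiability.

## Problem sizes and tolerances used by the test suite

Oracle equivalence uses a 30-day juvenile window (fixed-step Euler,
dt = 1e-3 d) at 1e-3 relative; the von Bertalanffy limit a 4000-day
constant-condition run at 0.5% of L_∞; conservation checks 40–400-day
windows at 1e-6; recovery fits cap Nelder–Mead at 300–600 iterations.
These sizes were chosen as the smallest that exercise each property
cleanly.

## Known limitations

* **Trait-table mismatch.** The tabulated parameter vector does not
  reproduce every published life-history trait prediction: with it,
  age at birth is 13.1 d (published prediction 5.2), wet weight at
  puberty 2.6 g (0.20), ultimate dry weight 30–44 g (16.2) and
  ultimate reproduction ~2.0e6 eggs/yr (3.57e6), while lifespan
  (14 100 vs 11 900 d), the lengths at birth/release/settlement
  (0.0191/0.0198/0.0380 vs 0.0190/0.0200/0.0387 cm) and both
  acceleration factors match to a few percent. Since the same
  machinery reproduces the latter group almost exactly, the mismatch
  indicates the published parameter table and trait predictions are
  not mutually consistent (κ = 0.92 with E_Hp = 32 J forces puberty
  near 2.6 g wet weight under any admissible reading); the
  corresponding soft checks in `tests/test_acceptance.py` fail by
  design and are kept as documentation of the gap.
* Salinity, current, turbidity, fouling and air-exposure effects on
  feeding are not modelled; chlorophyll-a is the only food proxy.
* Respiration is a relative proxy (weighted dissipating powers);
  no absolute O₂ calibration is attempted.
* The standard-model Pacific oyster set lacks maturity thresholds and
  the ageing block: post-metamorphic simulation only.
* Sex change is reduced to the κ_R = 0.45 even-allocation convention
  of the flat oyster; no explicit sex dynamics.
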