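# Methods

## Scope and state variables

The package models the batch-recycle degradation of paracetamol (PCT) by
Fenton and photo-Fenton chemistry at pH 2.8 and constant temperature. The
state is the four molar concentrations (PCT, H₂O₂, Fe²⁺, Fe³⁺). Reaction
intermediates, TOC evolution, pH drift, dissolved oxygen, and the
hydrodynamics of the recirculation loop are outside the model: the whole
15 L inventory is treated as a single well-stirred volume, with the
photochemical term scaled by the irradiated fraction V_IRR/V_T = 0.10.

## Rate laws

The mechanism is: (1) Fenton, Fe²⁺ + H₂O₂ → Fe³⁺ + OH⁻ + HO• (k₁);
(2) photolysis of the ferric-hydroxo complex regenerating Fe²⁺ and one HO•
(wavelength-averaged quantum yield Φ̄); (3) Fenton-like recycling,
Fe³⁺ + H₂O₂ → Fe²⁺ + H⁺ + HO₂• (k₃); (4) HO• + H₂O₂ (k₄); (5) HO• + PCT
(k₅). Applying the steady-state approximation to HO• (radical–radical
termination and HO• + Fe²⁺ neglected, O₂ in excess) partitions every
radical between its two sinks with fractions 1/δ = k₅C_PCT/(k₅C_PCT +
k₄C_H₂O₂) and 1/ρ = 1 − 1/δ. The partition is computed in this normalized
form rather than via δ and ρ themselves, which makes the degenerate states
well defined: both fractions are 0 when both sinks are zero, and each goes
to its continuous limit (0 or 1) when exactly one vanishes. As printed,
the per-species balance equations omit the τ = (−1/δ, −1/ρ, +1, −1)
factors on the radiation term; the implementation applies them, the only
form consistent with the general matrix rate expression and with photon
balance (the two organic loss channels must sum to the absorbed-photon
rate).

A structural property with consequences downstream: all rates depend on k₄
and k₅ only through k₄/k₅, so the pair is not jointly identifiable from
concentration data.

## Radiation field

The lamp is a line source with spherical isotropic emission (LSSE). The
monochromatic LVRPA at radius r and height z integrates the attenuated
emission over the limiting angles θ₁ = atan(r/(L_L−z)), θ₂ = −atan(r/z)
subtended by the lamp ends; attenuation follows the path
(r − r_int)/cos θ from the inner annulus wall. The printed integral runs
from θ₁ to θ₂, which is negative; the implementation orients it θ₂ → θ₁ so
absorption is positive. The only absorber in 300–420 nm is Fe(OH)²⁺, taken
equal to total Fe³⁺, so κ_λ = κ_T,λ = α_λ C_Fe³⁺. The axial registration
of the 13 cm irradiated annulus on the 58.98 cm lamp is not part of the
device specification; it is centred by default and configurable.

The volume average is computed on a tensor Gauss–Legendre grid
(16×16 in r,z; 32 in θ; the spectrum's wavelength grid with trapezoid
weights), doubled until the result moves < 0.5% (one doubling suffices for
every case exercised here — the integrand is smooth). Local values use
adaptive quadrature at relative tolerance 1e-8. Volume averages are
tabulated once against Fe³⁺ (mg/L) and coupled to the ODE through a
monotone piecewise-cubic (PCHIP) interpolant; beyond the last node the
table extrapolates linearly with the end slope. Direct quadrature inside
the ODE right-hand side is available behind a flag and agrees with the
table coupling to ~1e-4, but is ~100× slower.

Two synthetic data objects stand in for bench-specific inputs and are
labelled synthetic in code: a raised-cosine "actinic-BL-like" spectrum on
300–420 nm normalized to the actinometric total photon power
3.36e-4 Einstein/min, and an exponential Fe(OH)²⁺-like naperian
absorptivity (2300 M⁻¹cm⁻¹ at 300 nm, 30 nm decay). All self-contained
results (tests, acceptance) use them consistently for generation and
fitting, so no conclusion depends on their absolute shape; reproducing
bench-specific absolute LVRPA values (e.g. 1.18e-9 Einstein/cm³/s at
10 mg/L Fe³⁺) additionally requires the manufacturer spectrum and
literature absorptivities supplied as CSV (the basis — decadic vs
naperian — of published absorptivities must be converted to naperian;
the CSV header should record it).

Φ̄ is likewise a configuration constant: the package default is 0.14
mol/Einstein, a representative literature magnitude for ferric-hydroxo
photolysis in the near-UV, used consistently everywhere.

## Reactor integration

Internal units are mol/L and seconds; the API accepts mg/L and minutes and
converts once at the boundary (molar masses: PCT 151.16, H₂O₂ 34.01,
Fe 55.85 g/mol — IUPAC 2021; the ~0.1% gap between the computed 25.43 and
the nominal 25.40 mg C/L TOC equivalent of 40 mg/L PCT reflects rounding
in whatever masses were used for the nominal value, hence the 0.2%
comparison tolerance on stoichiometric quantities). Iron is dosed as
FeSO₄·7H₂O, so all iron starts ferrous (configurable).

The system is stiff: at the published constants the initial Fenton
transient consumes Fe²⁺ within seconds, after which Fe²⁺ sits at the
quasi-steady level k₃C_Fe³⁺/k₁ and the dynamics are governed by the
Fenton-like rate γ. The default integrator is scipy's BDF with an analytic
Jacobian (the Jacobian of the clipped rate laws, with zero columns for
clipped components; the Fe³⁺ row is exactly the negative of the Fe²⁺ row,
so total iron is conserved to solver precision), rtol 1e-8, atol 1e-13 M.
LSODA is faster on most runs but was observed to collapse its step size
without erroring after reagent exhaustion under the table coupling at some
parameter values, so BDF is the default; the method is selectable.
Solutions are clipped at zero on output; undershoot beyond 1e-5 of the
largest initial concentration is treated as a solver defect and raised.
No log-transform of the state is used, preserving exact iron conservation.

## Synthetic campaign

The generator emulates the 18-run factorial study design: PCT fixed at
40 mg/L; H₂O₂ at 94.5/189/378 mg/L (half, one and two times the 21:1
mineralization stoichiometry dose of 189 mg/L); Fe²⁺ at 5/7.5/10 mg/L
(upper bound: the Spanish wastewater discharge limit); dark and irradiated
blocks; 120 min runs. Species are sampled on their instrument schedules
(PCT by HPLC at 0, 1.5, 2.5, 5, 7.5, 10, 15 min; H₂O₂ and iron every
5 min to 30 min, then every 15 min) and corrupted with independent
Gaussian noise at the instrument standard errors (PCT 0.15, H₂O₂
1.43 mg/L), truncated at zero as instruments report near-zero readings.
The truncation biases means near zero; tests of noise centring therefore
restrict to samples > 5 sd from zero. Iron measurement error was not
characterized on the bench; the default 0.05 mg/L is an assumption.
Optional TOC series are the carbon equivalent of the PCT trajectory only,
carry a `model_backed=False` flag, and must never enter fitting — the
model tracks no intermediates and real TOC decays far more slowly than
the parent compound.

What passing tests on this generator do not show: robustness to drift,
autocorrelated errors, pH/temperature excursions, or model misspecification
— the generator draws from the fitted model itself plus white noise.

## Estimation

Residuals stack (observed − predicted)/C⁰ for every PCT and H₂O₂
observation across all runs in deterministic (run, species, time) order;
iron and TOC series are excluded. No weighting beyond the per-run
normalization by initial concentration is applied by default. Optimization
is Levenberg–Marquardt over log-transformed free parameters (positivity
without constraints), stopping tolerances 1e-8. k₄ is fixed by default at
its literature-anchored value because of the k₄/k₅ ratio degeneracy; the
fixing is explicit and configurable, and a fit with both free documents
the degeneracy (identical objective under joint rescaling). A fit whose
Jacobian is numerically zero (e.g. a catalyst-free dataset) is flagged
non-identifiable rather than reported as converged. During a fit,
parameter excursions that break the integrator return a uniformly large
residual vector, steering the optimizer back without aborting.

Identifiability under noise, as measured on the synthetic campaign:
k₅ and k₃ are recovered to a few percent at the instrument noise levels,
but k₁ is bounded from below only — its influence ends with the initial
Fenton transient (~1–3 s), well before the first nonzero sampling instant,
and afterwards the Fenton flux equals γ independently of k₁. The noisy
k₁-recovery check in the acceptance suite is expected to fail for this
structural reason; the noiseless round trip recovers all free constants to
better than 0.1% because the objective minimum sits exactly at the
generating values.

## Problem sizes and tolerances used by the test suite

The suite runs the full 18-run campaign for the noiseless round trip, 20
noise seeds for the noisy recovery study (stopping tolerance 1e-6,
simulation rtol 1e-6, ≤ 30 objective evaluations per fit — ample for the
~15 LM evaluations a converged fit takes), a 600 000-step RK4 fixed-step
oracle over a 10-min horizon at slowed-down constants for the stiff-solver
cross-check, and a 2-million-point midpoint rule as the quadrature oracle
for the local LVRPA integral.
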