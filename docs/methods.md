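# Methods

## Model and assumptions

The package treats blood in a straight cylindrical vessel as a single
inhomogeneous Newtonian fluid in steady laminar flow. Red cells and
plasma move with the same velocity (diffusive slip neglected — valid when
the vessel cross-section is much larger than a red cell), and the
hematocrit takes a step profile: a cell-rich core of uniform relative
viscosity η_c > 1 and a cell-poor marginal annulus of viscosity
η_A = 1 + α(η_c − 1) with 0 ≤ α ≤ 1. Three parameters carry all the
physics:

| parameter | meaning | units | default / range |
|---|---|---|---|
| η_c | core (bulk) relative viscosity; the large-diameter limit of η_app | — | fitting bounds (1.001, 10] |
| α | marginal viscosity fraction; α = 0 is a pure-plasma (Haynes) layer | — | 0.1; fitting bounds [0, 0.15] |
| a\* | red-cell exclusion half-thickness, the inlet marginal gap | μm | 1.2 (human, bounds [1.0, 1.5]); ~0.8 for rat |
| η_p\* | optional plasma viscosity scale for dimensional output | mPa·s | unset |

The inlet core radius is fixed by size exclusion, s₀ = 1 − 2a\*/D\*. The
asymptotic core radius s_∞ follows from equating the inlet core flux
(plug flow through radius s₀) with the core flux of the developed
two-region Poiseuille profile; that condition is a quartic in s_∞ with a
single admissible root, implemented in closed form and cross-checked by
an independent bisection solver. The apparent relative viscosity is the
viscosity of the homogeneous Poiseuille flow with the same discharge and
pressure gradient,
η_app = [s_∞⁴(1/η_c − 1/η_A) + 1/η_A]⁻¹.

η_c may be given directly or estimated from discharge hematocrit through
the Charm–Kurland correlation (constant 1107/310 kept as an exact
rational — it is 1107/T at body temperature T = 310 K); the
hematocrit route is recorded in the result metadata. The Pries and
Secomb empirical laws are provided for comparison, not used by the
model.

## Validity limits and guards

- **Continuum threshold.** Below D\* = 30 μm the tube is only a few cell
  sizes wide and the continuum step-profile picture is marginal; the
  model still evaluates but emits a `ContinuumValidityWarning`. The
  threshold is configurable and never fatal — there is no sharp physical
  cutoff.
- **Geometry.** D\* ≤ 2a\* leaves no room for a core and is a hard error.
- **Hematocrit guard.** The Charm–Kurland bracket 1 − ϕ·f(ϕ) crosses
  zero near ϕ ≈ 0.78 (a divergent packed-cell limit); the domain is
  capped at ϕ < 0.7, which keeps a safety margin while admitting the
  highest hematocrits used in practice (~0.66).
- **Inverse FL effect.** Capillary-scale tubes, where apparent viscosity
  rises again, are out of scope, as are entrance-region dynamics
  (only the developed asymptotic state is computed), shear-thinning of
  η_c, cell deformability and glycocalyx interactions.

## Numerical choices

- The closed-form s_∞ is the production path. The quartic bisection
  (`core_radius_numeric`, tolerance 1e−14 on s_∞²) and a
  first-principles quadrature route to η_app
  (`apparent_viscosity_poiseuille_oracle`: integrate the shear-stress
  balance dv/dr = −τ/η(r), integrate the flux, match a homogeneous
  Poiseuille discharge) are kept as independent oracles; the test suite
  requires mutual agreement to 1e−10 (radii) and 1e−8 relative
  (viscosities).
- Approach to the bulk limit is slow: η_c − η_app = O(√(a\*/D\*)), so
  even at D\* = 10⁶ μm the gap is ~10⁻² for typical parameters. Limit
  tests therefore check monotone convergence out to D\* = 10¹⁰ μm.
- The Pries/Secomb hematocrit ratio ((1−ϕ)^c − 1)/(0.55^c − 1) is
  continuously extended by its l'Hôpital limit ln(1−ϕ)/ln 0.55 where the
  shape exponent c(d) crosses zero (d ≈ 8.1 μm, |c| < 1e−8 branch).
- The Charm–Kurland inverse uses bracketed Brent root search on
  [0, 0.7), absolute tolerance 1e−10; uniqueness follows from strict
  monotonicity of the forward law.

## Fitting

Parameters are estimated by minimising the sum of squared **relative**
residuals (pred − obs)/obs — consistent with the multiplicative 10–20 %
errors of tube viscometry — with `scipy.optimize.least_squares`
(trust-region reflective, box bounds) started from a deterministic 3×3×3
interior grid over the bounds. Equal-loss optima are tie-broken by the
lexicographically smallest (η_c, a\*, α), so fits are fully
deterministic. Any parameter subset can be pinned (the usual use: share
a\* across series). Diameters violating D > 2a\* during the search incur
a large finite penalty residual rather than an exception, keeping the
optimizer in-bounds. A fit in which no start converges is reported with
`converged = False`, never as a silent success.

Identifiability in this design is uneven: with diameters of 40–600 μm,
η_app depends on a\* and α only through the thin marginal layer, so a\*
and α are weakly determined at realistic noise and often land on their
physical bounds, while η_c is well determined. The recovery harness
(`recovery_experiment`) quantifies this as per-parameter bias and RMSE
over seeded replicates.

## Synthetic data

`generate_dataset` emulates in-vitro viscosity–diameter series: the
exact model curve times (1 + ε), ε i.i.d. Gaussian with relative
standard deviation `rel_noise_sd` (default 0.10, the lower end of the
documented 10–20 % experimental errors), truncated at ±3 sd so that
observations stay physical. One integer seed fully determines a dataset
(numpy `default_rng`, PCG64; truncation via `scipy.stats.truncnorm`).
What the generator does **not** emulate: diameter-dependent error
magnitude, serial correlation between tubes from a shared blood sample,
hematocrit drift between runs, and digitisation error in historical
datasets — so recovery results bound performance under idealized noise
only. Problem sizes used in the tests (10–40 diameters per dataset,
6–16 replicates per recovery experiment) were chosen as typical of the
in-vitro series the model targets while keeping the suite quick.

Packaged fixtures (`fixture(...)`) transcribe published measurement
configurations: marginal-layer thicknesses in 30 μm tubes across
hematocrits 0.08–0.45 (human), cell-poor layer thicknesses in 30–72 μm
tubes (rat, a\* = 0.8 μm), fitted parameter sets for adult and infant
blood at three hematocrits, and the reference curve configuration
(η_c = 3.3, a\* = 1.2 μm, α ∈ {0.05, 0.1, 0.15}). The published
per-configuration thickness digits are carried as data
(`thickness_printed_um`) but are not asserted exactly: recomputing them
from the stated inputs gives values offset in the last digits (e.g.
≈3.2 μm vs printed 2.7 μm at ϕ = 0.08, D = 30 μm), and the rounding
conventions behind the printed digits are not recoverable. Tests assert
instead the robust behavior: thickness in the measured 2–3.5 μm range,
decreasing with η_c, increasing with D\*. For the same reason two of the
six published Charm–Kurland worked values (ϕ = 0.30 → 1.61 and
ϕ = 0.41 → 1.90) are **not** reproduced by the exact formula, which
gives 1.61503 and 1.90553 (rounding to 1.62 and 1.91); they match only
if the temperature constant is pre-truncated to 3.57. The package keeps
the exact constant and the corresponding two checks in the acceptance
test are expected to fail, documenting the discrepancy rather than
hiding it.

Historical 1931 viscosity series exist only as figures in the secondary
literature and are deliberately not bundled as numbers; users supply
their own digitisations as CSV.

## Design choices that were genuinely open

- **Loss on relative residuals** (not absolute): variance stabilization
  matching the stated multiplicative error structure.
- **Deterministic multistart local least squares** rather than a global
  optimizer: the 3-parameter surface is only mildly nonconvex, and
  reproducibility was prioritised.
- **Noise distribution**: only an error *magnitude* (10–20 %) is
  documented for the target data; truncated Gaussian multiplicative
  noise is the simplest model consistent with it.
- **Thickness definition**: the reported layer is the asymptotic
  R\*(1 − s_∞), not the inlet gap a\* — it is the quantity measured in
  the layer-thickness experiments the model is compared against.
- **CLI**: subcommands `predict`, `curve`, `compare`, `fit`, `simulate`;
  flags > TOML config > defaults, resolved config logged per run; CSVs
  written with 12 significant digits so identical invocations are
  byte-identical; plots are advisory (`--plot`), CSVs authoritative.
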