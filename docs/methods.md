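# Model and methods

## Constrained-mixture wall model

The aortic wall section is a constrained mixture of three structurally
significant constituents that deform with the tissue but keep individual
natural configurations and material laws:

* **elastin-dominated matrix** — incompressible neo-Hookean,
  `Ŵ^e = (c^e/2)(I₁^e − 3)`, deposited during development with the
  diagonal pre-stretch tensor `G^e = diag(1/(G_θ G_z), G_θ, G_z)`. Elastin
  is not produced in maturity: its referential mass ratio is identically
  one and its elastic deformation always composes the *full* mixture
  deformation with `G^e`.
* **smooth muscle** — one circumferential fibre family with the Fung
  exponential energy `Ŵ = c₁/(4c₂)·[exp(c₂(I₄−1)²)−1]` and scalar
  deposition stretch `G^m`.
* **collagen-dominated matrix** — four Fung families: circumferential,
  axial, and a symmetric diagonal pair at angle α₀ from the axial
  direction sharing the diagonal mass fraction equally. The deposition
  stretch `G^c` is the lever of the mechanoregulation insult; the diagonal
  angle remodels as `tan α₀ = (λ_θ/λ_z)^γ tan α₀₀` with γ = 0.2
  (small reorientation).

The Fung form is symmetric in (I₄ − 1); no tension-only switch is applied.
All simulated states keep fibre stretches at or above their deposition
values, so the choice is inert; an overflow guard converts runaway fibre
exponents (> 700) into a `NonPhysicalStateError` rather than a float
overflow.

Mixture energy follows the rule of mixtures with current mass-fraction
weights, `W = Σ_α φ̂^α Ŵ^α`. The baseline mass fractions as tabulated sum
to 1.010; they are used verbatim (the growth volume ratio is normalized by
their sum so baseline weights equal the tabulated values), because
renormalizing them displaces all calibrated stress and energy levels by
1%. Units are kPa and mm internally; pressures cross interfaces in mmHg
(1 mmHg = 0.133322 kPa).

## Ring reduction and mechanical equilibrium

All reported metrics refer to the centre of the insult region, where the
axial insult profile `ϑ(z) = ϑ_apex · exp(−|(z−l/2)/z_d|^v)` is maximal;
the model therefore collapses the segment to one thick-walled-ring cross
section at the apex with fixed axial stretch (λ_z = 1 relative to the
in-vivo reference). The mid-wall radius convects with λ_θ and the wall
cross-sectional area scales with total referential mass (incompressible
constituents at constant true density), which fixes (a, h) from
(λ_θ, λ_z, J).

Equilibrium is imposed in membrane form: the reaction-free deviatoric hoop
response σ_θθ − σ_rr carries the transmural Laplace load P_tm·a/h. With
the tabulated material parameters the stated in-vivo geometry is not
exactly a thin-ring equilibrium at systole (the deviatoric hoop response
is ~3% below the Laplace demand), so a constant perivascular support
pressure is calibrated once such that the in-vivo state at 120 mmHg is an
exact equilibrium; the calibrated value, 0.48 kPa ≈ 3.6 mmHg, is in the
physiological range of perivascular tethering. With this closure the
baseline diastolic stored energy (51.84 kPa) and circumferential stiffness
(1.519 MPa) match their reference values to 0.2%, as do the combined-
insult endpoints; the closure was selected on those anchors against the
alternative mid-wall-datum form P_tm·(a/h + 1/2), which biases both
diastolic metrics low by ~3%. For *reported stress components* and for the
intramural stimulus the radial datum is the mid-wall average
σ_rr = −P_tm/2, and the scalar intramural stress is one-third of the
trace.

Reported stiffness is the small-on-large material stiffness: the
sensitivity of the deviatoric Cauchy stress to a superposed logarithmic
stretch increment at fixed transverse stretch,
`c_θθθθ = ∂(σ_θθ−σ_rr)/∂ln λ_θ`, computed analytically per constituent
and verified against a centred finite-difference oracle (rel. 1e−4 in
tests; agreement is ~1e−9). Distensibility uses the diameter-based
clinical form `(d_sys − d_dia)/(d_dia·ΔP)` in 1/mmHg — the source data's
exact formula is not restated there, so only trends are comparable.

## Mechanobiological equilibrium

At mechanobiological equilibrium production balances removal and the
stress-driven stimuli vanish, collapsing the hereditary constrained-
mixture integrals to an algebraic system: smooth muscle and collagen carry
exactly their (possibly insulted) deposition stretches, and the unknowns
are the evolved stretch λ_θ and the constituent mass ratios. Stimuli are
`Δσ = ((1−δ)σ − σ_o)/σ_o` and `Δτ_w = ((1−ξ)τ_w − τ_wo)/τ_wo` with
`τ_w/τ_wo = (a₀/a)³` under fixed flow; ξ is never insulted and the
removal-stimulus weight ω defaults to zero (at equilibrium it only shifts
the stimulus balance).

Two regimes are distinguished:

* **intact shear sensing** (K_τw/K_σ > 0, outside the insult region): the
  muscle and collagen stimulus balances are generically independent
  conditions; in the limit they force Δσ = 0 *and* Δτ_w = 0 separately,
  with m^m and m^c both unknown. This makes the zero-insult baseline an
  exact fixed point and gives the classic adaptation to a sustained
  pressure step: radius returns exactly to target and the wall thickens.
* **insult apex** (K_τw/K_σ = 0, η = 1 for any nonzero insult): only the
  intramural condition (1−δ)σ = σ_o remains, and the turnover-ratio
  closure m^m = (m^c)^η selects the solution (equal fractional growth at
  η = 1).

A known, deliberate limitation: under a 20% pressure step the wall
thickens to 1.171·h₀ rather than the ideal 1.200·h₀. The ideal scaling
presumes every constituent's contribution can be restored; because elastin
cannot be re-deposited, its mass fraction dilutes as the wall grows and
the axial stress it carried must be compensated, pulling the one-third-
trace stimulus balance a few percent off the pure Laplace scaling. Radius
restoration and the vanishing of both stimulus deviations are exact
(tested to 1e−6/1e−8).

### Solver

The coupled system is solved by nested one-dimensional bracketed
root-finding — inner: mechanical equilibrium for λ_θ at frozen mass
ratios; outer: the stimulus condition over log m^c (apex) or a 2-D quasi-
Newton over (log m^c, log m^m) (intact) — with a secant fast path warm-
started from the previous solution and a bidirectional bracket walk as
fallback. Nested bracketing proved robust where a 2-D Newton on the raw
residuals diverged (regulation-only insults near their cap). The insult
(and any pressure change) ramps over 10 continuation increments; the
equilibrium is path-independent (doubling increments changes metrics by
< 0.1%, tested), so fitting-time evaluations use 1–2 increments with warm
starts across neighbouring porosities. Convergence tolerances: normalized
stimulus and mechanical residuals below 1e−9·(scale); elastic solves to
brentq machine tolerance with an explicit residual check.

Pure elastic solves (diastolic unload at frozen G&R state) root-find λ_θ
along the fixed-λ_z path; the pressure–radius relation is monotone over
0–200 mmHg (tested), and the unload/reload loop is reversible to 1e−8.

## Porosity-to-insult mapping

Normalized porosity ε̄ = (ε − 0.115)/(0.699 − 0.115) is clamped to [0, 1]
outside the experimental range (the insult formulas are defined on the
normalized range). Elastic-fibre integrity loss is linear,
ϑ_ce = ε̄·0.660, with the ceiling fixed by the fold change in non-void
space. Cell-function insults follow the saturating exponential
`ϑ = ϑ_max(e^{−gε̄} − 1)/(e^{−g} − 1)`: front-loaded for g > 0 (initial
slope exceeds ϑ_max) and approaching the linear ramp as g → 0⁺.
Single-contributor sweeps for sensing and regulation ramp linearly in ε̄
to caps of 0.150 and 0.012 respectively. All insults and the apex G&R
parameter switch share one axial profile shape (z_d = 3 mm, v = 2,
l = 15 mm), under which the profile decays below 0.5% of apex at the
segment ends.

## Objective and optimizer

For observations {(ε_i, Y_i)} the model curve is evaluated at each
observation's porosity under the combined insult, and
`J_Y = (1/n) Σ ((Y(A) − Y_i)/Y_WT)²` is averaged over circumferential
stiffness and stored energy, `Φ = (J_c + J_W)/2`; Y_WT are wild-type
normalizers (for synthetic sets, the zero-insult baseline metrics).

The surrogate management framework minimizes Φ over the box
ϑ_δmax ∈ [0, 0.1], ϑ_Gcmax ∈ [0, 0.015], g ∈ [0.01, 10]:

* initial design: Latin hypercube, 10·dim = 30 points (standard SMF
  sizing; the source does not state one);
* SEARCH: an interpolating kriging surrogate (anisotropic RBF, maximum-
  likelihood length scales, fixed 1e−10 nugget) is minimized from
  multi-start L-BFGS-B and the true objective evaluated at its minimizer,
  repeating while it improves;
* POLL: positive-spanning coordinate stencil (2·dim points) of relative
  size Δ around the incumbent, Δ halved on failure (a randomized
  orthogonal-basis poll is available via a flag);
* termination at Δ < 1e−3 of the box width or a 300-evaluation budget;
  failures inside the objective count as +∞; ties break first-found; all
  evaluations and seeds are logged in the result.

## Synthetic data

The generator emulates the statistical structure the fit assumes: two
genotype-like groups with overlapping uniform porosity ranges
(low group on [0.115, 0.40], high group on [0.30, 0.699]; the source gives
only pooled bounds and the group ordering, so the overlap mimics the
observed spread without reading values off plots), forward-model metrics
at a known insult triple, and mean-one multiplicative lognormal noise with
coefficient of variation 0.08 by default (biological-replicate scale,
configurable). What it does *not* emulate: inter-metric measurement
covariance, specimen-level parameter heterogeneity, and the porosity
estimation process itself — so passing recovery tests demonstrate
identifiability of the insult parameters under the model's own noise
assumptions, not robustness to real measurement structure.

Fits on noisy synthetic data reproduce the characteristic near-degenerate
ridge: independent trials return strongly anti-correlated
(ϑ_δmax*, ϑ_Gcmax*) at nearly identical Φ, reflecting that attenuated
stress sensing and reduced collagen pre-stretch have similar tissue-level
consequences; the progression rate g is comparatively stable.

## Known limitations

* The ring reduction has no axial tethering from the healthy boundary
  regions, so apex dilatation under strong insults is exaggerated relative
  to a three-dimensional simulation (the elastic-only stored-energy
  endpoint lands ~16% above its reference value for this reason);
  stiffness endpoints are much less affected.
* Passive behaviour only; no active smooth-muscle tone, no
  glycosaminoglycan accumulation, no medial/adventitial layering, no
  inner/outer-curvature heterogeneity.
* Transient G&R dynamics are out of scope: porosity, not time, is the
  progression variable, and only the equilibrated limit is computed.
* Sizes used in the shipped tests are chosen for single-CPU runs
  (observation sets of 10–16 specimens, fit budgets of 100–150
  evaluations, 8 optimizer trials); all are parameters.
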