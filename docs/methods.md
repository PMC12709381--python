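# Methods

`sfbkit` models, simulates and analyses surface force balance (SFB)
force–distance measurements between like-charged surfaces (mica) across
aqueous proline/KCl solutions. This note records the model, the numerical
choices, and what the synthetic-data experiments do and do not establish.

## Interaction model

The parallel-plate interaction free energy per unit area is

    W(D) = -A / (12 π D²)
           + 2 ε₀ ε_e κ ψ_eff² e^(-κD) / (1 + (1 - 2p) e^(-κD)),

with Hamaker constant `A` (J), electrolyte relative permittivity `ε_e`,
inverse Debye length `κ` (1/m), effective surface potential `ψ_eff` (V,
stored as a magnitude; the surfaces are negatively charged) and the
constant-regulation parameter `p ∈ [0, 1]`: `p = 0` is the
constant-potential boundary condition, `p = 1` constant charge. Repulsion
is positive. The measured force between crossed cylinders of radius `R`
maps to `W` through the Derjaguin relation `F(D) = 2πR·W(D)`, valid for
`R/D > 10³` (enforced by the simulator).

Defaults, with units and rationale:

| parameter | default | why |
|---|---|---|
| temperature | 298.15 K | standard laboratory conditions; configurable |
| ε_e (water) | 78.3 | fixed constant at 298.15 K, no T-correlation (see Non-goals) |
| A (mica–water–mica) | 2.2 × 10⁻²⁰ J | literature value; always configurable, logged in run headers |
| k_N (normal spring) | 150 N/m | representative SFB spring; configurable |
| R (lens radius) | 10 mm | crossed-cylinder lens scale |
| drive step | 0.05 nm | resolves 0.3–0.5 nm squeeze-out steps against the 3-step jump threshold |

### Electrolyte layer

Compositions are molal (mol per kg water). The molality→molarity bridge
assumes the solution volume equals the water volume at the pure-water
density (Kell correlation); species with a declared partial molar volume
add `n·V̄`. Zwitterions (valence 0) carry no ionic strength; proline-only
solutions therefore have *no predicted screening length* and
`debye_length` refuses them explicitly — κ is then a free fit parameter.
Species may carry a linear dielectric increment (per mol/L); proline's
default is 0 because no increment is established here, which means the
predicted screening length of a proline/KCl mixture is that of the KCl
alone. Osmotic pressure is the ideal van't Hoff estimate `Π = RT Σcᵢ`
(each ion counted once; no activity corrections).

Reported tables round to two significant figures, half away from zero. A
consequence worth stating: the closed-form prediction for 0.01 m KCl is
κ⁻¹ = 3.04 nm, which this convention reports as 3.0 nm.

### Charge regulation and the PB oracle

Eq. (1)-style constant regulation is an approximation to the full
Poisson–Boltzmann (PB) problem. `sfbkit.pb` solves the nonlinear PB
equation for two identical plates in a 1:1 electrolyte on the symmetry
half-domain (second-order finite differences, damped Newton, grid doubled
until the disjoining pressure moves < 0.1 %), with a *linear regulation*
wall closure `σ(ψ_s) = σ_∞ + C_inner(ψ_∞ − ψ_s)`. The mapping
`p = C_D/(C_D + C_inner)`, `C_D = ε₀ε_eκ`, identifies the two
descriptions: `C_inner = 0` is constant charge, `C_inner → ∞` constant
potential. Disjoining pressure is the midplane osmotic excess
`P = 2c₀N_Ak_BT(cosh(eψ_m/k_BT) − 1)`; the wall evaluation (osmotic minus
Maxwell stress) is exposed as a contact-value-theorem cross-check. Energy
follows from `W(D) = ∫_D^∞ P dD'` (trapezoid on a ≤ 0.15 κ⁻¹ grid,
integrated from 14 κ⁻¹ inward). In the weak-overlap comparison the
closed form is evaluated at the *effective* potential of the isolated
surface, `ψ_eff = (4k_BT/e) tanh(eψ₀/4k_BT)` — the amplitude the far field
actually carries. With that mapping the numerical energy agrees with the
closed form to better than 2 % for κD ≥ 3 and ψ₀ ≤ 25 mV, comfortably
inside the 5 % validation band; the closed form is the fitting model, the
PB solver only its oracle.

## Synthetic measurements

### What the simulator emulates

A quasi-static SFB: a drive advances the spring base in fixed steps; the
recorded separation at each step is a mechanically stable equilibrium of
`k_N(D − x_d) = F(D)`, stability requiring `dF/dD < k_N`. When a branch
loses stability the system lands on the nearest stable branch reachable in
the drive direction. This one mechanism produces jump-in, squeeze-out
steps and adhesive jump-out; no discontinuity is drawn by hand. The
equilibrium is tracked by a damped Newton iteration from the previous
state, with a global re-bracketing on a dense geometric grid (9000 nodes)
whenever the local step fails or moves more than five drive steps — that
is where jumps are resolved, by bisection to 10⁻¹⁴ m.

Short-range structure is an exponentially decaying oscillation (period =
layer thickness, envelope = decay length) on a steep `(D₀/D)¹²` wall; a
wall always backs the profile so a contact branch exists. When a pull-off
energy is prescribed, the wall stiffness is calibrated by a 1-D root find
so the contact minimum of the composed profile equals it exactly.
Measurement noise is i.i.d. Gaussian on the energy signal, seeded;
the mechanics themselves are noise-free.

### What it does not emulate

No interferometric fringe simulation, thermal drift, hydrodynamic
drainage, or dynamic (inertial) jump trajectories; approach and
retraction are strictly quasi-static. Real curves also carry distance-
offset uncertainty and slow force drifts that the idealized generator
omits — the `offset` fit parameter exists for real data but is off for
synthetic work. Passing recovery tests therefore demonstrates estimator
correctness and calibration under the stated noise model, not robustness
to every instrumental artefact.

### Known bias of the squeeze-out step reading

Because the spring is four orders of magnitude softer than the structural
force gradients, each branch is ridden essentially to its energy crest,
and a squeeze-out cascade can traverse several layers when inner crests
sit lower than the outermost one (the van der Waals divergence lowers
them). Under the 0.90 m proline conditions with a 0.5 nm layer
(amplitude 1 mJ/m², decay 0.4 nm) only the outermost layer branch is
visited and the measured crest spacing is ≈ 0.45 nm — compressed ~10 %
below the injected period by the DLVO barrier next to it. This is a
property of the mechanics under those conditions, not of the detector: in
a well-developed layering regime (envelope ≳ 1.5 periods long) the
detector recovers the period to ≈ 1 % across 0.2–1.0 nm, which is how the
thickness-sweep test is configured. A "layering" whose envelope dies
within half a period produces no squeeze-out sequence at all and is
treated as unobservable rather than as an estimator failure.

## Fitting

Weighted nonlinear least squares of the interaction model over a user
window (≥ 10 samples; the window must exclude the post-jump contact
region, and for structured profiles should start outside the layering
zone — residual RMS grows strictly as the window slides into it).
Internally `ψ_eff`, `κ` and `A` are fitted in log space and `p` through
the smooth bijection `p = (1 + sin q)/2`, so the optimizer
(Levenberg–Marquardt, tolerances 10⁻¹⁵) is unconstrained. A three-point
multi-start over `p ∈ {0.1, 0.5, 0.9}` avoids shallow local minima;
ties are broken toward the smallest `p`. Estimates within 10⁻³ of 0 or 1
are reported at the boundary (hence "1.0 ± 0.0" rows). Uncertainties are
1σ from the Jacobian covariance by default, or from a seeded residual
bootstrap on request — both are offered because run-to-run spreads and
fit covariances answer different questions.

Noiseless closed loops (simulate → fit) recover all six reference
parameter sets to machine precision, and 50-replicate noisy experiments
at σ = 0.005 mJ/m² are calibrated: the bias of the mean recovered
`ψ_eff`, `κ⁻¹` and `p` stays below the mean reported 1σ.

## Feature extraction

A jump is a maximal run of consecutive samples whose separation changes by
more than three drive steps in the direction of motion; runs are merged
because the soft spring produces a square-root creep of growing steps just
before an instability, and the event position is taken at the largest
single step of the run. Squeeze-out step heights are differences between
start separations of consecutive inward jumps in the near-contact region
(each jump start is the compressed limit of a hard-wall branch); the raw
jump span is not used because the landing phase depends on the growing
envelope and systematically under-reads the period. Adhesion is the most
negative energy recorded just before the outward jump on retraction; a
retraction without jump-out reports "no adhesion", which is distinct
from zero.

## Recovery experiments behind the headline numbers

* Low-proline experiment (0.07 m row: ψ_eff = 63 mV, κ⁻¹ = 40 nm,
  p = 0.90): 50 curves, D = 5–150 nm (300 points), σ = 0.005 mJ/m²,
  seeds `base…base+49`, window 5–120 nm, `ψ_eff, κ, p` free, A fixed.
* Mixture experiment (0.46 m proline + 0.01 m KCl row: ψ_eff = 49 mV,
  κ⁻¹ = 3.0 nm, p = 0.61): 50 curves, D = 1.5–25 nm (300 points),
  σ = 0.005 mJ/m², window 1.5–20 nm.
* Step experiment (0.90 m row plus 0.5 nm layering as above): one
  noiseless quasi-static approach; reported value is the median detected
  step height.

These sizes keep the whole acceptance run to a few seconds while the
replicate means are stable to well under the reference uncertainties.

## Limitations

Symmetric 1:1 electrolytes only (PB solver and full Grahame variant);
no activity coefficients, dielectric saturation or temperature-dependent
permittivity; no retarded van der Waals or asymmetric surfaces; the
structural force is phenomenological (decaying cosine + power wall), not
derived from liquid-state theory; fitted structural parameters are
detected, never co-fitted with the DLVO terms.
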