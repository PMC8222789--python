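# Methods

## Physical model

A two-dimensional slice of a thin-film bioreactor is modelled as two
stacked strips on (x, z) ∈ [0, L] × [0, h_M]: a hydrogel layer
(0 < z < h_H) seeded uniformly with N0 cells per unit area, and a media
layer (h_H < z < h_M) in slow pressure-driven flow with a free surface, so
the velocity is the half-Poiseuille profile u(z) = [u]·(z−h_H)²/(h_M−h_H)²
with no slip at the interface and maximum [u] at the surface. There is no
flow in the hydrogel.

Glucose (c) and lactate (w) diffuse in both layers; in the hydrogel the
cells consume glucose at rate ν_C·c per unit cell density and produce two
lactate molecules per glucose (glycolysis), with the cell density growing
exponentially, n(t) = N0·e^{pt}, independent of the metabolite field. The
layers are coupled by continuity of concentration and of diffusive flux at
z = h_H. Walls and the free surface are no-flux; the inlet carries a Robin
(total-flux) condition with the reservoir concentration (glucose) or zero
(lactate); the outlet is purely advective (zero diffusive flux). Initially
the media holds reservoir-strength glucose, the hydrogel none, and there is
no lactate.

Assumptions worth keeping in mind: growth is not limited by glucose or
lactate (so a harsh environment does not slow the cells — the model
overestimates late-time consumption for stressed lines); uptake is linear
in concentration (no Michaelis–Menten saturation); organoids are a
continuum bulk sink, not discrete spheroids; oxygen is assumed abundant.

## Non-dimensionalisation and scales

X = x/L, Z = z/(εL) with ε = h_M/L = 1/30, T = t/[t] with [t] = 1 day
(the growth timescale — the scale on which operating decisions act), and
concentrations scaled on the reservoir glucose c_∞. The groups are
μ = [u][t]/L (flow), ρ = [t]ν_C N0 (uptake), P = p[t] (proliferation),
d_i = [t]D_i/L² (horizontal diffusion), H_H = h_H/h_M, and the tolerated
lactate level W_tol = 0.7. At typical values the process timescales split
three ways — vertical diffusion: hours; flow, uptake, production,
proliferation: about a day; horizontal diffusion: months — which makes the
system stiff and licenses both reductions below.

The default seeding density is chosen so that ρ = 0.27, the midpoint
"standard" organoid line; the printed seeding bounds (2.7 and 4 × 10¹⁰
cells/m², giving ρ = 0.22–0.32) are exposed as constants. The reservoir
concentration is stored in its published areal form (0.36 mol/m²) and
never converted: all solvers are dimensionless, so it affects reporting
only. The glycolytic yield is an explicit field (default 2) rather than a
hard-coded factor.

## Longwave reduction

For ε → 0 with all other groups O(1), vertical diffusion equilibrates the
layers instantly on the day timescale, the leading-order fields are
Z-independent, and a solvability condition at O(ε²) gives the
depth-averaged system

    α C_T + β C_X = δ_C C_XX − γ C e^{PT},
    α W_T + β W_X = δ_W W_XX + 2 γ C e^{PT},

with θ = H_H/(1−H_H), α = 1+θ, β = μ·Ū (Ū = 1/3 is the exact
depth-average of the half-Poiseuille profile), γ = θρ,
δ_C = d_CM + θ·d_CH, δ_W likewise. The "initial" data C = 1/α, W = 0 are
matching conditions with the unresolved early (hour-scale) transient and
are deliberately discontinuous against the inlet data at (X, T) = (0, 0);
no smoothing is applied by default.

## Sublimit and closed forms

Sending δ_C, δ_W → 0 (horizontal diffusion is the month-scale process)
leaves a hyperbolic pair solved along characteristics dX/dT = β/α. The
solution is piecewise across the dividing characteristic αX = βT:

* unreplenished region (βT < αX): C = (1/α)·exp(−(γ/α)·(e^{PT}−1)/P),
  spatially uniform; W = (2/α)(1 − αC).
* replenished region (αX < βT): C = exp(−(γ/α)·e^{P(T−αX/β)}·(e^{PαX/β}−1)/P);
  W = 2(1 − C).

2C + W is conserved along characteristics (2/α and 2 respectively). The
P → 0 case is the analytic limit (e^{Px}−1)/P → x, implemented exactly via
`expm1` rather than by small-P thresholding, so non-proliferating lines are
first-class inputs. On the dividing characteristic the replenished-branch
value is returned, since the inlet information is what physically arrives
there. The weak outlet boundary layer that would reimpose the X = 1
condition is not resolved; the closed forms are used up to X = 1. The
metabolite transit time T* = α/β (≈ 4.69 days at defaults) is when the
characteristic exits the domain.

## Discretisation

Both PDE solvers use conservative finite volumes and the method of lines
with scipy's BDF integrator and an analytic Jacobian sparsity pattern.

* **Advection.** Faces take the upwind cell value plus a van Leer-limited
  MUSCL correction (default), or plain first-order upwind via the
  `scheme="upwind"` switch. The limited scheme is second order where the
  solution is smooth and oscillation-free across the inlet/initial
  discontinuity. The longwave solver uses the identical scheme so that
  cross-model comparisons isolate model error, not scheme error.
* **2D grid.** Tensor product with the interface always on a Z face
  (`NZ_H` hydrogel and `NZ_M` media cells), so refinement by 2 nests.
  Interface diffusive fluxes use the series resistance of the adjacent
  half-cells (distance-weighted harmonic mean of the layer diffusivities),
  which reproduces flux continuity exactly for piecewise-linear profiles.
  The printed interface condition for glucose carries an obvious
  transcription slip (the same concentration appears on both sides); the
  dimensional statement makes the intent clear and that is what the
  harmonic-mean flux implements.
* **ε handling.** The governing equations carry ε² on the time, advection
  and horizontal-diffusion terms; the solver integrates them divided
  through by ε², i.e. vertical diffusion enters with conductance d/ε²
  (the stiff direction) and everything else with its printed coefficient.
* **Boundary conditions.** Inlet Robin conditions prescribe the total face
  flux directly (μU(Z) per media row for glucose, zero for lactate; the
  hydrogel side walls are no-flux); outlet faces carry the upwind advective
  flux only. This makes the discrete budget exact: d/dT(total) + uptake =
  inflow − outflow holds to rounding at any state, which the tests assert.
* **Tolerances.** Longwave default rtol 1e-8 / atol 1e-10; full 2D default
  rtol 1e-6 / atol 1e-9 with grid 180 × (12 + 24). Save times default to
  steps of 0.05 days (1D) and 0.25 days (2D); metrics are computed post hoc
  from saved fields, so the save resolution bounds metric accuracy.

## Metrics

Spatial and temporal integrals use composite trapezoid on the stored grid.
Finite-volume solutions store cell-centre values; metric evaluation extends
them to X = 0 and X = 1 by constant extrapolation (consistent with the
zero-gradient outlet; at the inlet this underestimates the boundary value
by O(ΔX), negligible at default resolutions). The uninhabitable fraction
locates W = W_tol crossings by inverse linear interpolation between nodes,
so P_U varies continuously instead of snapping to the grid; the turn-off
time interpolates the first crossing of the W_max series and returns
infinity when the tolerance is never reached. Ties in argmax/argmin break
towards the smallest X. The glucose conversion follows the published
definition Q = ∫∫γCe^{PT} dX dT / ((1−H_H)βT), i.e. the supply integral
counts only glucose advected in during the run, not the initial loading —
with the consequence that Q can exceed 1 while the initial store is being
consumed, and that Q varies more strongly with flow rate than it would
under a total-input normalisation.

## Scenario running

Five preset organoid lines span low/high proliferation (P = 1/6, 1) ×
low/high uptake (ρ = 0.027, 2.7) plus the standard line (P = 1/3,
ρ = 0.27). The flow sweep maps each pump velocity through the full
non-dimensionalisation, solves the longwave model, and reports Q(7), T_off
and peak lactate; the "worst" flow rate is the T_off argmin on the sweep
grid refined by a parabola through the three neighbouring points in
log-velocity. Everything is deterministic — there is no randomness in the
model — so reproducibility needs only a fixed configuration.

Problem sizes used by the test suite (full 2D at 120 × (8+16) cells,
longwave at 160–256 cells, 40-point sweeps) were chosen as the coarsest
resolutions that sit comfortably inside the asymptotic convergence regime
verified by the grid-refinement tests.

## Validation and known limitations

The closed forms are cross-checked against an independent
characteristic-ODE oracle and adaptive quadrature; the solvers against
exact steady states, discrete conservation, grid-convergence order and
each other. Two quantitative caveats surfaced by this cross-validation are
worth stating:

* The depth-averaged model tracks the depth-averaged full 2D solution to
  about 1% through mid-run, but the neglected first correction grows like
  ε²ρe^{PT}/d and reaches ~3% of the field scale by day 7 at default
  parameters (halving ε quarters it, as the asymptotics predict). Metric
  series (C_min, W_max, X_max, outlet lactate) agree to within ~3%
  throughout.
* The sublimit approximation is accurate away from a diffusive band around
  the dividing characteristic and systematically overestimates lactate
  after the transit time — a conservative bias, since lactate is the
  quantity one worries about.

The synthetic scenarios are idealised: uniform seeding, constant inlet
concentration, steady flow, growth insensitive to the metabolic
environment. Passing tests therefore demonstrate fidelity to the model,
not to a specific wet-lab run; in particular the exponential-growth
assumption makes late-time predictions for high-uptake lines (which grow
unchecked in a glucose-starved, lactate-saturated domain) upper bounds on
metabolic load rather than forecasts.
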