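# Methods

## Model

`duplexsis` implements a discrete-time SIS (susceptible–infected–susceptible)
process on a two-layer network.  Both layers share one node set of size N;
node *i* in layer A is the counterpart of node *i* in layer B.  Within a
layer, an infected node transmits along each link with probability β₁
(layer A) or β₂ (layer B) per step.  Across layers, an infected counterpart
transmits with probability γ₁ (B→A) or γ₂ (A→B).  Writing p₁ᵢ(t) for the
probability that node *i* is infected in layer A, the synchronous node-level
update is

    p₁ᵢ(t+1) = [1 − p₁ᵢ][1 − q₁ᵢ] + [1 − μ₁] p₁ᵢ + γ₁ p₂ᵢ [1 − p₁ᵢ],
    q₁ᵢ(t)   = ∏ⱼ [1 − β₁ aᵢⱼ p₁ⱼ(t)],

with (aᵢⱼ) the layer-A adjacency matrix, and symmetrically for layer B.
This is the standard microscopic Markov-chain (individual-based mean-field)
approximation of the stochastic process: it neglects dynamical correlations
between neighbours but is exact in expectation for the update rule itself.

The distinguishing ingredient is the recovery law.  Recovery is not a
constant rate: an average resource amount R ∈ [0, 1] (a fraction of total
treatment capacity) is shared among the infected, so the per-step recovery
probability of layer *i* with prevalence ρᵢ(t) = N⁻¹ Σⱼ pᵢⱼ(t) is

    μᵢ(t) = exp(−c ρᵢ(t) / R),

with c > 0 a control coefficient (default 1).  Recovery degrades as the
epidemic grows — the feedback that produces discontinuous transitions.
Two limits need conventions: at R = 0 with ρ > 0 we set μ = 0 (the process
degenerates to SI, no recovery); at ρ = 0 we set μ = 1, the ρ→0 limit at
fixed R > 0, which keeps the disease-free state absorbing.

The three terms of the update are not a partition of one probability
space, so for large γ and high prevalence their sum can exceed 1.  The
implementation clamps each updated entry to [0, 1] and counts clamp events
on the trajectory (`clamp_events`); at the parameter values studied here
clamping is rare and confined to early transients.

## Mean-field reduction

On random-regular layers (uniform degrees k₁, k₂) all nodes are
statistically equivalent, so a uniform initial state stays uniform and the
N probabilities collapse to one prevalence per layer:

    ρ₁(t+1) = (1 − ρ₁)[1 − (1 − β₁ρ₁)^{k₁}] + (1 − μ₁)ρ₁ + γ₁ρ₂(1 − ρ₁),

and symmetrically for ρ₂.  The package treats this two-dimensional map as
the primary engine (it is N-independent and cheap) and the node-level
engine as the general-topology check; on uniform regular systems the two
agree to machine precision (the test suite asserts sup-norm < 1e−12 over
100 steps).

A fixed point (ρ₁*, ρ₂*) satisfies the balance

    (1 − ρ₁)[1 − (1 − β₁ρ₁)^{k₁} + γ₁ρ₂] − ρ₁ e^{−cρ₁/R} = 0,

and its layer-B twin.  Solving the layer-A balance for ρ₂ gives the
inter-layer consistency map ρ₂ = A(ρ₁) (`rho2_of_rho1`); substituting it
into the layer-B balance and dividing by A(ρ₁) yields one scalar equation
in ρ₁ (`scalar_steady_residual`) whose roots are the steady states.  Points
with A(ρ₁) outside (0, 1) are outside the equation's domain (no admissible
layer-B prevalence) and are skipped by the root scan.

Two solvers are deliberately kept separate:

* **dynamical** (`run_mf`, `batch_steady_state`): iterate from a fixed
  initial prevalence (0.1 in both layers unless configured).  This is the
  protocol used for every reported curve, because in bistable regimes the
  attained branch depends on the initial condition — the discontinuities
  live here.
* **algebraic** (`find_roots`): bracket sign changes of the scalar equation
  on a uniform grid over (0, 1) (default 2000 interior points) and refine
  by bisection to 1e−10.  This exposes *all* coexisting branches, including
  the unstable root that separates basins; the test suite cross-checks that
  the largest root equals the attractor reached from high initial
  prevalence and that every root's balance residuals are below 1e−8.

Two non-interior branches require care.  The disease-free root (0, 0) is
appended explicitly.  The saturated corner (1, 1) is a numerical fixed
point at small R: for ρ₁ bounded away from 1 the factor e^{−ρ₁/R}
underflows, A(ρ₁) turns negative, and the true root sits at
1 − ρ₁ ~ e^{−1/R}, far below float resolution.  `find_roots` therefore
tests (1, 1) directly and includes it whenever its balance residuals are
below 1e−8 (equivalently R ≲ 1/18 at c = 1).

### Vanishing-resource reduction

Sending R → 0 formally in the scalar equation (dropping both exponential
factors) collapses it to

    (1 + γ₂ρ₁)^{1/k₂} = 1 + (β₂/γ₁)[1 − (1 − β₁ρ₁)^{k₁}],

implemented as `small_resource_residual` / `small_resource_roots` with
ρ₁ = 0 always a root.  A caution established while validating: this
reduction is a formal limit of the *equation*, not of its root positions.
At the default parameters it has only the trivial root, and the full
scalar equation's nontrivial root at small R scales as ρ₁ ∝ R (the
admissible window of A(ρ₁) itself shrinks like R), so the two root sets
converge to each other as R → 0 — which is what the tests assert, using a
log-spaced scan grid to resolve the O(R) window.  In parameter regimes
where the reduction acquires a nontrivial root (sparse layer B with strong
A→B coupling, e.g. k₂ = 2, γ₂ ≈ 0.27), that root does not continue to a
root of the full equation at small finite R; it should be read as a
balance condition of the formal limit only.

## Fixed-point iteration and acceleration

The plain protocol iterates the map synchronously until the sup-norm step
falls below `tol` (default 1e−9, `max_steps` 1e6).  Near continuous
transitions the map's contraction rate approaches 1 (critical slowing
down) and the plain orbit needs 10⁵–10⁶ iterations.  The batch solver
(`batch_steady_state`, used by sweeps and bisections; `run_mf` never
accelerates) therefore applies safeguarded geometric extrapolation:

* a step-ratio estimate must be stable for three consecutive checks and
  the step below 1e−5 before an extrapolation is attempted — transients,
  in particular the slow passage near a saddle, are never mistaken for
  asymptotic convergence;
* the extrapolated point is accepted only if it reduces the fixed-point
  residual;
* after acceptance the element is monitored: if the step size grows past
  its acceptance level, or the state drifts more than 1e−3 from the
  accepted point, the solver rolls back to the saved plain-orbit state and
  runs plainly for 2000 steps before allowing a new episode.  Rollback
  states always lie on the exact plain orbit, so a misfired extrapolation
  costs time, never correctness beyond the drift budget.

The drift budget bounds the error a wrong-basin extrapolation can leave
behind by ~1e−3; against the plain iteration over 18 sweep configurations
spanning all three transition types the largest deviation observed was
2.7e−4, at near-critical points where the plain orbit's own stopping rule
carries comparable error.  The budget was chosen at the classifier's zero
threshold (see below) so that solver error cannot move a curve across the
extinction criterion.

## Transition classification

The central experiment is a resource sweep: steady prevalence from the
fixed initial condition at 201 values of R on [0, 1].  Classification
(`classify`) detects discontinuities with two thresholds, `jump_threshold`
= 0.05 (minimum gap in ρ₁ counted as a jump) and `zero_threshold` = 1e−3
(below which a prevalence counts as extinction):

* **first-order** — a gap > 0.05 landing below 1e−3 (jump to extinction);
* **hybrid** — a gap > 0.05 landing above 1e−3 (jump onto a small finite
  branch that then varies continuously);
* **continuous** — no super-threshold gap while the curve spans more than
  1e−3;
* **none** — the curve never leaves extinction.

Steep continuous segments can produce large gaps on the base grid, so each
candidate gap is re-measured on a ten-fold finer sub-grid before it counts.
Because a curve can carry both a steep continuous shoulder and a genuine
smaller jump elsewhere, the top four non-adjacent candidate gaps are
examined in decreasing order and the first that survives refinement is the
discontinuity.  When every base gap is below the threshold, no refined
sub-interval can hide a super-threshold jump, and refinement is skipped.
A genuine discontinuity smaller than `jump_threshold` is classified
continuous by convention — the convention the reported boundaries inherit.

Critical values are refined by bisection on the underlying model:
`find_critical_R` bisects the indicator "steady ρ₁ > zero_threshold" to a
default tolerance of 1e−4 in R; `refine_phase_boundary` bisects any other
parameter on the classification verdict itself.  Forward/backward
continuation branches (warm-started sweeps) are available as a hysteresis
diagnostic: in bistable regimes they disagree over the coexistence
interval, in continuous regimes they coincide to 1e−6.  The backward
branch reseeds a prevalence of 1e−4 when the warm state has died out, so
it can rejoin the endemic branch once it reappears.

### Problem sizes used

Reported boundaries use the 201-point resource grid with classification as
above; degree boundaries scan integer k₂ from 4 to 60; the coupling
boundary scans γ₁ in steps of 0.05 and refines by bisection to 2e−3.  The
node-level and stochastic engines default to N = 1000 (the mean-field
results are N-free; cross-checks in the test suite use N up to 5000).
These sizes resolve every boundary well below its reporting tolerance.

## Stochastic simulator

`montecarlo.simulate` runs the agent-based process: binary states per node
per layer, synchronous updates, and independent Bernoulli exposures — a
susceptible node of layer A with m infected neighbours and an infected
counterpart escapes with probability (1−β₁)^m (1−γ₁).  Note the
deterministic equations use an *additive* counterpart term
γ₁p₂(1−p₁); the independent-exposure product agrees with it to first order
in γ and the difference is O(γ p₂ · (1−q)) per step, negligible at the
couplings studied here but a modelling choice to be aware of at γ close
to 1.  Recovery uses the realised prevalence of the current step, exactly
as the deterministic recovery law.  One master seed spawns per-realisation
generators, so ensembles are reproducible and order-independent.

The simulator emulates the model's own stochasticity, not real
epidemiological data: no degree heterogeneity, no temporal networks, no
reporting noise.  Agreement between the ensemble mean and the mean-field
prediction (asserted at N = 5000 within three combined standard errors)
validates the implementation of both engines against each other, not the
model against the world.

## Design choices on genuinely open points

* The default N for node-level and stochastic runs is 1000; the reported
  boundaries are mean-field and hence N-free, so N only controls
  Monte-Carlo noise.
* Initial prevalence defaults to 0.1 in both layers, the protocol used for
  every reported curve; sweeps restart from it at every grid point rather
  than continuing, because continuation would erase the discontinuities the
  classification is after.
* The per-element drift budget (1e−3), extrapolation entry threshold
  (1e−5), and cooldown (2000 steps) were set from the wrong-basin failure
  modes observed while validating the accelerated solver against the plain
  orbit, and then held fixed.
* Degree sweeps use integer degrees only; the mean-field map would accept
  real k but the generated networks would not match it.

## Known limitations

* The node-level equations are the standard individual-based
  approximation: they ignore neighbour–neighbour correlations, which on
  sparse graphs (k ≲ 4) visibly shift thresholds relative to the
  stochastic process.
* Classification inherits its thresholds: a genuine jump below 0.05, or an
  endemic remnant below 1e−3, is invisible by construction.  Boundary
  values in parameter space are therefore convention-dependent at the
  margin (the sweeps make this explicit by reporting jump sizes).
* The recovery feedback couples nodes only through the global prevalence;
  heterogeneous or local resource allocation is out of scope.
* Layers must share one node set; unequal layer sizes and more than two
  layers are unsupported.
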