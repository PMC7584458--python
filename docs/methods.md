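# Methods

## The model

`proteonet` simulates two interacting protein families, each with a healthy
and a toxic (misfolded) population, on a weighted graph. Each family follows
heterodimer kinetics: healthy protein is produced at a constant rate (a₀,
b₀), cleared at a linear rate (a₁, b₁), and converted to the toxic form by
contact with existing toxic protein at a mean rate (a₂, b₂); toxic protein
is cleared at its own rate (ã₁, b̃₁). The single coupling term b₃ũvṽ lets
toxic amyloid catalyse the conversion of healthy to toxic tau; the amyloid
subsystem is unaffected by tau (one-way coupling), and toxic amyloid acts
enzymatically — it is not consumed. All parameters are per-region constants
on a dimensionless concentration scale; "p% concentration" in reporting
means the absolute value p/100 on that scale.

Transport uses the weighted graph Laplacian L = ρ(D − W) with
W_ij = n_ij/l_ij² built from tractography mean fiber counts n and lengths
l; the inverse-length-squared weighting is what a finite-difference
discretization of the continuum diffusion operator produces. Each species
carries its own effective diffusivity ρ (`rho_u`, `rho_ut`, `rho_v`,
`rho_vt`): the analysis literature often writes a single ρ, but the
mixed-modality parameter table assigns distinct per-population values
(1.38, 0.138, 1.38, 0.014), so per-species storage is the general case and
a shared value is the special case of four equal fields.

Damage q_j ∈ [0,1] per node follows first-order kinetics toward 1 with rate
k₁ũ + k₂ṽ + k₃ũṽ + k₄(Aq)_j, where A_ij = n_ij/l_ij is a distinct adjacency
(damage propagates transneuronally at a rate set by tract count per unit
length, not per length squared). Baseline rates k₁=1e-4, k₂=1e-2, k₃=1e-1,
k₄=1e-3 encode that tau tangles are far more damaging than amyloid alone
and that joint toxicity dominates. Damage does not feed back on transport
or kinetics.

## Equilibria and regimes

The homogeneous system has up to four stationary states, evaluated in
closed form:

- healthy: (a₀/a₁, 0, b₀/b₁, 0) — always a solution;
- toxic-amyloid: u₂ = ã₁/a₂, ũ₂ = a₁(u₁−u₂)/ã₁, admissible iff u₁ ≥ u₂;
- toxic-tau: v₃ = b̃₁/b₂, ṽ₃ = b₁(v₁−v₃)/b̃₁, admissible iff v₁ ≥ v₃;
- fully toxic: (u₂, ũ₂, v₄, ṽ₄) with v₄ = b̃₁/(b₂ + b₃ũ₂) and
  ṽ₄ = b₁(v₁−v₄)/b̃₁.

The last two forms are obtained by eliminating ṽ from the tau fixed-point
equations; they are algebraically identical to the usual printed quotient
but remain finite when u₁ = u₂ (where the quotient is 0/0) and reduce there
automatically to the l'Hôpital limit ṽ₄ → b₁(v₁−v₃)/b̃₁. The degenerate
point is still flagged. Every admissible state is verified as a fixed point
to a residual of 1e-10 in the test suite.

Regimes follow from the balance-of-clearance inequalities ã₁/a₂ > a₀/a₁ and
b̃₁/b₂ > b₀/b₁: both holding is `healthy_stable`; both violated is
`primary_tauopathy`; amyloid violated with the tau inequality holding is
`secondary_tauopathy` when the fully toxic state is admissible (large
enough b₃) and `amyloid_only` otherwise; the remaining corner is labelled
`tau_only_inadmissible_4` (a naming choice — the source analysis leaves
this corner implicit). Equality within relative 1e-12 is reported as a
distinct boundary annotation rather than silently assigned to a side,
because it is the transcritical bifurcation ("moment of susceptibility") at
which a toxic state coincides with the healthy one.

Stability uses the block-triangular Jacobian: the amyloid pair of
eigenvalues are roots of λ² + Bλ + C with B = a₁ + ã₁ + a₂(ũ−u) and
C = a₂(ã₁ũ − a₁u) + ã₁a₁; the tau pair use the analogous B̂, Ĉ augmented by
b₃ũ(ṽ−v) and b₃ũ(b̃₁ṽ−b₁v). Complex pairs are returned as complex numbers
and stability judged on real parts. Closed-form and numeric spectra agree
to 1e-8 over a thousand random positive parameter draws in the tests.

The tau excess sustained by amyloid, ṽ₄ − ṽ₃ =
a₁b₃b₁(u₁−u₂) / (b₂(a₁b₃(u₁−u₂) + b₂ã₁)), is strictly positive in the
primary regime: toxic amyloid always raises the asymptotic tau level.

## Front speeds

In one dimension the model selects pulled fronts: the asymptotic speed of a
front invading an unstable state is the minimum speed of the linearization
about that state. The catalogue (with d̃₁ = `rho_ut`, d̃₂ = `rho_vt`):

    c_β^(12) = 2√(d̃₁(a₂a₀/a₁ − ã₁))        c_τ^(12) = 0
    c_β^(13) = 0                            c_τ^(13) = 2√(d̃₂(b₂b₀/b₁ − b̃₁))
    c_β^(14) = c_β^(12)                     c_τ^(14) = c_τ^(13)
    c_β^(24) = 0
    c_τ^(24) = 2√( d̃₂ [ã₁(a₂(b₀b₂ − b₁b̃₁) − a₁b₀b₃) + a₀a₂b₀b₃] / (a₂b₁ã₁) )
    c_β^(34) = c_τ^(34) = c_β^(12)

A negative radicand means the target state does not exist and the front is
reported as nonexistent. The grouping of the c_τ^(24) expression was fixed
by requiring it to reproduce both reference evaluations 1/(2√15) ≈ 0.1291
(unit rates, ã₁ = b̃₁ = 3/4, b₃ = 1/2) and √(2/3)/5 ≈ 0.1633 (ã₁ = 3/4,
b̃₁ = 4/3, b₃ = 3) at toxic diffusivity 0.01.

The 1D front-experiment parameter presets do not come with printed
diffusivities; 0.01 is adopted for the toxic species because it reproduces
every reference front speed through the formulas above, and the healthy
species are set equal (they do not enter the speed formulas). This is an
inferred constant, stored in the `fig22_primary`/`fig23_secondary` presets.

Empirical speeds are measured by tracking the outermost linearly
interpolated crossing of 50% of the relevant plateau (pulled-front theory
is level-insensitive asymptotically) and fitting position against time by
least squares over the central 20–90% of the traversal, excluding the
early transient and the boundary-affected tail; the fit reports a standard
error and R². For the state-2 → state-4 tau speed the measurement scenario
initializes the whole domain at the toxic-amyloid state with a tau step
seed — the literal transition the formula describes — rather than
windowing the transient of a chasing front, which is fragile. Measured
speeds agree with the linearized values to within 5% at dx = 0.1 on a
length-100 domain; pulled fronts converge to their asymptotic speed slowly
(from below), so a percent-level negative bias at finite time is expected.

## Numerics

The network system is integrated as one stiff 5V-dimensional system (4V
when damage is disabled) with SciPy's BDF method, analytic sparse Jacobian,
and defaults rtol = 1e-8, atol = 1e-10 — reaction is fast relative to
transport, which makes the system stiff, and the analytic Jacobian makes
connectome- and lattice-scale runs take seconds. Front simulations use
rtol = 1e-6 / atol = 1e-9: speed measurement is a 5%-level quantity.
Concentration undershoot beyond −1e-6 aborts the run; the suite verifies
positivity to −1e-9. Threshold crossings (onset, saturation, front
position) are located by linear interpolation on the output grid rather
than solver event detection; output grids are chosen dense enough that the
interpolation error is negligible against the reported tolerances.

The 1D continuum solver is implemented as the path-lattice special case of
the network integrator: a lattice with spacing dx has Laplacian weights
1/dx², identical to second-order central differences with zero-flux
Neumann boundaries (the graph Laplacian conserves mass, which is the
Neumann condition). One code path is exercised by both the network and the
continuum tests.

## Observables

The invasion window starts when the node-averaged toxic-tau concentration
first reaches 0.01 (the 1% convention, absolute) and ends when it first
reaches a fraction of the analytic asymptote ṽ∞ (ṽ₄ when admissible, else
ṽ₃). "Achieved" needs a tolerance the source analysis does not state: the
default saturation fraction is 0.99. Sensitivity on the 30×6×3 lattice
baseline (b₃ = 1, opposing 5% seeds): the window is 63.0 at fraction 0.95,
75.2 at 0.99, and 92.4 at 0.999 — the choice shifts window lengths by tens
of time units (the approach to the plateau is exponential, so the cutoff
matters), but none of the reported orderings or monotonicities change. Saturation curves
are offered both normalized by the analytic ṽ∞ and by the trajectory's own
maximum (the per-coupling normalization used when overlaying different b₃
values). Window-vs-coupling fits use y = A·exp(−kx) + c with k > 0
constrained (the offset accommodates the plateau seen in secondary-regime
windows); a two-parameter form is available by flag.

## Synthetic domains and what the tests show

Tests and examples run on synthetic cubic lattices (the 30×6×3 channel for
front experiments) and small random connected graphs with
connectome-style fiber attributes; GraphML ingestion is exercised on a
generated stand-in with the published low-resolution scale (83 vertices,
1,654 edges) and attribute schema. These fixtures reproduce the model's
dynamical structure — fronts, plateaus, regime transitions, window
orderings — but not the anatomy of a real connectome: no hemispheric
organization, no heavy-tailed degree/weight distributions, no anatomical
region labels. Passing tests therefore validate the kinetics, transport
operator, and observables, not any claim about staging patterns on a
specific brain graph. For the lattice front-collision experiment the
diffusivity is set to ρ = 0.1 (all species): at ρ = 1 on a 30-node-long
domain the transport and reaction timescales overlap and the intermediate
tau-only plateau lasts under one time unit, while ρ = 0.1 separates the
timescales and exposes the two-stage plateau structure; the
invasion-window studies keep ρ = 1 as in the whole-brain application
setting.

Anatomical seeding selectors resolve by case-insensitive substring match
against region labels (with the resolved node list logged), since
anatomical names rarely come with node ids; coordinate predicates and
explicit index lists are also supported.

## Limitations

- The graph is static: no atrophy feedback of damage onto transport, no
  structural plasticity.
- Kinetics are deterministic and regionally constant unless overridden; no
  stochastic nucleation.
- The continuum solver is 1D, scalar-isotropic only; no anisotropic
  diffusion tensors.
- Transneuronal damage (k₄ term) is graph-only; 1D damage requires k₄ = 0.
- No parameter fitting: presets are literal transcriptions of reference
  parameter tables, and the mixed-modality preset's time unit is stored
  verbatim, uninterpreted.
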