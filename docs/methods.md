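# Methods

## Model class and assumptions

`bistab` operates on deterministic mass-action reaction networks: the state
x ∈ ℝⁿ⁺ collects species concentrations, parameters p ∈ ℝᵐ⁺ are strictly
positive rate constants, and every reaction contributes
k·∏(reactant concentration)^stoichiometry to the rate equations. The
resulting vector field is polynomial in x, which the whole toolchain relies
on: steady states are roots of a polynomial system, and the Jacobian is
obtained by exact symbolic differentiation (sympy), never by finite
differences. Species may be held at a fixed concentration (external
sources/sinks); they scale rates but carry no equation. Non-polynomial
kinetics (Hill, Michaelis–Menten) and differential-algebraic constraints
are out of scope, as are limit cycles and Hopf phenomena — stability here
always means the sign pattern of Jacobian eigenvalue real parts at an
equilibrium.

The bundled two-species network is the smallest mass-action system known to
be bistable. Its nominal rate constants (k₁S, k₂, k₃, k₄) = (8, 1, 1, 1.5)
are reconstructed uniquely from the published linearizations of its three
steady states: J(0,0) = [[−k₄, 2k₁S], [0, −k₁S]] pins k₄ = 1.5 and
k₁S = 8, and the off-diagonal entries at the saddle (2, 0.5) pin k₃ = 1 and
k₂ = 1 (see the derivation comment in
`reaction_model.wilhelm_document`). The source species S is modeled as a
fixed species at concentration 1, so the parameter named `k1` is
effectively k₁·S; because both sensitivities are logarithmic derivatives,
this convention does not affect any reported number. All quantities are
non-dimensional.

## Steady states

All non-negative real equilibria are found, not just one: for two-species
systems the second species is eliminated by a symbolic resultant (computed
once per network with symbolic parameters and cached as coefficient
functions), the univariate polynomial is solved via its companion matrix,
and candidates are back-substituted and Newton-polished on the full system.
For n > 2 the package falls back to Groebner-basis solving with
rationalized coefficients. Numerical choices:

* polish target ‖f‖∞ < 1e−12 (accepted if below 1e−9 when the Jacobian is
  near-singular, as at a fold),
* deduplication radius 1e−6 relative to 1 + ‖x‖,
* coordinates in (−1e−9, 0) are clipped to zero; more negative or complex
  roots are discarded (concentrations live in ℝⁿ⁺),
* eigenvalues come from the exact symbolic Jacobian at the polished root,
* a state with any |Re λ| < 1e−8 is labelled *marginal* rather than
  stable/saddle — near a fold a binary label would be noise.

`assert_bistable` enforces the two-stable-plus-saddle structure and orders
the stable states by ascending first coordinate (SS1, SS2). Stable states
of two models are matched by minimal total Euclidean distance (exhaustive
assignment for ≤ 3 states); a change in the stable-state count raises a
bistability-change error, which is how perturbation routines detect that
they stepped over a bifurcation.

## Sensitivity estimators

Both measures are centered-difference logarithmic derivatives at the
nominal point, with the two perturbed models solved from scratch and
matched state-by-state to the nominal one. The default fractional step is
ε = 0.01: small enough that the O(ε²) truncation error is far below the
quantities of interest on the bundled system (verified by a Richardson
comparison against ε = 0.001 in the tests), large enough that root-polish
noise (~1e−12) is negligible. If a ±ε step exits the bistable region, ε is
halved up to six times before a bifurcation-proximity error is reported.
The estimators are undefined when the nominal spectral abscissa is
numerically zero (|α*| < 1e−8) — that only happens at the fold itself.

Sign semantics for a stable state (α* < 0): m̂ > 0 ⇔ ∂α/∂p < 0 ⇔ increasing
the parameter deepens stability. Because the estimator is a log-log slope,
it is invariant under rescaling a parameter's units and, for α(p) = C·pᵐ,
returns the exponent m to O(ε²) — both properties are exercised as tests.
Parameter clustering buckets m̂ (per chosen stable state) and ŝ by sign with
a neutral band |value| < 1e−6, and emits the corresponding
increase/decrease design-rule text.

One quantitative caveat on the bundled system: the separation sensitivity
of k₁ at the nominal point is +1.68 (exact: d ln x₊/d ln k₁ = 3/2 on the
closed-form upper branch, plus the y-component). It is therefore *not* the
smallest-magnitude separation knob (that is k₄, |ŝ| = 0.68), even though
k₁'s S-curve is sometimes read as visually flat. The sign pattern
(+, +, −, −) across (k₁…k₄) and the dominance of k₃ are unambiguous.

## Continuation, folds and arc length

Folds are located by bisection on a bistability predicate (full re-solve at
each probe, which the cached resultant makes cheap): geometric bracketing
away from the nominal value within a ×100 span, then bisection to 1e−8
relative in the parameter. A branch is then tabulated between the nominal
point and the fold at ≥ 200 parameter values spaced uniformly in
√|p_fold − p|. Near a saddle-node the state behaves like
x − x_fold ∼ √(p_fold − p), so this spacing makes the polyline chords
roughly uniform and the trapezoidal arc length accurate; sampling stops at
|p_fold − p| = 1e−9 of the span, truncating the arc length by O(1e−4)
relative. Arc length is accumulated in raw (p, x₁…xₙ) coordinates with no
per-axis scaling — appropriate for non-dimensional models; dimensional
users should non-dimensionalize first. The "auto" continuation direction is
the side with the nearer fold (in percent of nominal), which coincides with
the destabilizing sign of m̂ wherever the latter is nonzero but remains
well-defined when a state is locally insensitive to the parameter (the
origin state vs k₁, k₂, k₃ in the bundled system).

`switching_perturbation` reports the percent distance to the nearer fold,
searching both directions; when both sides fold, both are available from
`fold_summary` and the nearer one is the headline number.

## Population Monte Carlo

Cell-to-cell variability is emulated by one-parameter log-normal noise:
log(p_j) ~ N(log p_nom, σ²) with 3σ = ln(1 + Δ%/100), i.e. the *median* of
the population is the nominal value and a 3σ excursion equals a Δ% change.
(A mean-centred convention would shift the median off the nominal model;
the log-scale σ convention keeps a Δ% excursion symmetric in both
directions.) Each draw is scored by interpolating the precomputed branch
arc-length map — draws on the stabilizing side score s_c = 1, draws at or
past the fold score exactly s_c = 0 — so a 20 000-model population costs
microseconds per noise level once the branch is traced. Ranking scans
Δ = 1%…40% in 1% steps; per parameter the standard-normal draws are an
independent substream spawned from the seed and are shared across the grid
(common random numbers), which makes min(s_c) monotone in Δ and the first
switching level well-defined and reproducible. Ties rank lexicographically.

A structural property of the bundled system worth knowing: its folds sit at
−25% (k₁, k₂) and +33.3% (k₃, k₄), and ln(0.75) = −ln(4/3), so under *any*
log-normal noise convention the two clusters are exactly equidistant from
their folds in log space. The population first-switching levels of the two
clusters are therefore identically distributed, and which cluster switches
first in a given run is decided by the extreme draws of that run's seed —
typically in the 23–28% range for n = 20 000. The deterministic cluster
ordering (25% < 33.3%) is real, but log-symmetric population noise does not
reproduce it on average; only the per-run numbers are meaningful, which is
why every population routine is strictly seed-deterministic.

## What the synthetic fixture does and does not show

The bundled network is an idealized, non-dimensional, two-species switch
with exact mass-action kinetics and one-parameter-at-a-time noise. Passing
tests demonstrate the estimators, continuation and Monte Carlo machinery on
a system where every answer has a closed form (reduced quadratic
discriminants, analytic branches). They do not demonstrate robustness to
model misspecification, joint multi-parameter noise, stiff
higher-dimensional kinetics, or states near Hopf bifurcations — none of
which this package claims to handle. Population-level eigenvalue and
separation sensitivities are deliberately not implemented.

## Problem sizes

Default sizes used throughout: 256 branch samples per continuation, 20 000
models per Monte Carlo setting (2 000 in the scaled-down check), 1% grids
over 1–40%. On one CPU the full test suite runs in well under a minute and
the end-to-end reproduction script in a few seconds.
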