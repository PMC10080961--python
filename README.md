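# bistab

Quantitative design tools for **bistable mass-action reaction networks** —
the chemical switches that underlie cell-fate decisions, apoptosis
commitment and synthetic toggle circuits. Given a network of mass-action
reactions with named rate constants, `bistab` answers two practical
questions a switch designer asks:

1. *Which rate constants control how stable each ON/OFF state is, and in
   which direction should each be pushed?*
2. *How far is the switch from breaking — i.e. from the saddle-node
   bifurcation where one stable state disappears — both for a single model
   and for a noisy population of cells?*

It is aimed at systems/synthetic biologists and modelers working with small
polynomial (mass-action) ODE models.

## The quantities it computes

For a network ẋ = f(x, p) with Jacobian **A** = ∂f/∂x, a bistable system has
two stable steady states SS₁, SS₂ (all Re λ(**A**) < 0) and a saddle. Write
α_i = max Re λ(SS_i) for the spectral abscissa of state *i*.

* **Eigenvalue (spectral-abscissa) sensitivity** — a dimensionless
  centered-difference log-derivative per stable state *i* and parameter *j*:

      m̂_ij = (α_i⁺ − α_i⁻) / (2 ε p_j*) · p_j*/α_i*

  where α_i± are evaluated at p_j*(1 ± ε) with the stable states matched
  across models by Euclidean distance. For a stable state, m̂ > 0 means
  increasing p_j stabilizes it; m̂ < 0 means increasing p_j destabilizes it,
  and |m̂| reads as the local polynomial exponent of α(p_j).
* **Separation sensitivity** ŝ_j — the same estimator applied to the
  Euclidean distance ΔSS between the two stable states (a proxy for noise
  immunity of the whole switch).
* **Sign clustering & design rules** — parameters partitioned by sign(m̂)
  and sign(ŝ) into "increase to stabilize" / "decrease to stabilize"
  clusters.
* **Distance to the cliff** — one-parameter continuation of a stable state
  to the fold, arc length s along the branch in joint (p, x) space,
  s_r = s/s_max and s_c = 1 − s_r, so s_c = 0 exactly at the bifurcation.
* **Population ranking** — Monte Carlo draws log(p_j) ~ N(log p_nom, σ²)
  with 3σ = ln(1 + Δ%/100); parameters ranked by the smallest Δ% at which a
  population of 20 000 models first contains a draw past the fold
  (min s_c = 0).

The bundled fixture is the smallest known bistable mass-action system
(two dynamic species; S + Y → 2X, 2X → X + Y, X + Y → Y + P, X → P with
S held constant), with nominal rate constants (k₁S, k₂, k₃, k₄) =
(8, 1, 1, 1.5).

## Worked example

```sh
bistab steady examples/wilhelm.json --out out/
```

```
model_id  state_index   X   Y stability  spectral_abscissa
 wilhelm            0 0.0 0.0    stable          -1.500000
 wilhelm            1 2.0 0.5    saddle           0.549834
 wilhelm            2 6.0 4.5    stable          -0.958405
```

Three steady states: OFF at the origin, ON at (6, 4.5), and the saddle
between them — the eigenvalues (−1.5, −8), (0.55, −14.55) and
(−0.96, −25.04) give the stable/saddle/stable classification.

```sh
bistab sensitivity examples/wilhelm.json --out out/
```

```
parameter  epsilon  m_SS1     m_SS2     s_sep cluster_SS2
       k1     0.01   -0.0  2.706136  1.680099    positive
       k2     0.01   -0.0  1.998702  1.040147    positive
       k3     0.01   -0.0 -1.998386 -2.040415    negative
       k4     0.01    1.0 -1.706034 -0.680060    negative
```

The OFF state responds only to k₄ (α = −k₄, hence m̂ = 1 exactly). For the
ON state, raising k₁ or k₂ stabilizes it while raising k₃ or k₄ pushes it
toward collapse — the {k₁,k₂} vs {k₃,k₄} clustering. k₃ has the largest
separation magnitude: it is the strongest knob on the switch's noise
immunity (decrease it to widen the switch).

```sh
bistab cliff examples/wilhelm.json --out out/
```

```
nearest fold (percent from nominal):
  k1: 25.00%   k2: 25.00%   k3: 33.33%   k4: 33.33%
```

A 25% drop in k₁ or k₂ (or a 33.3% rise in k₃ or k₄) lands the system
exactly on the saddle-node fold; these match the analytic discriminant of
the reduced steady-state quadratic. `bistab population MODEL.json --seed N`
then reports, per parameter, the smallest population noise level (3σ
percent) at which at least one of the sampled cells crosses its fold.

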