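# Methods

## Model and conventions

The package works with one-generation transitions: a parent population with
per-individual p-scores (and, for social traits, q-scores — the partner's
p-score), realized offspring counts, and per-parent offspring p-scores.
Fitness is wᵢ = offspring countᵢ / ploidy, with ploidy defaulting to 1
(haploid, asexual). Offspring bookkeeping is per parent, which is sufficient
to compute both Δp̄ and the transmission term E(wΔp) without a pedigree
structure.

All covariances use the divide-by-n convention (no Bessel correction):
Cov(x, y) = (1/n) Σ (xᵢ − x̄)(yᵢ − ȳ). The transmission term is
E(wΔp) = (1/n) Σ wᵢ (p̄ᵢ′ − pᵢ) with p̄ᵢ′ the mean p-score of parent i's
offspring. Under these two conventions the covariance form
w̄Δp̄ = Cov(w, p) + E(wΔp) balances exactly for any transition — the
identity-suite property tests assert |gap| < 1e-9 relative to
max(1, |w̄Δp̄|) on randomized transitions, including sexual transmission
(arbitrary offspring p-scores) and ploidy 2. A parent with zero offspring has
no defined Δpᵢ; it is assigned its own p-score, which is inconsequential
because every use multiplies by wᵢ = 0. This is a convention of the package,
not something the underlying theory fixes.

A fitness model is an exponent set E with coefficients,
wᵢ = Σ β_{k,l} pᵢᵏ qᵢˡ + εᵢ, required to contain (0,0) and (1,0). Fitting is
plain OLS (numpy SVD-based least squares). Residual orthogonality to the
constant and linear-p columns is what makes Cov(ŵ, p) = Cov(w, p) and hence
the generalized covariance and regression forms identities; for that reason
no weighting or regularization is offered. Rank deficiency (relative
singular-value cutoff 1e-10) is an error that names the collinear columns,
never a silent model reduction: *which* spec is fitted is the scientific
content, and automatic term-dropping would mask misspecification. Typical
triggers are binary p-scores (p² ≡ p) and clonal pairing (q ≡ p).

Coefficient standard errors use the homoskedastic OLS formula and a Wald
t-test. Binomial offspring noise is heteroskedastic, so these are approximate
and intended for diagnostic screening only. An exact (zero-residual) fit is
flagged; its test statistic degenerates to ±∞ with p-value 0 for non-zero
coefficients.

## Selection rules

From a fitted spec the general rule reads off c = −β̂₁₀, b_{k,l} = β̂_{k,l}
over E′ = E \ {(0,0),(1,0)}, and r_{k,l} = Cov(p, pᵏqˡ)/Var(p) from the
parent population; selection for higher p-scores ⇔ Σ r_{k,l}b_{k,l} > c.
Rules are computed from coefficients and parent moments only; the realized
Δp̄ is reserved as the independent validation oracle (`direction_check`).
The inequality is strict: |lhs| within 1e-12 (relative) is flagged as a knife
edge and reported as "not selected for".

The rule-by-model map evaluates all nine combinations of the three nested
rules (non-social 0 > c; classical rb > c; interaction
r₀₁b₀₁ + r₁₁b₁₁ > c) with the three nested models. Underspecified cells use
the closed forms obtained by projecting the missing regressors onto the
included ones; in particular the classical rule applied to the interaction
model has b = β₀₁ + s_b β₁₁ and c = −β₁₀ + s_c β₁₁ with

    s_b = [Cov(p,q)Cov(p,pq) − Cov(q,pq)Var(p)] / [Cov(p,q)² − Var(p)Var(q)]
    s_c = [Cov(p,pq)Var(q) − Cov(p,q)Cov(q,pq)] / [Cov(p,q)² − Var(p)Var(q)]

These closed forms are verified against brute-force OLS of the corresponding
underspecified regression on deterministic transitions. The non-social rule
applied to the interaction model uses c = −(β₁₀ + r₀₁β₀₁ + r₁₁β₁₁); the
symbol in that cell is read as the linear-p coefficient β₁₀ (the only reading
consistent with the OLS projection, which the oracle test confirms). The 2×2
projection system is declared singular when |Cov(p,q)² − Var(p)Var(q)| falls
below 1e-10 of its natural scale (e.g. q ≡ p).

The random-mating simplification of the quadratic non-social rule,
β₁ + β₂(½ + p̄) > 0, is provided separately; with β₂ < 0 < lhs-crossing it
describes heterozygote-advantage dynamics with an interior equilibrium at
p̄* = −β₁/β₂ − ½.

## What the simulator emulates

`simulate_transition` builds a grid population (a chosen count of parents at
each p-score level), optionally assigns partners, and draws offspring.

* **Stochastic mode** draws offspring counts from Binomial(T, μᵢ/T) with
  μᵢ the model-implied mean fitness. Only the mean is theoretically pinned
  down; the trial count T sets the noise level. The default is T = 2, the
  smallest binomial compatible with the canonical experiments' maximum mean
  fitness (μ_max = 2 on the standard grid with α = 1 and β = 1). This
  minimum-variance choice implies sampling SDs of ≈ 0.011 for the linear-fit
  slope and ≈ 0.04 for quadratic-fit coefficients at 2500 parents per level,
  consistent with the dispersion of the reference estimates the experiment is
  meant to reproduce. Estimates are unbiased for any T, and T is
  configurable.
* **Expected mode** sets wᵢ = μᵢ exactly (non-integer "counts", flagged on
  the transition). It is the finite stand-in for the infinite-population
  modeling setting: least squares then recovers generating coefficients to
  machine precision, which is what makes closed-form oracle tests exact.
* **Partner matching** uses the clone-with-probability-r construction: qᵢ is
  the individual's own pᵢ with probability r, otherwise a uniformly drawn
  individual's p. This realizes Cov(p,q)/Var(p) → r and
  Cov(p,pq)/Var(p) → (1−r)p̄ + r as n → ∞, which the tests verify (error
  < 0.02 at n ≈ 10⁵). Offspring partnerships are *not* generated — a fitness
  model alone does not determine who pairs with whom in the next generation —
  so multi-generation runs require an explicit re-matching rule from the
  caller.

What the simulator does **not** emulate: mutation, drift across generations,
age structure, explicit diploid genetics (diploid users supply gamete
p-scores through `offspring_p`), or any matching mechanism beyond clone
matching. Passing tests therefore demonstrate the algebraic identities and
estimator behavior under clean binomial noise, not robustness to the richer
error structures of field data.

## Diagnostics

`coefficient_constancy_scan` refits a spec to transitions generated by a
known true model at several parent compositions. In expected mode any spread
above 1e-9 flags population dependence (a well-specified fit is exact at
every composition); in stochastic mode the spread of per-composition means
must exceed 4× the pooled Monte-Carlo SE — a deliberately conservative
multiple so that well-specified fits are not flagged by seed noise. The
recommended composition sweep varies level weights (p̄ over roughly 0.2–0.8)
rather than introducing new levels, so moment ratios such as
Cov(p,p²)/Var(p) change smoothly.

## Problem sizes and numerics

The full-size experiment uses 2500 parents at each of 11 levels (n = 27500),
matching the canonical design; unit tests use 50–400 parents per level, which
keeps the whole suite in a few seconds while leaving Monte-Carlo error well
inside the asserted tolerances. The identity tolerance is 1e-9 relative to
max(1, |w̄Δp̄|); all quantities are low-degree polynomial aggregates of
numbers in [0, 10], so this is far above accumulated rounding error but far
below any real violation.

## Known limitations

* Standard errors ignore heteroskedasticity; for inference-grade tests a
  sandwich estimator would be needed (out of scope — the fitting method of
  record is plain least squares).
* The constancy scan detects the *symptom* of misspecification; it is not a
  formal specification test and has no p-value.
* Interactions among more than two individuals are representable in the
  exponent-set data model (terms with additional variables) but no
  multi-partner operations are implemented.
* The counterfactual (non-regression) definition of costs and benefits is
  intentionally not implemented; all b's and c's here are regression
  coefficients.
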