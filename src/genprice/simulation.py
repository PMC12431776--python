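"""Transition generators: stochastic binomial offspring and deterministic expected mode.

Stochastic mode draws each parent's offspring count from a binomial
distribution whose mean is the model-implied fitness μ_i; transmission is
asexual (offspring copy the parent's p-score).  Expected mode sets the
"offspring count" equal to μ_i exactly — a deterministic stand-in for the
infinite-population modeling setting, in which least squares recovers the
generating coefficients without noise.

Partner assignment for social models uses the clone-with-probability-r
construction: each individual's q-score is its own p-score with probability
r, otherwise the p-score of a uniformly drawn individual.  In the large-n
limit this realizes relatedness Cov(p,q)/Var(p) → r and reproduces the
interaction relatedness r₁₁ = (1−r)p̄ + r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model_core import (
    DomainError,
    FittedModel,
    ModelSpec,
    ParentPopulation,
    Transition,
    make_grid_population,
    model_a,
    model_b,
)
from .model_fitting import fit_least_squares
from .price_equations import PriceDecomposition, generalized_price_regression

__all__ = [
    "SimulationConfig",
    "pair_partners",
    "transition_from_population",
    "simulate_transition",
    "figure1_experiment",
    "FIG1_LEVELS",
    "FIG1_COUNT_PER_LEVEL",
    "FIG1_PANELS",
]

# The 11 p-score levels 0, 0.1, ..., 1 with 2500 parents each (n = 27500).
FIG1_LEVELS: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.05, 0.1), 10))
FIG1_COUNT_PER_LEVEL = 2500

# Panel → (generating model coefficients, fit spec).  Panels a and c share a
# transition generated by the linear model (α=1, β₁=1); panels b and d share
# one generated by the quadratic model (α=1, β₁=0, β₂=1).  Panels a and b fit
# the linear spec, c and d the quadratic spec.
FIG1_PANELS = {
    "a": ("A", "linear"),
    "b": ("B", "linear"),
    "c": ("A", "quadratic"),
    "d": ("B", "quadratic"),
}

_MODEL_A_COEFFS = {(0, 0): 1.0, (1, 0): 1.0}
_MODEL_B_COEFFS = {(0, 0): 1.0, (1, 0): 0.0, (2, 0): 1.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one transition.

    ``levels``/``count_per_level`` define the grid composition; ``model`` is a
    spec *with* coefficients; ``relatedness_r`` (social models only) sets the
    clone-matching probability; ``mode`` selects stochastic binomial offspring
    or deterministic expected fitnesses; ``trials_per_parent`` is the binomial
    trial count (the mean μ_i is what the model pins down, so estimates are
    unbiased for any trial count ≥ μ_i).
    """

    levels: tuple[float, ...]
    count_per_level: int
    model: ModelSpec
    relatedness_r: float | None = None
    mode: Literal["stochastic", "expected"] = "stochastic"
    seed: int = 0
    trials_per_parent: int = 2

    def __post_init__(self) -> None:
        if self.model.coefficients is None:
            raise DomainError("simulation model must carry coefficients")
        if self.model.is_social and self.relatedness_r is None:
            raise DomainError("social model requires relatedness_r")
        if self.relatedness_r is not None and not 0.0 <= self.relatedness_r <= 1.0:
            raise DomainError("relatedness_r must lie in [0, 1]")
        if self.trials_per_parent < 1:
            raise DomainError("trials_per_parent must be positive")


def pair_partners(
    pop: ParentPopulation, r: float, seed: int | np.random.Generator = 0
) -> ParentPopulation:
    """Assign q-scores by clone matching at target relatedness ``r``.

    Each individual is paired with itself (q_i = p_i) with probability r, and
    with a uniformly drawn individual otherwise, so Cov(p,q)/Var(p) → r as
    n → ∞.  The marginal distribution of q equals that of p in expectation.
    """
    if not 0.0 <= r <= 1.0:
        raise DomainError("relatedness r must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = pop.n
    if float(np.var(pop.p)) == 0.0:
        warnings.warn(
            "population has Var(p) = 0; realized relatedness is undefined",
            stacklevel=2,
        )
    partner = rng.integers(0, n, size=n)
    clone = rng.random(n) < r
    q = np.where(clone, pop.p, pop.p[partner])
    return ParentPopulation(p=pop.p, q=q)


def transition_from_population(
    pop: ParentPopulation,
    model: ModelSpec,
    mode: Literal["stochastic", "expected"] = "stochastic",
    seed: int | np.random.Generator = 0,
    trials_per_parent: int = 2,
) -> Transition:
    """Generate an asexual transition from a given parent population.

    Stochastic mode: offspring_counts_i ~ Binomial(trials, μ_i/trials).
    Expected mode: w_i = μ_i exactly (non-integer counts, flagged on the
    transition object).
    """
    mu = model.predict(pop)
    if np.any(mu < 0):
        raise DomainError("model-implied mean fitness is negative for some parents")
    if mode == "expected":
        return Transition(parents=pop, offspring_counts=mu, expected_mode=True)
    if np.any(mu > trials_per_parent):
        raise DomainError(
            f"mean fitness exceeds trials_per_parent={trials_per_parent}; "
            "raise trials_per_parent"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.binomial(trials_per_parent, mu / trials_per_parent)
    return Transition(parents=pop, offspring_counts=counts.astype(float))


def simulate_transition(cfg: SimulationConfig) -> Transition:
    """Build the grid population, pair partners if social, and generate offspring."""
    rng = np.random.default_rng(cfg.seed)
    pop = make_grid_population(cfg.levels, cfg.count_per_level)
    if cfg.model.is_social:
        pop = pair_partners(pop, cfg.relatedness_r, rng)
    return transition_from_population(
        pop, cfg.model, mode=cfg.mode, seed=rng, trials_per_parent=cfg.trials_per_parent
    )


def figure1_experiment(
    panel: str,
    seed: int = 0,
    count_per_level: int = FIG1_COUNT_PER_LEVEL,
) -> tuple[Transition, FittedModel, PriceDecomposition]:
    """One panel of the two-models-by-two-fits experiment.

    The grid holds ``count_per_level`` parents at each p-score 0, 0.1, ..., 1.
    Offspring counts are binomial with mean 1 + p (linear generator, panels a
    and c) or 1 + p² (quadratic generator, panels b and d); reproduction is
    asexual so E(wΔp) = 0.  The panel's fit spec is linear (a, b) or quadratic
    (c, d); the well-specified panels are a and d, panel c is an (innocuous)
    overspecification and panel b an underspecification, whose fitted slope
    tends to β₁ + β₂·Cov(p,p²)/Var(p) rather than the true β₁.

    Returns the transition, the fitted model, and the regression-form
    decomposition of w̄Δp̄.
    """
    panel = panel.lower()
    if panel not in FIG1_PANELS:
        raise DomainError(f"panel must be one of {sorted(FIG1_PANELS)}, got {panel!r}")
    generator, fit_kind = FIG1_PANELS[panel]
    coeffs = _MODEL_A_COEFFS if generator == "A" else _MODEL_B_COEFFS
    gen_spec = (model_a() if generator == "A" else model_b()).with_coefficients(coeffs)
    cfg = SimulationConfig(
        levels=FIG1_LEVELS,
        count_per_level=count_per_level,
        model=gen_spec,
        mode="stochastic",
        seed=seed,
    )
    t = simulate_transition(cfg)
    fit_spec = model_a() if fit_kind == "linear" else model_b()
    fit = fit_least_squares(t, fit_spec)
    decomp = generalized_price_regression(t, fit)
    return t, fit, decomp
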