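"""The general version of Hamilton's rule and its nested special cases.

For a fitted exponent-set model with coefficient β̂₁₀ on the linear p-term and
rule-relevant terms E′, higher p-scores are selected for if and only if

    Σ_{(k,l)∈E′} r_{k,l} b_{k,l} > c

with cost c = −β̂₁₀, benefits b_{k,l} = β̂_{k,l}, and generalized relatedness
coefficients r_{k,l} = Cov(p, p^k q^l)/Var(p).  The classical r₀₁ is
Cov(p,q)/Var(p); under clone matching at relatedness r in a large population,
r₁₁ = Cov(p,pq)/Var(p) → (1−r)p̄ + r.

Nesting: the linear non-social spec gives the non-social rule 0 > c; adding a
q-term gives classical Hamilton's rule rb > c; adding the pq interaction
gives Queller's rule r₀₁b₀₁ + r₁₁b₁₁ > c.

The misspecification map evaluates all nine combinations of the three nested
rules and the three nested models, with closed forms for the effective
(population-state-dependent) costs and benefits of each underspecified cell.

Rules are evaluated from fitted coefficients and parent-population moments
only — never from the realized Δp̄, which serves as the independent
validation oracle elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .model_core import (
    DomainError,
    FittedModel,
    IdentifiabilityError,
    ModelSpec,
    ParentPopulation,
    validate_spec,
)
from .price_equations import cov, var

__all__ = [
    "KNIFE_EDGE_TOL",
    "RuleResult",
    "MisspecCell",
    "relatedness_coefficients",
    "evaluate_rule",
    "general_hamilton_rule",
    "random_mating_quadratic_rule",
    "misspecification_map",
]

# |lhs| at or below this (relative) scale is flagged as a knife edge: the rule
# uses strict inequalities, so the verdict there is "not selected for".
KNIFE_EDGE_TOL = 1e-12


@dataclass(frozen=True)
class RuleResult:
    """Outcome of evaluating one selection rule.

    ``lhs`` is Σ r_{k,l}b_{k,l} − c; selection for higher p-scores holds iff
    lhs > 0.  ``knife_edge`` flags |lhs| ≈ 0, where the strict inequality
    gives a "False" verdict but Δp̄ = 0 in the matching deterministic model.
    """

    rule_name: str
    c: float
    b: dict[tuple[int, int], float]
    r: dict[tuple[int, int], float]
    lhs: float
    selection_for_higher_p: bool
    knife_edge: bool = False


@dataclass(frozen=True)
class MisspecCell:
    """One rule×model cell: the rule's effective cost/benefit terms.

    For well- or over-specified cells (rule at least as general as the model)
    the entries are the model's own coefficients, padded with zeros.  For
    underspecified cells they absorb population moments and are therefore
    population-state dependent.
    """

    rule: int
    model: int
    effective_c: float
    effective_b: float | None = None
    effective_b01: float | None = None
    effective_b11: float | None = None
    population_dependent: bool = False
    s_b: float | None = None
    s_c: float | None = None

    def lhs(self, r01: float, r11: float) -> float:
        """The rule's Σ r·b − c given the population's relatedness coefficients."""
        if self.rule == 1:
            return -self.effective_c
        if self.rule == 2:
            return r01 * self.effective_b - self.effective_c
        return r01 * self.effective_b01 + r11 * self.effective_b11 - self.effective_c


def relatedness_coefficients(
    pop: ParentPopulation, spec: ModelSpec
) -> dict[tuple[int, int], float]:
    """Generalized relatedness r_{k,l} = Cov(p, p^k q^l)/Var(p) over E′."""
    v = var(pop.p)
    if v <= 0.0:
        raise IdentifiabilityError("Var(p) = 0: relatedness coefficients undefined")
    validate_spec(spec, pop)
    out = {}
    for (k, l) in spec.rule_terms:
        col = pop.p**k if k else np.ones(pop.n)
        if l:
            col = col * pop.q**l
        out[(k, l)] = cov(pop.p, col) / v
    return out


def _rule_name(spec: ModelSpec) -> str:
    terms = set(spec.rule_terms)
    if not terms:
        return "rule1"
    if terms == {(0, 1)}:
        return "classical"
    if terms == {(0, 1), (1, 1)}:
        return "queller"
    return "general"


def evaluate_rule(spec: ModelSpec, pop: ParentPopulation) -> RuleResult:
    """Evaluate Σ r_{k,l}b_{k,l} > c for a coefficient-carrying spec on a population.

    Uses fitted (or model) coefficients plus parent-population moments only;
    the realized Δp̄ is never consulted — it is the independent check.
    """
    if spec.coefficients is None:
        raise DomainError("spec must carry coefficients to evaluate a rule")
    r = relatedness_coefficients(pop, spec)
    c = -spec.coefficients[(1, 0)]
    b = {term: spec.coefficients[term] for term in spec.rule_terms}
    lhs = sum(r[t] * b[t] for t in b) - c
    scale = max(1.0, abs(c), *(abs(v) for v in b.values())) if b else max(1.0, abs(c))
    knife = abs(lhs) <= KNIFE_EDGE_TOL * scale
    return RuleResult(
        rule_name=_rule_name(spec),
        c=c,
        b=b,
        r=r,
        lhs=float(lhs),
        selection_for_higher_p=bool(lhs > 0 and not knife),
        knife_edge=knife,
    )


def general_hamilton_rule(fit: FittedModel, pop: ParentPopulation) -> RuleResult:
    """Evaluate the general rule for a fitted model on its parent population.

    Reduces to the nested special cases automatically: with no rule terms it
    is the non-social rule 0 > c; with only (0,1) it is classical Hamilton's
    rule rb > c; with (0,1) and (1,1) it is Queller's rule.
    """
    if fit.n != pop.n:
        raise DomainError(
            f"fit has n={fit.n} but population has n={pop.n}; "
            "rules must be evaluated on the fit's own population"
        )
    return evaluate_rule(fit.coefficient_spec(), pop)


def random_mating_quadratic_rule(
    beta1: float, beta2: float, p_bar: float
) -> RuleResult:
    """Selection rule for the quadratic non-social model under random mating.

    With random mating between generations the quadratic rule
    β₁Var(p) + β₂Cov(p,p²) > 0 simplifies to β₁ + β₂(½ + p̄) > 0 — the
    workhorse for heterozygote-advantage dynamics, with an interior
    equilibrium at p̄* = −β₁/β₂ − ½ when that lies in [0, 1].  With β₂ = 0 it
    reverts to the linear rule β₁ > 0.
    """
    if not 0.0 <= p_bar <= 1.0:
        raise DomainError("p_bar must lie in [0, 1]")
    lhs = beta1 + beta2 * (0.5 + p_bar)
    knife = abs(lhs) <= KNIFE_EDGE_TOL * max(1.0, abs(beta1), abs(beta2))
    return RuleResult(
        rule_name="random_mating_quadratic",
        c=-beta1,
        b={(2, 0): beta2},
        r={(2, 0): 0.5 + p_bar},
        lhs=float(lhs),
        selection_for_higher_p=bool(lhs > 0 and not knife),
        knife_edge=knife,
    )


def _social_moments(pop: ParentPopulation) -> dict[str, float]:
    p, q = pop.p, pop.q
    return {
        "var_p": var(p),
        "var_q": var(q),
        "cov_pq": cov(p, q),
        "cov_p_pq": cov(p, p * q),
        "cov_q_pq": cov(q, p * q),
    }


def misspecification_map(
    model3_coeffs: Mapping[tuple[int, int], float],
    pop: ParentPopulation,
) -> dict[tuple[int, int], MisspecCell]:
    """All nine rule×model combinations of the three nested rules and models.

    ``model3_coeffs`` supplies the full interaction-model coefficients
    {(0,0): α, (1,0): β₁₀, (0,1): β₀₁, (1,1): β₁₁}; models 1 and 2 are its
    restrictions with β₀₁ and/or β₁₁ zeroed.  Keys of the result are
    ``(rule, model)`` with rule, model ∈ {1, 2, 3}.

    Underspecified cells (rule < model) absorb population moments:

    * rule 1 on model 2: c = −(β₁₀ + r₀₁β₀₁)
    * rule 1 on model 3: c = −(β₁₀ + r₀₁β₀₁ + r₁₁β₁₁)
    * rule 2 on model 3: b = β₀₁ + s_b·β₁₁,  c = −β₁₀ + s_c·β₁₁

    with s_b = [Cov(p,q)Cov(p,pq) − Cov(q,pq)Var(p)] / [Cov(p,q)² − Var(p)Var(q)]
    and s_c = [Cov(p,pq)Var(q) − Cov(p,q)Cov(q,pq)] / [Cov(p,q)² − Var(p)Var(q)];
    these equal the coefficients brute-force OLS of the underspecified
    regression would produce on a deterministic expected-mode transition.
    """
    if not pop.has_q:
        raise DomainError("misspecification map needs a population with q-scores")
    for term in ((0, 0), (1, 0), (0, 1), (1, 1)):
        if term not in model3_coeffs:
            raise DomainError(f"model3_coeffs missing term {term}")
    b10 = float(model3_coeffs[(1, 0)])
    b01 = float(model3_coeffs[(0, 1)])
    b11 = float(model3_coeffs[(1, 1)])

    m = _social_moments(pop)
    if m["var_p"] <= 0.0:
        raise IdentifiabilityError("Var(p) = 0: rules undefined")
    r01 = m["cov_pq"] / m["var_p"]
    r11 = m["cov_p_pq"] / m["var_p"]
    det = m["cov_pq"] ** 2 - m["var_p"] * m["var_q"]
    scale = max(m["var_p"] * m["var_q"], m["cov_pq"] ** 2, 1e-300)
    if abs(det) <= 1e-10 * scale:
        raise IdentifiabilityError(
            "p and q are collinear (e.g. q ≡ p): s_b and s_c are undefined"
        )
    s_b = (m["cov_pq"] * m["cov_p_pq"] - m["cov_q_pq"] * m["var_p"]) / det
    s_c = (m["cov_p_pq"] * m["var_q"] - m["cov_pq"] * m["cov_q_pq"]) / det

    cells: dict[tuple[int, int], MisspecCell] = {}
    # Rule 1: 0 > c (non-social rule).
    cells[(1, 1)] = MisspecCell(rule=1, model=1, effective_c=-b10)
    cells[(1, 2)] = MisspecCell(
        rule=1, model=2, effective_c=-(b10 + r01 * b01), population_dependent=True
    )
    cells[(1, 3)] = MisspecCell(
        rule=1,
        model=3,
        effective_c=-(b10 + r01 * b01 + r11 * b11),
        population_dependent=True,
    )
    # Rule 2: rb > c (classical Hamilton's rule).
    cells[(2, 1)] = MisspecCell(rule=2, model=1, effective_c=-b10, effective_b=0.0)
    cells[(2, 2)] = MisspecCell(rule=2, model=2, effective_c=-b10, effective_b=b01)
    cells[(2, 3)] = MisspecCell(
        rule=2,
        model=3,
        effective_c=-b10 + s_c * b11,
        effective_b=b01 + s_b * b11,
        population_dependent=True,
        s_b=s_b,
        s_c=s_c,
    )
    # Rule 3: r01·b01 + r11·b11 > c (Queller's rule).
    for model, (eb01, eb11) in ((1, (0.0, 0.0)), (2, (b01, 0.0)), (3, (b01, b11))):
        cells[(3, model)] = MisspecCell(
            rule=3,
            model=model,
            effective_c=-b10,
            effective_b01=eb01,
            effective_b11=eb11,
        )
    return cells
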