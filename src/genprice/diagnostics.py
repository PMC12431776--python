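"""Misspecification diagnostics: coefficient constancy across parent compositions.

A well-specified fit recovers the same coefficients whatever the composition
of the parent population; an underspecified fit's coefficients absorb
population moments (e.g. the linear fit to quadratic truth yields
β̂₁ = β₁ + β₂·Cov(p,p²)/Var(p)) and therefore drift as the composition
changes.  That drift — not "dynamic insufficiency" — is the operational
symptom of having combined the decomposition with the wrong model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .model_core import DomainError, ModelSpec, ParentPopulation, Transition
from .model_fitting import fit_least_squares
from .price_equations import transition_stats
from .selection_rules import RuleResult
from .simulation import transition_from_population

__all__ = ["ConstancyScan", "coefficient_constancy_scan", "direction_check"]

# Spread threshold flagging population dependence in expected (noise-free) mode.
EXPECTED_MODE_TOL = 1e-9
# In stochastic mode, spread must exceed this multiple of the pooled MC
# standard error before a coefficient is flagged (conservative, seed-robust).
STOCHASTIC_SE_MULTIPLE = 4.0


@dataclass(frozen=True)
class ConstancyScan:
    """Result of a coefficient-constancy scan.

    ``estimates`` is long-format: one row per (composition, term, replicate)
    with the fitted coefficient; terms are encoded as ``"k,l"`` strings.  ``spread`` maps each term to the range of
    its per-composition mean estimates; ``flagged`` marks terms whose spread
    exceeds the mode-appropriate threshold, and ``population_dependent`` is
    their disjunction.
    """

    estimates: pd.DataFrame
    spread: dict[tuple[int, int], float]
    flagged: dict[tuple[int, int], bool]
    mode: str

    @property
    def population_dependent(self) -> bool:
        return any(self.flagged.values())


def coefficient_constancy_scan(
    true_model: ModelSpec,
    fit_spec: ModelSpec,
    compositions: Sequence[ParentPopulation],
    mode: Literal["expected", "stochastic"] = "expected",
    seed: int = 0,
    replicates: int = 20,
    trials_per_parent: int = 2,
) -> ConstancyScan:
    """Fit ``fit_spec`` to transitions generated by ``true_model`` at each composition.

    In expected mode one deterministic transition per composition suffices and
    any spread above numerical noise indicates population dependence.  In
    stochastic mode, ``replicates`` transitions are drawn per composition and
    the spread of per-composition means is compared with the pooled
    Monte-Carlo standard error.
    """
    if len(compositions) < 2:
        raise DomainError("need at least 2 compositions to assess constancy")
    if true_model.coefficients is None:
        raise DomainError("true_model must carry coefficients")
    rng = np.random.default_rng(seed)
    rows = []
    for ci, pop in enumerate(compositions):
        reps = 1 if mode == "expected" else replicates
        for rep in range(reps):
            t = transition_from_population(
                pop, true_model, mode=mode, seed=rng,
                trials_per_parent=trials_per_parent,
            )
            fit = fit_least_squares(t, fit_spec)
            for term, beta in fit.beta_hat.items():
                rows.append(
                    {
                        "composition": ci,
                        "term": f"{term[0]},{term[1]}",
                        "replicate": rep,
                        "estimate": beta,
                    }
                )
    est = pd.DataFrame(rows)
    spread: dict[tuple[int, int], float] = {}
    flagged: dict[tuple[int, int], bool] = {}
    for term in fit_spec.terms:
        sub = est[est["term"] == f"{term[0]},{term[1]}"]
        means = sub.groupby("composition")["estimate"].mean()
        rng_means = float(means.max() - means.min())
        spread[term] = rng_means
        if mode == "expected":
            flagged[term] = rng_means > EXPECTED_MODE_TOL
        else:
            within = sub.groupby("composition")["estimate"].sem().to_numpy()
            pooled_se = float(np.sqrt(np.mean(within**2)))
            flagged[term] = rng_means > STOCHASTIC_SE_MULTIPLE * pooled_se
    return ConstancyScan(estimates=est, spread=spread, flagged=flagged, mode=mode)


def direction_check(t: Transition, rule: RuleResult, atol: float = 1e-9) -> bool:
    """Does the rule's verdict agree with the realized direction of selection?

    Agreement means sign(Δp̄) matches the verdict: Δp̄ > 0 with selection for,
    Δp̄ < 0 with selection against, and |Δp̄| ≈ 0 with a knife-edge rule.
    """
    _, dp, _ = transition_stats(t)
    if abs(dp) <= atol:
        return rule.knife_edge or not rule.selection_for_higher_p and abs(rule.lhs) <= atol
    if dp > 0:
        return rule.selection_for_higher_p
    return not rule.selection_for_higher_p and not rule.knife_edge
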