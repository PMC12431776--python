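"""Ordinary least squares over exponent-set regressors.

Fitting a model spec to a transition means minimizing Σ(w_i − ŵ_i)² over the
coefficients, where ŵ_i = Σ β_{k,l} p_i^k q_i^l.  Plain OLS is the method —
no weighting, no regularization — because the decomposition identities rest
on the exact orthogonality of OLS residuals to every regressor column.

Rank deficiency (e.g. binary p-scores make p² ≡ p; clonal pairing makes
q ≡ p) is an error, never a silent model reduction: which spec is fitted is
the whole point, and dropping terms would hide misspecification.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .model_core import (
    DomainError,
    FittedModel,
    IdentifiabilityError,
    ModelSpec,
    ParentPopulation,
    Transition,
    validate_spec,
)

__all__ = ["RANK_TOL", "design_matrix", "fit_least_squares", "coefficient_test"]

# Relative singular-value cutoff below which the design is declared rank deficient.
RANK_TOL = 1e-10


def design_matrix(pop: ParentPopulation, spec: ModelSpec) -> np.ndarray:
    """Regressor matrix with one column per exponent pair, entry p_i^k q_i^l.

    Column order is the spec's sorted term order (k ascending, then l
    ascending) and is stable across calls.  The convention 0⁰ = 1 applies, so
    the (0, 0) column is all ones.
    """
    validate_spec(spec, pop)
    cols = []
    for (k, l) in spec.terms:
        col = pop.p**k if k else np.ones(pop.n)
        if l:
            col = col * pop.q**l
        cols.append(col)
    return np.column_stack(cols)


def _collinear_terms(X: np.ndarray, spec: ModelSpec) -> list[tuple[int, int]]:
    """Terms involved in a collinearity: dropping any of them restores full rank."""
    full_rank = np.linalg.matrix_rank(X, tol=RANK_TOL * float(np.linalg.norm(X, 2)))
    involved = []
    for j, term in enumerate(spec.terms):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced, tol=RANK_TOL * float(np.linalg.norm(X, 2))) == full_rank:
            involved.append(term)
    return involved


def fit_least_squares(t: Transition, spec: ModelSpec) -> FittedModel:
    """Fit a spec to a transition by ordinary least squares.

    Returns a :class:`FittedModel` whose residuals are orthogonal to every
    regressor column (the property the generalized Price identities rely on).
    Standard errors use the homoskedastic OLS formula; with binomial offspring
    noise they are approximate and intended for diagnostics only.
    """
    X = design_matrix(t.parents, spec)
    w = t.fitness
    n, m = X.shape
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[0] == 0.0 or sv[-1] / sv[0] < RANK_TOL:
        bad = _collinear_terms(X, spec)
        raise IdentifiabilityError(
            f"design matrix is rank deficient; collinear columns: {bad}. "
            "Remove or reparameterize these terms explicitly."
        )
    beta, *_ = np.linalg.lstsq(X, w, rcond=None)
    predicted = X @ beta
    residuals = w - predicted
    rss = float(residuals @ residuals)
    df = n - m
    scale = max(1.0, float(w @ w))
    exact = rss <= 1e-20 * scale
    if df > 0 and not exact:
        sigma2 = rss / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
    else:
        se = np.zeros(m)
    return FittedModel(
        spec=spec,
        beta_hat={term: float(b) for term, b in zip(spec.terms, beta)},
        predicted_fitness=predicted,
        residuals=residuals,
        standard_errors={term: float(s) for term, s in zip(spec.terms, se)},
        df_resid=df,
        exact_fit=exact,
    )


def coefficient_test(
    fit: FittedModel, term: tuple[int, int]
) -> tuple[float, float]:
    """Wald t-test of H0: β_{k,l} = 0 against a two-sided alternative.

    Returns ``(statistic, p_value)``.  On an exact (noiseless) fit the
    standard error is zero and the statistic degenerates: ±inf with p-value 0
    for a non-zero coefficient, 0 with p-value 1 otherwise.
    """
    term = (int(term[0]), int(term[1]))
    if term not in fit.beta_hat:
        raise DomainError(f"term {term} is not in the fitted spec {fit.spec.terms}")
    if fit.df_resid < 1:
        raise DomainError("no residual degrees of freedom for a coefficient test")
    beta = fit.beta_hat[term]
    se = fit.standard_errors[term]
    if se == 0.0:
        if beta == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, beta), 0.0
    stat = beta / se
    p = 2.0 * float(stats.t.sf(abs(stat), fit.df_resid))
    return stat, p
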