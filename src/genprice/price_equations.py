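"""The Price equation and its generalized covariance and regression forms.

All three forms are *identities*: for any transition between a parent and an
offspring generation they balance exactly, whatever the data and (for the
generalized forms) whatever the reference model, as long as it contains a
constant and a linear p-term.

The covariance convention throughout is divide-by-n (no Bessel correction):
``Cov(x, y) = (1/n) Σ (x_i − x̄)(y_i − ȳ)``.  The transmission term is the
fitness-weighted average parent–offspring p-score difference,
``E(wΔp) = (1/n) Σ w_i (p̄ᵢ' − p_i)`` with p̄ᵢ' the mean p-score of parent
i's offspring; with asexual transmission it is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import (
    DegenerateTransitionError,
    DomainError,
    FittedModel,
    Transition,
)

__all__ = [
    "IDENTITY_TOL",
    "PriceDecomposition",
    "cov",
    "var",
    "transition_stats",
    "price_covariance_form",
    "generalized_price_covariance",
    "generalized_price_regression",
]

# Absolute tolerance for the identity check, relative to max(1, |w̄Δp̄|).
# All quantities are low-degree polynomial aggregates, so 1e-9 is generous.
IDENTITY_TOL = 1e-9


def cov(x: np.ndarray, y: np.ndarray) -> float:
    """Divide-by-n sample covariance (1/n) Σ (x_i − x̄)(y_i − ȳ)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError(f"cov needs equal-length vectors, got {x.shape} and {y.shape}")
    if x.size == 0:
        raise DomainError("cov of empty vectors is undefined")
    return float(np.mean((x - x.mean()) * (y - y.mean())))


def var(x: np.ndarray) -> float:
    """Divide-by-n sample variance, Cov(x, x)."""
    return cov(x, x)


@dataclass(frozen=True)
class PriceDecomposition:
    """One additive decomposition of w̄Δp̄ into named terms.

    ``residual_gap`` is the left-hand side minus the sum of the terms; the
    decomposition is an identity, so the gap is zero up to floating-point
    error on *every* transition — that is a property of the algebra, not a
    modeling assumption.
    """

    lhs: float
    terms: tuple[tuple[str, float], ...]
    form: str

    @property
    def residual_gap(self) -> float:
        return self.lhs - sum(v for _, v in self.terms)

    @property
    def balances(self) -> bool:
        return abs(self.residual_gap) <= IDENTITY_TOL * max(1.0, abs(self.lhs))

    def term(self, name: str) -> float:
        for key, value in self.terms:
            if key == name:
                return value
        raise KeyError(name)


def transition_stats(t: Transition) -> tuple[float, float, float]:
    """Return (w̄, Δp̄, E(wΔp)) for a transition.

    Δp̄ is the offspring-population mean p-score minus the parent mean; the
    offspring mean weights each parent's mean offspring p-score by its
    offspring count.  A parent with zero offspring contributes nothing.
    """
    w = t.fitness
    total = float(np.sum(w))
    if total <= 0:
        raise DegenerateTransitionError("no offspring: per-generation change undefined")
    w_bar = float(np.mean(w))
    off_p = t.mean_offspring_p()
    offspring_mean = float(np.sum(w * off_p) / total)
    delta_p_bar = offspring_mean - t.parents.p_bar
    e_w_dp = float(np.mean(w * (off_p - t.parents.p)))
    return w_bar, delta_p_bar, e_w_dp


def _check_fit_matches(t: Transition, fit: FittedModel) -> None:
    if fit.n != t.n:
        raise DomainError(
            f"fitted model has n={fit.n} but transition has n={t.n}"
        )
    if not np.allclose(t.fitness - fit.predicted_fitness, fit.residuals,
                       rtol=0.0, atol=1e-8 * max(1.0, float(np.max(np.abs(t.fitness))))):
        raise DomainError("fitted model was not produced on this transition")


def price_covariance_form(t: Transition) -> PriceDecomposition:
    """Covariance form: w̄Δp̄ = Cov(w, p) + E(wΔp)."""
    if t.n < 2:
        raise DomainError("covariance form needs at least 2 parents")
    w_bar, dp, e_w_dp = transition_stats(t)
    c = cov(t.fitness, t.parents.p)
    return PriceDecomposition(
        lhs=w_bar * dp,
        terms=(("Cov(w,p)", c), ("E(wΔp)", e_w_dp)),
        form="PE.C",
    )


def generalized_price_covariance(t: Transition, fit: FittedModel) -> PriceDecomposition:
    """Generalized covariance form: w̄Δp̄ = Cov(ŵ, p) + E(wΔp).

    Because the spec contains a constant and a linear p-term, least-squares
    orthogonality forces Cov(ŵ, p) = Cov(w, p): the predicted fitnesses can
    replace the realized ones without breaking the identity, for *any* such
    reference model.
    """
    _check_fit_matches(t, fit)
    w_bar, dp, e_w_dp = transition_stats(t)
    c_hat = cov(fit.predicted_fitness, t.parents.p)
    return PriceDecomposition(
        lhs=w_bar * dp,
        terms=(("Cov(ŵ,p)", c_hat), ("E(wΔp)", e_w_dp)),
        form="GPE.C",
    )


def generalized_price_regression(t: Transition, fit: FittedModel) -> PriceDecomposition:
    """Regression form: w̄Δp̄ = Σ_{(k,l)≠(0,0)} β̂_{k,l}·Cov(p, p^k q^l) + E(wΔp).

    One term per non-constant exponent pair; the constant term drops out
    because Cov(p, 1) = 0.  For the linear spec this reduces to
    β̂₁·Var(p) + E(wΔp), the regression form of the original Price equation.
    """
    _check_fit_matches(t, fit)
    w_bar, dp, e_w_dp = transition_stats(t)
    p = t.parents.p
    q = t.parents.q
    terms: list[tuple[str, float]] = []
    for (k, l) in fit.spec.terms:
        if (k, l) == (0, 0):
            continue
        col = p**k if k else np.ones(t.n)
        if l:
            col = col * q**l
        name = f"β̂[{k},{l}]·Cov(p,p^{k}q^{l})" if l else f"β̂[{k},0]·Cov(p,p^{k})"
        terms.append((name, fit.beta_hat[(k, l)] * cov(p, col)))
    terms.append(("E(wΔp)", e_w_dp))
    return PriceDecomposition(lhs=w_bar * dp, terms=tuple(terms), form="GPE.R")
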