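"""Core domain types: parent populations, transitions, and exponent-set fitness models.

The central abstraction is the *p*-score: a number in [0, 1] summarizing an
individual's genotype at the tracked locus or loci (presence/absence of a gene
in the haploid case).  Social models additionally carry a *q*-score per
individual — the p-score of its interaction partner.

A fitness model is a choice of exponent pairs ``(k, l)``: the model
``w_i = sum_{(k,l)} beta_{k,l} p_i^k q_i^l + eps_i``.  Every model must contain
the constant term ``(0, 0)`` and the linear p-term ``(1, 0)``; the remaining
terms form the rule-relevant set ``E'`` used by the selection rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenPriceError",
    "DomainError",
    "SpecError",
    "DataError",
    "IdentifiabilityError",
    "DegenerateTransitionError",
    "ParentPopulation",
    "Transition",
    "ModelSpec",
    "FittedModel",
    "MANDATORY_TERMS",
    "make_grid_population",
    "validate_spec",
    "model_a",
    "model_b",
    "nonsocial_model",
    "model_1",
    "model_2",
    "model_3",
]

# Mandatory exponent pairs: constant term and linear p-term.
MANDATORY_TERMS = ((0, 0), (1, 0))


class GenPriceError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(GenPriceError, ValueError):
    """An input value lies outside its mathematical domain."""


class SpecError(GenPriceError, ValueError):
    """A model specification violates the structural requirements."""


class DataError(GenPriceError, ValueError):
    """Data are structurally incompatible with the requested operation."""


class IdentifiabilityError(GenPriceError, ValueError):
    """A regression design is rank deficient; coefficients are not identified."""


class DegenerateTransitionError(GenPriceError, ValueError):
    """A transition has no offspring, so per-generation change is undefined."""


def _as_unit_interval(values: Sequence[float] | np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    if arr.size and (np.min(arr) < 0.0 or np.max(arr) > 1.0):
        raise DomainError(f"all {name} values must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class ParentPopulation:
    """A parent generation: per-individual p-scores and optional partner q-scores.

    Parameters
    ----------
    p
        Vector of p-scores, each in [0, 1].
    q
        Optional vector of partner p-scores (same length as ``p``).  Required
        for social models, i.e. any model spec with a term ``(k, l)`` with
        ``l > 0``.
    """

    p: np.ndarray
    q: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", _as_unit_interval(self.p, "p"))
        if self.q is not None:
            q = _as_unit_interval(self.q, "q")
            if q.shape != self.p.shape:
                raise DomainError(
                    f"q has length {q.size} but p has length {self.p.size}"
                )
            object.__setattr__(self, "q", q)

    @property
    def n(self) -> int:
        return int(self.p.size)

    @property
    def has_q(self) -> bool:
        return self.q is not None

    @property
    def p_bar(self) -> float:
        return float(np.mean(self.p))

    def with_q(self, q: Sequence[float] | np.ndarray) -> "ParentPopulation":
        return ParentPopulation(p=self.p, q=np.asarray(q, dtype=float))


@dataclass(frozen=True)
class Transition:
    """A parent generation plus its realized offspring.

    Fitness is defined as ``w_i = offspring_counts_i / ploidy``.  Offspring
    bookkeeping is per parent: ``offspring_p[i]`` lists the p-scores of parent
    i's offspring (or successful gametes).  ``offspring_p=None`` denotes
    asexual transmission — every offspring inherits its parent's p-score
    exactly, which forces the transmission term E(wΔp) to vanish.

    ``expected_mode=True`` marks a deterministic infinite-population
    transition whose "counts" are model-predicted mean fitnesses; the
    integrality requirement on counts is relaxed for such transitions (they
    are necessarily asexual).
    """

    parents: ParentPopulation
    offspring_counts: np.ndarray
    ploidy: int = 1
    offspring_p: tuple[np.ndarray, ...] | None = None
    expected_mode: bool = False

    def __post_init__(self) -> None:
        counts = np.asarray(self.offspring_counts, dtype=float)
        if counts.shape != self.parents.p.shape:
            raise DomainError(
                f"offspring_counts has length {counts.size} "
                f"but population has {self.parents.n} parents"
            )
        if np.any(counts < 0):
            raise DomainError("offspring counts must be non-negative")
        if self.ploidy < 1:
            raise DomainError("ploidy must be a positive integer")
        if not self.expected_mode and not np.allclose(counts, np.round(counts)):
            raise DomainError(
                "offspring counts must be integers unless expected_mode=True"
            )
        object.__setattr__(self, "offspring_counts", counts)
        if self.offspring_p is not None:
            if self.expected_mode:
                raise DomainError("expected-mode transitions are asexual by construction")
            off = tuple(
                _as_unit_interval(o, f"offspring_p[{i}]")
                for i, o in enumerate(self.offspring_p)
            )
            if len(off) != self.parents.n:
                raise DomainError("offspring_p must list one entry per parent")
            for i, o in enumerate(off):
                if o.size != int(round(counts[i])):
                    raise DataError(
                        f"parent {i}: {o.size} offspring p-scores but "
                        f"offspring_count is {int(round(counts[i]))}"
                    )
            object.__setattr__(self, "offspring_p", off)

    @property
    def n(self) -> int:
        return self.parents.n

    @property
    def asexual(self) -> bool:
        return self.offspring_p is None

    @property
    def fitness(self) -> np.ndarray:
        """Realized fitness w_i = offspring count divided by ploidy."""
        return self.offspring_counts / self.ploidy

    def mean_offspring_p(self) -> np.ndarray:
        """Per-parent mean offspring p-score; a zero-fitness parent keeps its own p.

        The convention for childless parents is inconsequential downstream:
        every use multiplies by w_i, which is 0 for them.
        """
        if self.offspring_p is None:
            return self.parents.p.copy()
        out = self.parents.p.copy()
        for i, o in enumerate(self.offspring_p):
            if o.size:
                out[i] = float(np.mean(o))
        return out


def _sorted_terms(terms: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    return tuple(sorted(set((int(k), int(l)) for k, l in terms)))


@dataclass(frozen=True)
class ModelSpec:
    """An exponent-set fitness model ``w_i = Σ_{(k,l)∈E} β_{k,l} p_i^k q_i^l + ε_i``.

    ``terms`` is the set E of exponent pairs with non-zero coefficients;
    ``coefficients`` maps terms to their β values (absent for a spec that is
    to be fitted).  ``rule_terms`` is E′ = E \\ {(0,0), (1,0)}, the set over
    which the general selection rule sums r·b products.
    """

    terms: tuple[tuple[int, int], ...]
    coefficients: Mapping[tuple[int, int], float] | None = None

    def __post_init__(self) -> None:
        terms = _sorted_terms(self.terms)
        for k, l in terms:
            if k < 0 or l < 0:
                raise SpecError(f"exponents must be non-negative, got ({k}, {l})")
        object.__setattr__(self, "terms", terms)
        if self.coefficients is not None:
            coeffs = {(int(k), int(l)): float(v) for (k, l), v in self.coefficients.items()}
            extra = set(coeffs) - set(terms)
            if extra:
                raise SpecError(f"coefficients given for terms not in the spec: {sorted(extra)}")
            missing = set(terms) - set(coeffs)
            if missing:
                raise SpecError(f"missing coefficients for terms: {sorted(missing)}")
            object.__setattr__(self, "coefficients", coeffs)

    @property
    def rule_terms(self) -> tuple[tuple[int, int], ...]:
        """E′: the spec's terms minus the constant and the linear p-term."""
        return tuple(t for t in self.terms if t not in MANDATORY_TERMS)

    @property
    def is_social(self) -> bool:
        return any(l > 0 for _, l in self.terms)

    def with_coefficients(
        self, coefficients: Mapping[tuple[int, int], float]
    ) -> "ModelSpec":
        return ModelSpec(terms=self.terms, coefficients=coefficients)

    def without_coefficients(self) -> "ModelSpec":
        return ModelSpec(terms=self.terms)

    def predict(self, pop: ParentPopulation) -> np.ndarray:
        """Model-implied mean fitness μ_i = Σ β_{k,l} p_i^k q_i^l."""
        if self.coefficients is None:
            raise SpecError("spec has no coefficients; fit or supply them first")
        validate_spec(self, pop)
        mu = np.zeros(pop.n)
        for (k, l), beta in self.coefficients.items():
            col = pop.p**k if k else np.ones(pop.n)
            if l:
                col = col * pop.q**l
            mu += beta * col
        return mu

    @classmethod
    def from_string(cls, text: str) -> "ModelSpec":
        """Parse a comma-separated term string such as ``"1,p,q,p*q"`` or ``"1,p,p^2"``.

        Tokens: ``1`` (constant), ``p``/``p^k``, ``q``/``q^l``, and products
        like ``p^2*q`` — each token maps to one exponent pair (k, l).
        """
        terms = []
        for raw in text.split(","):
            tok = raw.strip()
            if not tok:
                continue
            k = l = 0
            for factor in tok.split("*"):
                factor = factor.strip()
                if factor == "1":
                    continue
                var, _, exp = factor.partition("^")
                power = int(exp) if exp else 1
                if var == "p":
                    k += power
                elif var == "q":
                    l += power
                else:
                    raise SpecError(f"unrecognized factor {factor!r} in term {tok!r}")
            terms.append((k, l))
        return cls(terms=tuple(terms))

    def to_string(self) -> str:
        parts = []
        for k, l in self.terms:
            factors = []
            if k == 1:
                factors.append("p")
            elif k > 1:
                factors.append(f"p^{k}")
            if l == 1:
                factors.append("q")
            elif l > 1:
                factors.append(f"q^{l}")
            parts.append("*".join(factors) if factors else "1")
        return ",".join(parts)


@dataclass(frozen=True)
class FittedModel:
    """A least-squares fit of a :class:`ModelSpec` to one transition.

    ``beta_hat`` holds the estimated coefficients, ``predicted_fitness`` the
    fitted values ŵ_i, ``residuals`` ε̂_i = w_i − ŵ_i, and ``standard_errors``
    the homoskedastic OLS standard errors (approximate under binomial noise).
    ``exact_fit`` flags residual sums of squares at machine zero, where
    standard errors degenerate to 0 and Wald statistics are infinite.
    """

    spec: ModelSpec
    beta_hat: dict[tuple[int, int], float]
    predicted_fitness: np.ndarray
    residuals: np.ndarray
    standard_errors: dict[tuple[int, int], float]
    df_resid: int
    exact_fit: bool = False

    @property
    def n(self) -> int:
        return int(self.predicted_fitness.size)

    def coefficient_spec(self) -> ModelSpec:
        """The spec with the fitted coefficients attached."""
        return self.spec.with_coefficients(self.beta_hat)


def make_grid_population(
    levels: Sequence[float], count_per_level: int
) -> ParentPopulation:
    """Population with ``count_per_level`` identical parents at each p-score level.

    Levels are placed in ascending order and individuals within a level keep
    their index order, so the layout is bit-reproducible.
    """
    if count_per_level < 1:
        raise DomainError("count_per_level must be >= 1")
    lv = _as_unit_interval(levels, "levels")
    p = np.repeat(np.sort(lv), count_per_level)
    return ParentPopulation(p=p)


def validate_spec(spec: ModelSpec, population: ParentPopulation) -> ModelSpec:
    """Check a spec's structural requirements against a population.

    A valid spec contains the constant term (0,0) and the linear p-term (1,0),
    and uses q-terms (l > 0) only when the population carries q-scores.
    """
    for term in MANDATORY_TERMS:
        if term not in spec.terms:
            raise SpecError(
                f"model spec must contain the exponent pair {term} "
                "(constant and linear p-term are mandatory)"
            )
    if not population.has_q and any(l > 0 for _, l in spec.terms):
        social = [t for t in spec.terms if t[1] > 0]
        raise DataError(
            f"spec contains q-terms {social} but the population has no q-scores"
        )
    return spec


def model_a() -> ModelSpec:
    """Linear non-social model: w = α + β₁p + ε (also Model 1)."""
    return ModelSpec(terms=((0, 0), (1, 0)))


def model_b() -> ModelSpec:
    """Quadratic non-social model: w = α + β₁p + β₂p² + ε."""
    return ModelSpec(terms=((0, 0), (1, 0), (2, 0)))


def nonsocial_model(degree: int) -> ModelSpec:
    """Degree-R polynomial non-social model: terms {(0,0), (1,0), ..., (R,0)}."""
    if degree < 1:
        raise SpecError("degree must be >= 1")
    return ModelSpec(terms=tuple((r, 0) for r in range(degree + 1)))


def model_1() -> ModelSpec:
    """Non-social linear model (identical to Model A)."""
    return model_a()


def model_2() -> ModelSpec:
    """Linear social model: w = α + β₁₀p + β₀₁q + ε."""
    return ModelSpec(terms=((0, 0), (0, 1), (1, 0)))


def model_3() -> ModelSpec:
    """Social model with interaction: w = α + β₁₀p + β₀₁q + β₁₁pq + ε."""
    return ModelSpec(terms=((0, 0), (0, 1), (1, 0), (1, 1)))
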