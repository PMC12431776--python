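"""Shared fixtures and randomized-input helpers."""

from __future__ import annotations

import numpy as np
import pytest

import genprice as gp

GRID_LEVELS = tuple(np.round(np.arange(0.0, 1.05, 0.1), 10))


@pytest.fixture
def grid11() -> gp.ParentPopulation:
    """One parent at each p-score 0, 0.1, ..., 1 (Var(p) = 0.10)."""
    return gp.make_grid_population(GRID_LEVELS, 1)


@pytest.fixture
def tiny_transition() -> gp.Transition:
    """Two parents p = (0, 1) with offspring counts (1, 2): w̄Δp̄ = 0.25."""
    return gp.Transition(
        parents=gp.ParentPopulation(p=np.array([0.0, 1.0])),
        offspring_counts=np.array([1.0, 2.0]),
    )


def random_transition(
    rng: np.random.Generator,
    n: int | None = None,
    social: bool = False,
    sexual: bool = False,
    ploidy: int = 1,
) -> gp.Transition:
    """An arbitrary valid transition: the identity suite must balance on anything."""
    if n is None:
        n = int(rng.integers(5, 40))
    p = rng.random(n)
    q = rng.random(n) if social else None
    counts = rng.poisson(2.0, size=n).astype(float) * ploidy
    if counts.sum() == 0:
        counts[int(rng.integers(0, n))] = ploidy
    offspring_p = None
    if sexual:
        offspring_p = tuple(rng.random(int(c)) for c in counts)
    return gp.Transition(
        parents=gp.ParentPopulation(p=p, q=q),
        offspring_counts=counts,
        ploidy=ploidy,
        offspring_p=offspring_p,
    )


def spec_menu(social: bool) -> list[gp.ModelSpec]:
    """Model specs spanning the linear/quadratic non-social family and the
    social family up to the interaction model, plus higher-order sets."""
    menu = [
        gp.model_a(),
        gp.model_b(),
        gp.nonsocial_model(3),
    ]
    if social:
        menu += [
            gp.model_2(),
            gp.model_3(),
            gp.ModelSpec(terms=((0, 0), (1, 0), (2, 0), (0, 1), (1, 1), (2, 1))),
            gp.ModelSpec(terms=((0, 0), (1, 0), (0, 2))),
        ]
    return menu
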