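"""CSV round-trip for populations and transitions, plus test-fixture generation.

Formats
-------
Population CSV: columns ``id,p,q`` (``q`` may be empty/absent), one row per
individual, header required.

Transition CSV: columns ``parent_id,p,q,offspring_count``.  Asexual
transitions need only this file; non-asexual transmission adds a companion
long-format file with columns ``parent_id,offspring_p`` holding one row per
offspring.  Non-integer offspring counts mark an expected-mode
(deterministic, infinite-population) transition.

Floats are written with Python's shortest round-trip ``repr``, so
write → read → write is byte-identical.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import (
    DataError,
    ParentPopulation,
    Transition,
)

__all__ = [
    "read_population",
    "write_population",
    "read_transition",
    "write_transition",
    "make_fixtures",
]


def _fmt(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_population(pop: ParentPopulation, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        out = csv.writer(fh)
        out.writerow(["id", "p", "q"])
        for i in range(pop.n):
            q = _fmt(pop.q[i]) if pop.has_q else ""
            out.writerow([i, _fmt(pop.p[i]), q])


def _parse_unit(value: str, name: str, line: int) -> float:
    try:
        x = float(value)
    except ValueError:
        raise DataError(f"line {line}: {name}={value!r} is not a number") from None
    if not 0.0 <= x <= 1.0:
        raise DataError(f"line {line}: {name}={x} outside [0, 1]")
    return x


def read_population(path: str | Path) -> ParentPopulation:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "p" not in df.columns or "id" not in df.columns:
        raise DataError(f"{path}: population CSV must have columns id,p[,q]")
    p, q = [], []
    has_q = "q" in df.columns and any(v.strip() for v in df["q"])
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        p.append(_parse_unit(row["p"], "p", line))
        if has_q:
            if not str(row["q"]).strip():
                raise DataError(f"line {line}: q present for some rows but empty here")
            q.append(_parse_unit(row["q"], "q", line))
    return ParentPopulation(
        p=np.array(p), q=np.array(q) if has_q else None
    )


def write_transition(
    t: Transition, path: str | Path, offspring_path: str | Path | None = None
) -> None:
    """Write the per-parent table and, for non-asexual transitions, the offspring file."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        out = csv.writer(fh)
        out.writerow(["parent_id", "p", "q", "offspring_count"])
        for i in range(t.n):
            q = _fmt(t.parents.q[i]) if t.parents.has_q else ""
            out.writerow([i, _fmt(t.parents.p[i]), q, _fmt(t.offspring_counts[i])])
    if not t.asexual:
        if offspring_path is None:
            raise DataError("non-asexual transition needs an offspring_path")
        with Path(offspring_path).open("w", newline="") as fh:
            out = csv.writer(fh)
            out.writerow(["parent_id", "offspring_p"])
            for i, kids in enumerate(t.offspring_p):
                for op in kids:
                    out.writerow([i, _fmt(op)])


def read_transition(
    path: str | Path, offspring_path: str | Path | None = None
) -> Transition:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"parent_id", "p", "offspring_count"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: transition CSV must have columns parent_id,p[,q],offspring_count")
    p, q, counts = [], [], []
    has_q = "q" in df.columns and any(v.strip() for v in df["q"])
    for idx, row in df.iterrows():
        line = idx + 2
        p.append(_parse_unit(row["p"], "p", line))
        if has_q:
            if not str(row["q"]).strip():
                raise DataError(f"line {line}: q present for some rows but empty here")
            q.append(_parse_unit(row["q"], "q", line))
        try:
            c = float(row["offspring_count"])
        except ValueError:
            raise DataError(
                f"line {line}: offspring_count={row['offspring_count']!r} is not a number"
            ) from None
        if c < 0:
            raise DataError(f"line {line}: negative offspring_count {c}")
        counts.append(c)
    counts_arr = np.array(counts)
    expected_mode = not np.allclose(counts_arr, np.round(counts_arr))
    pop = ParentPopulation(p=np.array(p), q=np.array(q) if has_q else None)

    offspring_p = None
    if offspring_path is not None and Path(offspring_path).exists():
        odf = pd.read_csv(offspring_path, dtype=str, keep_default_na=False)
        if not {"parent_id", "offspring_p"} <= set(odf.columns):
            raise DataError(f"{offspring_path}: needs columns parent_id,offspring_p")
        per_parent: list[list[float]] = [[] for _ in range(pop.n)]
        for idx, row in odf.iterrows():
            line = idx + 2
            try:
                pid = int(row["parent_id"])
            except ValueError:
                raise DataError(f"line {line}: bad parent_id {row['parent_id']!r}") from None
            if not 0 <= pid < pop.n:
                raise DataError(f"line {line}: parent_id {pid} not in the transition")
            per_parent[pid].append(_parse_unit(row["offspring_p"], "offspring_p", line))
        for pid, kids in enumerate(per_parent):
            if len(kids) != int(round(counts_arr[pid])):
                raise DataError(
                    f"parent_id {pid}: offspring file lists {len(kids)} p-scores "
                    f"but offspring_count is {int(round(counts_arr[pid]))}"
                )
        offspring_p = tuple(np.array(kids) for kids in per_parent)
    return Transition(
        parents=pop,
        offspring_counts=counts_arr,
        offspring_p=offspring_p,
        expected_mode=expected_mode,
    )


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write small reference inputs: a hand-computable transition, reduced
    panel transitions (100 parents per level), and a clone-matched social
    population at r = 0.5.
    """
    from .simulation import FIG1_PANELS, figure1_experiment, pair_partners
    from .model_core import make_grid_population

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tiny = Transition(
        parents=ParentPopulation(p=np.array([0.0, 1.0])),
        offspring_counts=np.array([1.0, 2.0]),
    )
    paths["tiny"] = outdir / "tiny_transition.csv"
    write_transition(tiny, paths["tiny"])

    for panel in FIG1_PANELS:
        t, _, _ = figure1_experiment(panel, seed=seed, count_per_level=100)
        key = f"panel_{panel}_small"
        paths[key] = outdir / f"{key}_transition.csv"
        write_transition(t, paths[key])

    grid = make_grid_population(np.round(np.arange(0, 1.05, 0.1), 10), 200)
    social = pair_partners(grid, r=0.5, seed=seed)
    paths["social_r05"] = outdir / "social_r05_population.csv"
    write_population(social, paths["social_r05"])
    return paths
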