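"""Rarefaction (retrospective power) analysis of CNA diversity.

Plots the cumulative number of *unique* CNAs against the cumulative
number of single cells, averaged over random cell orderings. A curve
that flattens indicates the sequenced cells already capture most of the
CNA diversity in the population; a steep final slope suggests further
sampling would reveal new events.

Two overlapping CNAs on the same chromosome count as the *same* event
iff both breakpoints agree within a tolerance (default 5 Mb) and their
total copy-number states are equal; under this reading an event is
never double-counted across cells. Pairwise sameness is not transitive,
so events are grouped into equivalence classes by transitive closure
(union-find) before counting. Events smaller than 5 Mb are excluded as
likely noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classify import BREAKPOINT_TOL, MIN_EVENT_SIZE, CnaEvent

__all__ = ["RarefactionCurve", "is_same_cna", "event_classes", "rarefy"]

#: Final-step mean increment below which a curve is called saturated.
SATURATION_INCREMENT = 0.5

#: Default number of random cell orderings.
DEFAULT_N_PERM = 100_000


@dataclass
class RarefactionCurve:
    """Mean/SD cumulative unique-CNA counts per number of cells."""

    k: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_permutations: int
    min_event_size: int
    breakpoint_tolerance: int
    saturated: bool

    @property
    def total_unique(self) -> float:
        return float(self.mean[-1]) if len(self.mean) else 0.0


def is_same_cna(e1: CnaEvent, e2: CnaEvent, tol: int = BREAKPOINT_TOL) -> bool:
    """Two CNAs are the same iff they overlap, both breakpoints lie
    within ``tol``, and their total copy-number states are equal."""
    if not e1.overlaps(e2):
        return False
    if abs(e1.start - e2.start) > tol or abs(e1.end - e2.end) > tol:
        return False
    return e1.cn_state == e2.cn_state


def event_classes(
    cells: list[list[CnaEvent]], tol: int = BREAKPOINT_TOL
) -> list[set[int]]:
    """Group all events into equivalence classes by transitive closure.

    Returns, per cell, the set of class ids its events belong to. The
    grouping is independent of input order: union-find with
    deterministic smallest-root merging over all pairwise
    :func:`is_same_cna` relations.
    """
    flat = [(ci, e) for ci, evs in enumerate(cells) for e in evs]
    n = len(flat)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            lo, hi = min(rx, ry), max(rx, ry)
            parent[hi] = lo

    for i in range(n):
        for j in range(i + 1, n):
            if is_same_cna(flat[i][1], flat[j][1], tol=tol):
                union(i, j)

    roots = sorted({find(i) for i in range(n)})
    class_of_root = {r: c for c, r in enumerate(roots)}
    per_cell: list[set[int]] = [set() for _ in cells]
    for i, (ci, _) in enumerate(flat):
        per_cell[ci].add(class_of_root[find(i)])
    return per_cell


def rarefy(
    cells: list[list[CnaEvent]],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    min_event_size: int = MIN_EVENT_SIZE,
    tol: int = BREAKPOINT_TOL,
) -> RarefactionCurve:
    """Cumulative unique-CNA saturation curve over random cell orderings.

    For each of ``n_perm`` permutations of the cells, counts how many
    new event classes each added cell contributes; reports mean and SD
    per cumulative cell count k. The value at k = n_cells is a set
    union and identical across permutations. Deterministic given seed.
    """
    if not cells:
        raise ValueError("need at least one cell")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    filtered = [[e for e in evs if e.size >= min_event_size] for evs in cells]
    if all(len(evs) == 0 for evs in filtered):
        warnings.warn("no events of sufficient size in any cell; flat curve", stacklevel=2)
        n = len(cells)
        return RarefactionCurve(
            k=np.arange(1, n + 1),
            mean=np.zeros(n),
            sd=np.zeros(n),
            n_permutations=n_perm,
            min_event_size=min_event_size,
            breakpoint_tolerance=tol,
            saturated=True,
        )

    classes = event_classes(filtered, tol=tol)
    n_classes = max(c for s in classes for c in s) + 1
    n_cells = len(cells)
    member = np.zeros((n_cells, n_classes), dtype=bool)
    for ci, s in enumerate(classes):
        member[ci, list(s)] = True

    # permutations in batches: cumulative-OR along the cell axis, then count
    sum_k = np.zeros(n_cells)
    sumsq_k = np.zeros(n_cells)
    batch = max(1, min(n_perm, 2_000_000 // max(n_cells * n_classes, 1)))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        orders = np.argsort(rng.random((b, n_cells)), axis=1)
        seen = np.maximum.accumulate(member[orders], axis=1)  # (b, n_cells, n_classes)
        counts = seen.sum(axis=2)  # (b, n_cells)
        sum_k += counts.sum(axis=0)
        sumsq_k += (counts.astype(np.int64) ** 2).sum(axis=0)
        done += b

    mean = sum_k / n_perm
    var = np.maximum(sumsq_k / n_perm - mean**2, 0.0)
    sd = np.sqrt(var)
    last_step = mean[-1] - mean[-2] if n_cells >= 2 else mean[-1]
    return RarefactionCurve(
        k=np.arange(1, n_cells + 1),
        mean=mean,
        sd=sd,
        n_permutations=n_perm,
        min_event_size=min_event_size,
        breakpoint_tolerance=tol,
        saturated=bool(last_step < SATURATION_INCREMENT),
    )
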