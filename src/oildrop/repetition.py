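"""Specificity-versus-repetition planning.

Two biological strategies reach the same goal: encode the recognition with
high per-attempt specificity p (an enzyme's substrate selection, a hormone
addressed to a selective receptor), or repeat a low-specificity attempt k
times and rely on at least one success (antibody mass production, seed
dispersal). With independent attempts the success probability is
1 − (1 − p)^k, and the planner finds the (p, k) pair reaching a target
success probability at minimum energy.

The energy model is deliberately minimal and isolated here: each attempt
costs ``base_cost`` plus ``specificity_cost`` per bit of coding burden
b(p) = −log2(1 − p) — each independent recognition element added to the
code halves the per-attempt failure probability, so b counts the elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InfeasibleError, InputError

__all__ = [
    "PKQuery", "PKPlan", "success_prob", "min_repetitions",
    "plan_energy", "optimize", "grid_rows",
]


@dataclass
class PKQuery:
    """A planning problem: candidate specificities, target, costs, repetition cap."""

    p_grid: list[float]
    target_success: float
    base_cost: float = 1.0
    specificity_cost: float = 1.0
    k_max: int = 10_000

    def validate(self) -> None:
        if not self.p_grid:
            raise InputError("p_grid must be non-empty")
        if any(not 0 < p < 1 for p in self.p_grid):
            raise InputError("every p must lie strictly in (0, 1)")
        if not 0 < self.target_success < 1:
            raise InputError("target_success must lie strictly in (0, 1)")
        if self.base_cost < 0 or self.specificity_cost < 0:
            raise InputError("costs must be non-negative")
        if self.k_max < 1:
            raise InputError("k_max must be >= 1")


@dataclass(frozen=True)
class PKPlan:
    """A chosen (p, k) pair with its achieved success probability and energy."""

    p: float
    k: int
    achieved: float
    energy: float


def success_prob(p: float, k: int) -> float:
    """Probability that at least one of k independent attempts succeeds."""
    if not 0 < p <= 1:
        raise InputError("p must lie in (0, 1]")
    if int(k) != k or k < 1:
        raise InputError("k must be an integer >= 1")
    return 1.0 - (1.0 - p) ** int(k)


def min_repetitions(p: float, target: float) -> int:
    """Smallest k with 1 − (1 − p)^k ≥ target.

    Computed as ⌈log(1 − target)/log(1 − p)⌉ and then verified by direct
    evaluation at k and k − 1 to absorb floating-point edge cases.
    """
    if not 0 < p < 1:
        raise InputError("p must lie strictly in (0, 1)")
    if not 0 < target < 1:
        raise InputError("target must lie strictly in (0, 1)")
    k = max(1, math.ceil(math.log1p(-target) / math.log1p(-p)))
    while k > 1 and success_prob(p, k - 1) >= target:
        k -= 1
    while success_prob(p, k) < target:
        k += 1
    return k


def coding_burden(p: float) -> float:
    """Bits of recognition coding needed for per-attempt specificity p."""
    if not 0 < p < 1:
        raise InputError("coding burden is defined for p in (0, 1) only")
    return -math.log2(1.0 - p)


def plan_energy(
    p: float, k: int, base_cost: float, specificity_cost: float
) -> float:
    """Total energy of k attempts at specificity p: k·(base + cost·b(p))."""
    if int(k) != k or k < 1:
        raise InputError("k must be an integer >= 1")
    return int(k) * (base_cost + specificity_cost * coding_burden(p))


def optimize(query: PKQuery) -> PKPlan:
    """Minimum-energy plan reaching the target success probability.

    For each candidate p the repetition count is the minimal feasible k;
    the cheapest plan wins, with ties broken toward smaller k, then
    smaller p. Raises :class:`InfeasibleError` when no candidate reaches
    the target within ``k_max`` repetitions.
    """
    query.validate()
    best: tuple[float, int, float] | None = None  # (energy, k, p)
    for p in query.p_grid:
        k = min_repetitions(p, query.target_success)
        if k > query.k_max:
            continue
        energy = plan_energy(p, k, query.base_cost, query.specificity_cost)
        key = (energy, k, p)
        if best is None or key < best:
            best = key
    if best is None:
        raise InfeasibleError(
            f"no p in the grid reaches {query.target_success} within "
            f"k_max={query.k_max} repetitions"
        )
    energy, k, p = best
    return PKPlan(p=p, k=k, achieved=success_prob(p, k), energy=energy)


def grid_rows(query: PKQuery) -> list[dict]:
    """Full (p, k, achieved, energy) table over the feasible grid, for export."""
    query.validate()
    rows = []
    for p in query.p_grid:
        k = min_repetitions(p, query.target_success)
        if k > query.k_max:
            continue
        rows.append(
            {
                "p": p,
                "k": k,
                "achieved": success_prob(p, k),
                "energy": plan_energy(p, k, query.base_cost, query.specificity_cost),
            }
        )
    return rows
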