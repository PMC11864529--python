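"""Maximal covering location problem (MCLP) solvers.

Select at most p candidate sites to maximize the total weight of demand
points covered within the service standard. In the canonical integer
program: maximize Σ w_i y_i subject to y_i ≤ Σ_j a_ij x_j and Σ_j x_j ≤ p,
with a_ij the binary coverage relation, x_j site-opening indicators and
y_i coverage indicators.

Two solvers: a greedy heuristic (largest uncovered-weight gain per step,
the classical (1 − 1/e)-approximation for this submodular objective) and
a bounded exhaustive exact search with lexicographic tie-breaking. A
search wrapper finds the smallest facility budget reaching a target
coverage fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from aedsim.coverage import CoverageMatrix

__all__ = [
    "MCLPProblem",
    "MCLPSolution",
    "MinFacilitiesResult",
    "solve_mclp_greedy",
    "solve_mclp_exact",
    "min_facilities_for_target",
]


@dataclass
class MCLPProblem:
    """An MCLP instance: coverage relation, demand weights, facility budget p."""

    coverage: CoverageMatrix
    p: int
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        n_demand, n_cand = self.coverage.a.shape
        if not (1 <= self.p <= n_cand):
            raise ValueError(f"p must be in [1, {n_cand}]")
        if self.weights is None:
            self.weights = np.ones(n_demand)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n_demand,):
            raise ValueError("weights length must equal demand count")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")


@dataclass
class MCLPSolution:
    """Selected sites, covered demand, and the covered weight achieved."""

    selected: list[str]
    covered: list[str]
    objective: float
    method: str  # greedy | exact
    optimal: bool


def _solution(problem: MCLPProblem, sel_idx: list[int], method: str, optimal: bool) -> MCLPSolution:
    a = problem.coverage.a
    covered_mask = a[:, sel_idx].any(axis=1) if sel_idx else np.zeros(a.shape[0], bool)
    cand_ids = problem.coverage.candidates.ids
    demand_ids = problem.coverage.demand.ids
    return MCLPSolution(
        selected=[cand_ids[j] for j in sel_idx],
        covered=[demand_ids[i] for i in np.flatnonzero(covered_mask)],
        objective=float(problem.weights[covered_mask].sum()),
        method=method,
        optimal=optimal,
    )


def solve_mclp_greedy(problem: MCLPProblem) -> MCLPSolution:
    """Greedy MCLP: repeatedly open the site covering the largest uncovered
    weight; ties break to the lowest candidate index; stops early when no
    site adds coverage. Marked optimal only when coverage is complete."""
    a = problem.coverage.a.astype(bool)
    w = problem.weights
    uncovered = np.ones(a.shape[0], dtype=bool)
    sel: list[int] = []
    for _ in range(problem.p):
        gains = (a & uncovered[:, None]).T @ w  # gain per candidate
        gains[sel] = -1.0
        j = int(np.argmax(gains))  # first max -> lowest index on ties
        if gains[j] <= 0:
            break
        sel.append(j)
        uncovered &= ~a[:, j]
    total_coverable = float(w.sum())
    sol = _solution(problem, sorted(sel), "greedy", optimal=False)
    if sol.objective == total_coverable:
        sol.optimal = True
    return sol


def solve_mclp_exact(problem: MCLPProblem, max_combinations: int = 10**6) -> MCLPSolution:
    """Exact MCLP by bounded exhaustive search over candidate subsets.

    Enumerates subsets of size 1..p in ascending size then lexicographic
    order, keeping the first strictly better objective — so the returned
    optimum is the smallest, lexicographically least site set. Raises when
    the subset count exceeds ``max_combinations``.
    """
    a = problem.coverage.a.astype(bool)
    w = problem.weights
    n_cand = a.shape[1]
    n_subsets = sum(math.comb(n_cand, k) for k in range(1, problem.p + 1))
    if n_subsets > max_combinations:
        raise ValueError(
            f"{n_subsets} subsets exceed the budget of {max_combinations}; "
            "use solve_mclp_greedy or raise max_combinations"
        )
    # weight covered by each subset via precomputed per-candidate masks
    best_obj = -1.0
    best_sel: list[int] = []
    for k in range(1, problem.p + 1):
        for combo in combinations(range(n_cand), k):
            obj = float(w[a[:, combo].any(axis=1)].sum())
            if obj > best_obj:
                best_obj, best_sel = obj, list(combo)
        if best_obj == float(w.sum()):
            break  # full coverage cannot be improved by larger subsets
    return _solution(problem, best_sel, "exact", optimal=True)


@dataclass
class MinFacilitiesResult:
    """Smallest facility budget reaching a target coverage fraction."""

    p: int
    solution: MCLPSolution
    target_met: bool


def min_facilities_for_target(
    coverage: CoverageMatrix,
    target_fraction: float,
    solver: str = "exact",
    weights: np.ndarray | None = None,
    max_combinations: int = 10**6,
) -> MinFacilitiesResult:
    """Search the smallest p whose MCLP objective reaches
    ``target_fraction`` of the total demand weight.

    When even opening every candidate cannot reach the target, the best
    attainable solution is returned with ``target_met=False``.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError("target_fraction must be in (0, 1]")
    if solver not in ("exact", "greedy"):
        raise ValueError(f"unknown solver {solver!r}")
    n_cand = coverage.a.shape[1]
    w = np.ones(coverage.a.shape[0]) if weights is None else np.asarray(weights, float)
    target = target_fraction * float(w.sum())
    sol = None
    for p in range(1, n_cand + 1):
        problem = MCLPProblem(coverage=coverage, p=p, weights=w)
        if solver == "exact":
            sol = solve_mclp_exact(problem, max_combinations=max_combinations)
        else:
            sol = solve_mclp_greedy(problem)
        if sol.objective >= target or math.isclose(sol.objective, target):
            return MinFacilitiesResult(p=len(sol.selected) or p, solution=sol, target_met=True)
    assert sol is not None
    return MinFacilitiesResult(p=n_cand, solution=sol, target_met=False)
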