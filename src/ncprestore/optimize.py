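"""Budget-constrained minimum weighted proportional-shortfall optimization.

The problem over planning units i and NCP features j:

    minimize    sum_j  w_j * y_j / t_j
    subject to  sum_i  x_i r_ij + y_j >= t_j      for all j
                sum_i  x_i c_i        <= B
                0 <= x_i <= 1,  y_j >= 0

x_i is the proportion of unit i's restorable area selected (continuous by
default; a binary mode is available), y_j the shortfall of feature j below
its target t_j, c_i the restorable area, B the area budget. Solved with the
HiGHS LP/MILP backend via scipy. A brute-force oracle (subset enumeration
in binary mode, fractional-knapsack greedy in single-feature proportional
mode) verifies the solver on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy import optimize as sco
from scipy import sparse

from .ncp import NCPFeature

__all__ = [
    "ProblemSpec",
    "Solution",
    "build_problem",
    "solve",
    "brute_force_oracle",
    "ncp_metrics",
    "evaluate_objective",
]

FEAS_TOL = 1e-6

#: weight assignment per plan; "integrated" splits weight at the NCP-group
#: level by default so 56 species features cannot outvote the single climate
#: or societal feature.
PLAN_WEIGHT_RULES = ("carbon-centric", "biodiversity-centric",
                     "people-centric", "integrated")


@dataclass
class ProblemSpec:
    """One optimization instance: weighted features, unit costs, budget."""

    features: list[NCPFeature]
    unit_costs: np.ndarray  # c_i, ha
    budget: float  # B, ha
    decision_mode: str = "proportional"  # or "binary"
    plan: str | None = None
    weight_mode: str = "group-equal"

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if self.decision_mode not in ("proportional", "binary"):
            raise ValueError(f"unknown decision_mode {self.decision_mode!r}")
        if not any(f.weight > 0 and f.target > 0 for f in self.features):
            raise ValueError("at least one feature must have weight > 0 and target > 0")

    @property
    def active(self) -> list[NCPFeature]:
        """Features that enter the objective (positive target)."""
        return [f for f in self.features if f.target > 0]


@dataclass
class Solution:
    x: np.ndarray  # [0,1]^I
    shortfalls: np.ndarray  # y_j >= 0, aligned with problem.active
    objective: float
    status: str  # "optimal" | "infeasible" | "error"
    delivered: np.ndarray  # per-active-feature sum_i x_i r_ij
    message: str = ""


def build_problem(features: list[NCPFeature], unit_costs: np.ndarray,
                  budget: float, plan: str,
                  decision_mode: str = "proportional",
                  weight_mode: str = "group-equal") -> ProblemSpec:
    """Attach plan weights to the features and validate the instance.

    Single-NCP plans give weight only to their own NCP; the integrated plan
    weights all three. ``group-equal`` gives each NCP group total weight 1
    (species share 1/N each); ``feature-equal`` gives every feature weight 1.
    """
    if plan not in PLAN_WEIGHT_RULES:
        raise ValueError(f"unknown plan {plan!r}; expected one of {PLAN_WEIGHT_RULES}")
    if weight_mode not in ("group-equal", "feature-equal"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    total_cost = float(np.asarray(unit_costs).sum())
    if budget > total_cost * (1 + FEAS_TOL):
        raise ValueError(f"budget {budget} exceeds total restorable area {total_cost}")
    n_species = sum(1 for f in features if f.kind == "species")
    per_species = (1.0 / n_species) if (n_species and weight_mode == "group-equal") else 1.0
    wanted = {
        "carbon-centric": {"climate"},
        "people-centric": {"societal"},
        "biodiversity-centric": {"species"},
        "integrated": {"climate", "societal", "species"},
    }[plan]
    weighted = []
    for f in features:
        if f.kind in wanted:
            w = per_species if f.kind == "species" else 1.0
        else:
            w = 0.0
        weighted.append(replace(f, weight=w))
    return ProblemSpec(
        features=weighted,
        unit_costs=np.asarray(unit_costs, dtype=float),
        budget=float(budget),
        decision_mode=decision_mode,
        plan=plan,
        weight_mode=weight_mode,
    )


def _matrices(problem: ProblemSpec):
    active = problem.active
    R = np.stack([f.contributions for f in active], axis=1)  # (n, m)
    t = np.array([f.target for f in active])
    w = np.array([f.weight for f in active])
    return active, R, t, w


def solve(problem: ProblemSpec) -> Solution:
    """Solve the shortfall LP (or MILP in binary mode) with HiGHS.

    Shortfalls are reported tight (``y_j = max(0, t_j - delivered_j)``)
    regardless of solver slack; the solver run is deterministic for a fixed
    problem, with residual degeneracy resolved by input ordering.
    """
    active, R, t, w = _matrices(problem)
    n, m = R.shape
    c = np.concatenate([np.zeros(n), w / t])
    # feature rows: -R x - y <= -t ; budget row: cost x <= B
    A = sparse.vstack([
        sparse.hstack([sparse.csr_matrix(-R.T), -sparse.identity(m)]),
        sparse.csr_matrix(np.concatenate([problem.unit_costs, np.zeros(m)])[None, :]),
    ])
    b_ub = np.concatenate([-t, [problem.budget]])
    lb = np.zeros(n + m)
    ub = np.concatenate([np.ones(n), np.full(m, np.inf)])
    if problem.decision_mode == "binary":
        integrality = np.concatenate([np.ones(n), np.zeros(m)])
        res = sco.milp(
            c=c,
            constraints=sco.LinearConstraint(A, -np.inf, b_ub),
            bounds=sco.Bounds(lb, ub),
            integrality=integrality,
        )
    else:
        res = sco.linprog(c, A_ub=A, b_ub=b_ub, bounds=np.column_stack([lb, ub]),
                          method="highs")
    if not res.success:
        status = "infeasible" if getattr(res, "status", None) == 2 else "error"
        return Solution(
            x=np.zeros(n), shortfalls=t.copy(), objective=float("nan"),
            status=status, delivered=np.zeros(m), message=str(res.message),
        )
    x = np.clip(res.x[:n], 0.0, 1.0)
    if problem.decision_mode == "binary":
        x = np.round(x)
    delivered = R.T @ x
    y = np.maximum(0.0, t - delivered)
    objective = float((w / t) @ y)
    return Solution(x=x, shortfalls=y, objective=objective, status="optimal",
                    delivered=delivered, message=str(res.message))


def evaluate_objective(problem: ProblemSpec, x: np.ndarray) -> float:
    """Weighted proportional shortfall of an arbitrary decision vector under
    this problem's weights (used for cross-plan dominance checks)."""
    _, R, t, w = _matrices(problem)
    y = np.maximum(0.0, t - R.T @ x)
    return float((w / t) @ y)


def brute_force_oracle(problem: ProblemSpec) -> float:
    """Reference optimum for small instances, independent of the LP path.

    Binary mode: exhaustive enumeration of all within-budget subsets
    (<= 12 units). Proportional mode: restricted to a single positively
    weighted feature, where filling units greedily by the ratio r_i / c_i
    is the exact fractional-knapsack optimum.
    """
    active, R, t, w = _matrices(problem)
    n, m = R.shape
    cost = problem.unit_costs
    if problem.decision_mode == "binary":
        if n > 12:
            raise ValueError("binary enumeration limited to 12 units")
        best = np.inf
        for bits in product((0, 1), repeat=n):
            x = np.array(bits, dtype=float)
            if x @ cost > problem.budget + FEAS_TOL:
                continue
            y = np.maximum(0.0, t - R.T @ x)
            best = min(best, float((w / t) @ y))
        return best
    weighted = [j for j in range(m) if w[j] > 0]
    if len(weighted) != 1:
        raise ValueError("proportional oracle requires exactly one weighted feature")
    j = weighted[0]
    r = R[:, j]
    # greedy ratio fill; zero-cost units with positive r are free
    deliver = float(r[cost <= 0].sum())
    pos = np.flatnonzero(cost > 0)
    order = pos[np.argsort(-(r[pos] / cost[pos]), kind="stable")]
    remaining = problem.budget
    for i in order:
        take = min(1.0, remaining / cost[i])
        if take <= 0:
            break
        deliver += take * r[i]
        remaining -= take * cost[i]
    y = max(0.0, t[j] - deliver)
    return float(w[j] * y / t[j])


def ncp_metrics(solution: Solution, problem: ProblemSpec,
                tol: float = FEAS_TOL) -> dict[str, float]:
    """Per-NCP delivery of a solution.

    climate: delivered tC; societal: delivered persons; biodiversity: the
    proportion of species features whose target is met within tolerance.
    """
    active = problem.active
    out = {"climate": 0.0, "societal": 0.0, "biodiversity": 0.0}
    n_species = met = 0
    for f, d, t in zip(active, solution.delivered,
                       (f.target for f in active)):
        if f.kind == "climate":
            out["climate"] += float(d)
        elif f.kind == "societal":
            out["societal"] += float(d)
        else:
            n_species += 1
            if d >= t * (1.0 - tol):
                met += 1
    # species features with zero target are trivially met and never active
    total_species = n_species + sum(
        1 for f in problem.features if f.kind == "species" and f.target <= 0
    )
    met += total_species - n_species
    out["biodiversity"] = met / total_species if total_species else float("nan")
    return out
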