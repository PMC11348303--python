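"""Plan × budget sweeps: accumulation curves, selection frequency, cessation.

The experiment solves one optimization per (plan, budget) over evenly
spaced budget increments up to the total restorable area — with the four
standard plans and 1% increments that is 400 problems. From each sweep it
derives per-NCP accumulation curves (delivered fraction vs. budget), the
per-unit selection frequency across budgets, and the cessation budget: the
smallest budget at which the plan's weighted shortfall objective reaches
zero, beyond which extra budget changes nothing for that plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import Landscape
from .ncp import NCPFeature
from .optimize import FEAS_TOL, ProblemSpec, Solution, build_problem, ncp_metrics, solve

__all__ = [
    "PLAN_NAMES",
    "PlanScheme",
    "SweepResult",
    "run_sweep",
    "accumulation_curves",
    "selection_frequency",
    "detect_cessation",
]

PLAN_NAMES = ("carbon-centric", "biodiversity-centric", "people-centric", "integrated")


@dataclass(frozen=True)
class PlanScheme:
    """A named weight assignment over features."""

    name: str
    weight_mode: str = "group-equal"

    def __post_init__(self) -> None:
        if self.name not in PLAN_NAMES:
            raise ValueError(f"plan name must be one of {PLAN_NAMES}, got {self.name!r}")


@dataclass
class SweepResult:
    plan: PlanScheme
    budgets_pct: np.ndarray  # strictly increasing, in (0, 100]
    budgets_ha: np.ndarray
    solutions: list[Solution]
    problems: list[ProblemSpec]
    metrics: list[dict[str, float]] = field(default_factory=list)
    cessation_budget_pct: float | None = None

    @property
    def objectives(self) -> np.ndarray:
        return np.array([s.objective for s in self.solutions])


def run_sweep(landscape: Landscape, features: list[NCPFeature],
              plans: list[PlanScheme], increments: int = 100,
              decision_mode: str = "proportional") -> list[SweepResult]:
    """Solve every (plan, budget) problem; budget b of ``increments`` means
    B = b/increments × Σ c_i. Any non-optimal solve aborts the sweep with
    the offending plan and budget named."""
    if increments < 1:
        raise ValueError("increments must be >= 1")
    costs = landscape.restorable_area
    total = float(costs.sum())
    budgets_pct = 100.0 * np.arange(1, increments + 1) / increments
    results = []
    for plan in plans:
        solutions, problems, metrics = [], [], []
        for b_pct in budgets_pct:
            B = b_pct / 100.0 * total
            prob = build_problem(features, costs, B, plan.name,
                                 decision_mode=decision_mode,
                                 weight_mode=plan.weight_mode)
            sol = solve(prob)
            if sol.status != "optimal":
                raise RuntimeError(
                    f"solver returned {sol.status} for plan {plan.name!r} at "
                    f"budget {b_pct:.1f}%: {sol.message}"
                )
            solutions.append(sol)
            problems.append(prob)
            metrics.append(ncp_metrics(sol, prob))
        res = SweepResult(
            plan=plan,
            budgets_pct=budgets_pct,
            budgets_ha=budgets_pct / 100.0 * total,
            solutions=solutions,
            problems=problems,
            metrics=metrics,
        )
        res.cessation_budget_pct = detect_cessation(res)
        results.append(res)
    return results


def accumulation_curves(sweep: SweepResult) -> dict[str, np.ndarray]:
    """Delivered fraction of each NCP vs. budget.

    Climate and societal are normalized by the maximum deliverable (the sum
    over all units); biodiversity is already the proportion of species whose
    target is met. An NCP whose maximum is zero is reported as NaN
    (undefined), not 0/0.
    """
    feats = sweep.problems[0].features
    max_per = {
        "climate": sum(f.max_deliverable for f in feats if f.kind == "climate"),
        "societal": sum(f.max_deliverable for f in feats if f.kind == "societal"),
    }
    curves: dict[str, np.ndarray] = {}
    for ncp in ("climate", "societal"):
        vals = np.array([m[ncp] for m in sweep.metrics])
        curves[ncp] = vals / max_per[ncp] if max_per[ncp] > 0 else np.full_like(vals, np.nan)
    curves["biodiversity"] = np.array([m["biodiversity"] for m in sweep.metrics])
    return curves


def selection_frequency(sweep: SweepResult, inclusion_threshold: float = 0.5
                        ) -> dict[str, np.ndarray]:
    """Per-unit inclusion across the sweep's budgets.

    ``count`` is the number of budgets at which x_i >= threshold (0..n
    budgets); ``fractional`` is Σ_b x_i^(b), which needs no inclusion
    convention for fractional decisions.
    """
    X = np.stack([s.x for s in sweep.solutions], axis=0)
    return {
        "count": (X >= inclusion_threshold).sum(axis=0),
        "fractional": X.sum(axis=0),
    }


def detect_cessation(sweep: SweepResult, tol: float = FEAS_TOL) -> float | None:
    """Smallest budget % with objective <= tol (all of the plan's weighted
    targets met); None if never reached within the sweep."""
    obj = sweep.objectives
    hit = np.flatnonzero(obj <= tol)
    if hit.size == 0:
        return None
    return float(sweep.budgets_pct[hit[0]])


def nestedness(sweep: SweepResult, inclusion_threshold: float = 0.5) -> np.ndarray:
    """Jaccard similarity of the selected-unit sets at consecutive budgets.

    Independent solves do not guarantee nested priorities; this measures
    how nested they turn out to be (1.0 everywhere = perfectly nested).
    """
    sets = [s.x >= inclusion_threshold for s in sweep.solutions]
    out = []
    for a, b in zip(sets[:-1], sets[1:]):
        union = np.logical_or(a, b).sum()
        inter = np.logical_and(a, b).sum()
        out.append(inter / union if union else 1.0)
    return np.array(out)
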