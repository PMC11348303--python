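"""Distributional equity of societal-NCP delivery.

Apportions the people reached by a restoration solution to demographic
groups (socioeconomically disadvantaged; women) through each unit's
subjurisdiction fractions, and compares the resulting beneficiary shares
against the population-weighted national averages. Beneficiaries scale
with the proportional decision x_i: a half-restored unit delivers half its
societal NCP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import Landscape
from .ncp import NCPFeature
from .optimize import Solution
from .sweep import SweepResult

__all__ = ["EquityReport", "beneficiaries", "national_average", "equity_report"]


@dataclass(frozen=True)
class EquityReport:
    plan: str
    budget_pct: float
    total_beneficiaries: float
    disadvantaged_beneficiaries: float
    women_beneficiaries: float
    frac_disadvantaged: float
    frac_women: float
    national_frac_disadvantaged: float
    national_frac_women: float
    above_average_disadvantaged: bool
    above_average_women: bool
    #: True when the budget falls at or below the biodiversity-centric
    #: cessation budget (the within-cessation report group)
    within_cessation: bool | None = None


def _group_fracs(landscape: Landscape) -> tuple[np.ndarray, np.ndarray]:
    by_id_d = {s.subjur_id: s.frac_disadvantaged for s in landscape.subjurisdictions}
    by_id_w = {s.subjur_id: s.frac_women for s in landscape.subjurisdictions}
    try:
        d = np.array([by_id_d[int(j)] for j in landscape.subjur_id])
        w = np.array([by_id_w[int(j)] for j in landscape.subjur_id])
    except KeyError as e:
        raise ValueError(f"unit mapped to unknown subjurisdiction {e.args[0]}") from e
    return d, w


def beneficiaries(solution: Solution, societal: NCPFeature,
                  landscape: Landscape) -> tuple[float, float, float]:
    """(total, disadvantaged, women) persons reached by a solution.

    total = Σ_i x_i r_i; group counts weight each unit's delivery by its
    subjurisdiction's group fraction.
    """
    d, w = _group_fracs(landscape)
    delivered = solution.x * societal.contributions
    total = float(delivered.sum())
    return total, float((delivered * d).sum()), float((delivered * w).sum())


def national_average(landscape: Landscape) -> tuple[float, float]:
    """Population-weighted national means of the two group fractions."""
    pop = np.array([s.population for s in landscape.subjurisdictions])
    if pop.sum() <= 0:
        raise ValueError("total population must be positive")
    d = np.array([s.frac_disadvantaged for s in landscape.subjurisdictions])
    w = np.array([s.frac_women for s in landscape.subjurisdictions])
    return float(d @ pop / pop.sum()), float(w @ pop / pop.sum())


def equity_report(sweeps: list[SweepResult], landscape: Landscape,
                  budgets_of_interest: list[float],
                  cessation_budget_pct: float | None = None
                  ) -> list[EquityReport]:
    """One report per (plan, requested budget).

    A requested budget not present in a sweep falls back to the nearest
    available one. Reports are grouped by whether the budget lies within
    the biodiversity-plan cessation budget when one is supplied.
    """
    nat_d, nat_w = national_average(landscape)
    reports = []
    for sweep in sweeps:
        societal = next(f for f in sweep.problems[0].features if f.kind == "societal")
        for b in budgets_of_interest:
            k = int(np.argmin(np.abs(sweep.budgets_pct - b)))
            total, dis, wom = beneficiaries(sweep.solutions[k], societal, landscape)
            fd = dis / total if total > 0 else float("nan")
            fw = wom / total if total > 0 else float("nan")
            reports.append(
                EquityReport(
                    plan=sweep.plan.name,
                    budget_pct=float(sweep.budgets_pct[k]),
                    total_beneficiaries=total,
                    disadvantaged_beneficiaries=dis,
                    women_beneficiaries=wom,
                    frac_disadvantaged=fd,
                    frac_women=fw,
                    national_frac_disadvantaged=nat_d,
                    national_frac_women=nat_w,
                    above_average_disadvantaged=bool(fd >= nat_d),
                    above_average_women=bool(fw >= nat_w),
                    within_cessation=(
                        None if cessation_budget_pct is None
                        else bool(sweep.budgets_pct[k] <= cessation_budget_pct)
                    ),
                )
            )
    return reports
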