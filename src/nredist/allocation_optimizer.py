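"""Constrained allocation of a fixed nitrogen budget across units and crops.

Two problems are solved over the per-(unit, crop) uniform fertilizer rates:

* maximize total calorie production subject to a global total-nitrogen
  budget (fertilizer plus biological fixation) and per-ha rate bounds;
* minimize total nitrogen input subject to a calorie-production floor.

Both are separable programs with a single coupling constraint.  When every
unit response is concave and non-decreasing on its feasible interval the
solver follows the equimarginal (KKT) structure exactly: rates are obtained
by bisecting on the shadow price of nitrogen, with each unit's rate the
point where its marginal calorie product equals the shadow price, clipped
to its bounds.  Non-concave responses fall back to SLSQP on normalized
variables; correctness in that regime is established against brute-force
oracles rather than by solver identity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize as sciopt

from .errors import InfeasibleError
from .response_model import UnitResponse

logger = logging.getLogger(__name__)

RateKey = tuple[int, str]


@dataclass
class Allocation:
    """Per-(unit, crop) synthetic-fertilizer rates in kg/ha."""

    rates: dict[RateKey, float]

    def as_array(self, keys: Sequence[RateKey]) -> np.ndarray:
        return np.array([self.rates[k] for k in keys], dtype=float)

    @classmethod
    def from_arrays(cls, keys: Sequence[RateKey], values: np.ndarray) -> "Allocation":
        return cls(dict(zip(keys, map(float, values))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(u, c, r) for (u, c), r in sorted(self.rates.items())],
            columns=["unit_id", "crop", "fert_rate_kg_ha"],
        )


class _Packed:
    """Vectorized view over a sorted collection of unit responses."""

    def __init__(self, responses: Sequence[UnitResponse]):
        self.responses = sorted(responses, key=lambda r: (r.unit_id, r.crop.name))
        self.keys: list[RateKey] = [
            (r.unit_id, r.crop.name) for r in self.responses
        ]
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("duplicate (unit, crop) responses")
        self.area = np.array([r.total_area_ha for r in self.responses])
        self.bnf = np.array([r.bnf_rate for r in self.responses])
        bounds = np.array([r.fert_bounds for r in self.responses])
        self.lb, self.ub = bounds[:, 0], bounds[:, 1]
        self.n = len(self.responses)

    def production(self, rates: np.ndarray) -> float:
        return float(
            sum(
                a * r.calorie_response(x)
                for a, r, x in zip(self.area, self.responses, rates)
            )
        )

    def production_grad(self, rates: np.ndarray) -> np.ndarray:
        return np.array(
            [
                a * r.marginal(x)
                for a, r, x in zip(self.area, self.responses, rates)
            ]
        )

    def marginals(self, rates: np.ndarray) -> np.ndarray:
        """Marginal calorie product per kg N for each (unit, crop)."""
        return np.array(
            [r.marginal(x) for r, x in zip(self.responses, rates)]
        )

    def fert_n(self, rates: np.ndarray) -> float:
        return float(self.area @ rates)

    @property
    def bnf_total(self) -> float:
        return float(self.area @ self.bnf)

    def all_concave(self) -> bool:
        return all(r.is_concave_nonneg() for r in self.responses)

    def cubic_coeffs(self) -> np.ndarray:
        return np.array([r.aggregated_cubic() for r in self.responses])


@dataclass
class OptimizationProblem:
    responses: Sequence[UnitResponse]
    objective: str  # "max_production" | "min_input"
    budget_kg: float | None = None  # total N incl. BNF (max_production)
    production_floor_gcal: float | None = None  # (min_input)
    init: Allocation | None = None
    tol_constraint: float = 1e-8  # relative
    tol_objective: float = 1e-10  # relative
    max_evaluations: int = 20000
    method: str = "auto"  # "auto" | "dual" | "slsqp"


@dataclass
class OptimizationResult:
    allocation: Allocation
    objective_value: float
    total_production_gcal: float
    total_n_kg: float  # incl. BNF
    fert_n_kg: float
    converged: bool
    n_evaluations: int
    method: str
    shadow_price: float | None = None
    kkt_report: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# public accounting helpers


def total_production(alloc: Allocation, responses: Sequence[UnitResponse]) -> float:
    """Total calorie production (Gcal) of an allocation."""
    tot = 0.0
    for r in responses:
        key = (r.unit_id, r.crop.name)
        if key in alloc.rates:
            tot += r.total_area_ha * r.calorie_response(alloc.rates[key])
    return tot


def total_n_input(
    alloc: Allocation,
    responses: Sequence[UnitResponse],
    include_bnf: bool = True,
) -> float:
    """Total nitrogen input (kg); optionally including biological fixation."""
    tot = 0.0
    for r in responses:
        key = (r.unit_id, r.crop.name)
        if key in alloc.rates:
            tot += r.total_area_ha * alloc.rates[key]
            if include_bnf:
                tot += r.total_area_ha * r.bnf_rate
    return tot


# ---------------------------------------------------------------------------
# dual (equimarginal) solver for the concave case


def _rates_at_price(packed: _Packed, cubics: np.ndarray, lam: float) -> np.ndarray:
    """Per-unit rate whose marginal equals ``lam``, clipped to bounds.

    Marginals are non-increasing on [lb, ub] in the concave regime, so the
    root is unique; vectorized bisection on the fertilizer rate.  ``cubics``
    are the aggregated unit cubics already expressed in the fertilizer rate.
    """

    def marg(r):
        return cubics[:, 1] + 2 * cubics[:, 2] * r + 3 * cubics[:, 3] * r**2

    m_lo, m_hi = marg(packed.lb), marg(packed.ub)
    lo, hi = packed.lb.copy(), packed.ub.copy()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        above = marg(mid) > lam
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    r = 0.5 * (lo + hi)
    r = np.where(m_lo <= lam, packed.lb, r)
    r = np.where(m_hi >= lam, packed.ub, r)
    return r


def _dual_max_production(
    packed: _Packed, fert_budget: float, tol_rel: float
) -> tuple[np.ndarray, float, int]:
    cubics = packed.cubic_coeffs()
    m_lo = (
        cubics[:, 1]
        + 2 * cubics[:, 2] * packed.lb
        + 3 * cubics[:, 3] * packed.lb**2
    )

    n_at = lambda lam: packed.fert_n(_rates_at_price(packed, cubics, lam))
    # satiation: if even a zero shadow price needs less than the budget,
    # marginal returns are exhausted and the budget binds slack
    if n_at(0.0) <= fert_budget * (1 + tol_rel):
        return _rates_at_price(packed, cubics, 0.0), 0.0, 1

    lam_lo, lam_hi = 0.0, float(np.max(m_lo)) + 1e-12
    evals = 1
    lam = lam_hi
    for _ in range(200):
        mid = 0.5 * (lam_lo + lam_hi)
        n = n_at(mid)
        evals += 1
        if n > fert_budget:
            lam_lo = mid
        else:
            lam_hi = mid  # feasible side: n ≤ budget
            if fert_budget - n <= 1e-4 * tol_rel * max(fert_budget, 1.0):
                break
        if lam_hi - lam_lo < 1e-16 * max(1.0, lam_hi):
            break
    lam = lam_hi  # n_at(lam_hi) ≤ budget by construction
    rates = _rates_at_price(packed, cubics, lam)
    return rates, lam, evals


def _dual_min_input(
    packed: _Packed, floor: float, tol_rel: float
) -> tuple[np.ndarray, float, int]:
    cubics = packed.cubic_coeffs()
    prod_at = lambda lam: packed.production(_rates_at_price(packed, cubics, lam))
    m_lo = (
        cubics[:, 1]
        + 2 * cubics[:, 2] * packed.lb
        + 3 * cubics[:, 3] * packed.lb**2
    )
    lam_top = float(np.max(m_lo)) + 1e-12  # all rates at lower bounds
    evals = 0
    if packed.production(packed.lb) >= floor:
        return packed.lb.copy(), lam_top, 1
    if prod_at(0.0) < floor * (1 - tol_rel):
        raise InfeasibleError(
            f"production floor {floor:.6g} Gcal exceeds the maximum "
            f"attainable {prod_at(0.0):.6g} Gcal at full rate bounds"
        )
    lam_lo, lam_hi = 0.0, lam_top
    for _ in range(200):
        lam = 0.5 * (lam_lo + lam_hi)
        p = prod_at(lam)
        evals += 1
        if p >= floor:
            lam_lo = lam
        else:
            lam_hi = lam
        if lam_hi - lam_lo < 1e-15 * max(1.0, lam_hi):
            break
    lam = lam_lo  # feasible side: production ≥ floor
    return _rates_at_price(packed, cubics, lam), lam, evals


# ---------------------------------------------------------------------------
# SLSQP fallback (non-concave responses)


def _slsqp(
    packed: _Packed,
    objective: str,
    fert_budget: float | None,
    floor: float | None,
    x0: np.ndarray,
    max_evaluations: int,
) -> tuple[np.ndarray, bool, int]:
    span = np.maximum(packed.ub - packed.lb, 1e-12)

    def denorm(z):
        return packed.lb + z * span

    scale_p = max(abs(packed.production(packed.ub)), 1.0)
    scale_n = max(packed.fert_n(packed.ub), 1.0)

    if objective == "max_production":
        fun = lambda z: -packed.production(denorm(z)) / scale_p
        jac = lambda z: -packed.production_grad(denorm(z)) * span / scale_p
        cons = [
            {
                "type": "ineq",
                "fun": lambda z: (fert_budget - packed.fert_n(denorm(z))) / scale_n,
                "jac": lambda z: -packed.area * span / scale_n,
            }
        ]
    else:
        fun = lambda z: packed.fert_n(denorm(z)) / scale_n
        jac = lambda z: packed.area * span / scale_n
        cons = [
            {
                "type": "ineq",
                "fun": lambda z: (packed.production(denorm(z)) - floor) / scale_p,
                "jac": lambda z: packed.production_grad(denorm(z)) * span / scale_p,
            }
        ]

    z0 = np.clip((x0 - packed.lb) / span, 0.0, 1.0)
    res = sciopt.minimize(
        fun,
        z0,
        jac=jac,
        bounds=[(0.0, 1.0)] * packed.n,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": max_evaluations, "ftol": 1e-12},
    )
    return denorm(np.clip(res.x, 0.0, 1.0)), bool(res.success), int(res.nit)


# ---------------------------------------------------------------------------
# public entry points


def _default_init_max(packed: _Packed, problem: OptimizationProblem,
                      fert_budget: float) -> np.ndarray:
    if problem.init is not None:
        x0 = np.clip(problem.init.as_array(packed.keys), packed.lb, packed.ub)
        n0 = packed.fert_n(x0)
        if n0 > fert_budget > 0:
            # uniform rescaling toward the bounds-respecting budget point
            lo_n = packed.fert_n(packed.lb)
            frac = (fert_budget - lo_n) / max(n0 - lo_n, 1e-300)
            x0 = packed.lb + np.clip(frac, 0.0, 1.0) * (x0 - packed.lb)
        return x0
    lo_n = packed.fert_n(packed.lb)
    hi_n = packed.fert_n(packed.ub)
    frac = np.clip((fert_budget - lo_n) / max(hi_n - lo_n, 1e-300), 0.0, 1.0)
    return packed.lb + frac * (packed.ub - packed.lb)


def optimize_max_production(problem: OptimizationProblem) -> OptimizationResult:
    """Maximize calorie production under a total-nitrogen budget."""
    packed = _Packed(problem.responses)
    if problem.budget_kg is None:
        raise ValueError("max_production requires budget_kg")
    fert_budget = problem.budget_kg - packed.bnf_total
    min_fert = packed.fert_n(packed.lb)
    if fert_budget < min_fert * (1 - 1e-12):
        raise InfeasibleError(
            f"budget {problem.budget_kg:.6g} kg (fertilizer share "
            f"{fert_budget:.6g} kg) is below the lower-bound requirement "
            f"{min_fert:.6g} kg: the per-ha rate floors are binding"
        )

    use_dual = problem.method in ("auto", "dual") and packed.all_concave()
    if problem.method == "dual" and not packed.all_concave():
        raise ValueError("dual method requires concave responses")
    if use_dual:
        rates, lam, evals = _dual_max_production(
            packed, fert_budget, problem.tol_constraint
        )
        converged, method = True, "dual"
    else:
        x0 = _default_init_max(packed, problem, fert_budget)
        rates, converged, evals = _slsqp(
            packed, "max_production", fert_budget, None, x0,
            problem.max_evaluations,
        )
        # enforce the budget exactly if SLSQP overshot within its own slack
        if packed.fert_n(rates) > fert_budget:
            lo_n = packed.fert_n(packed.lb)
            frac = (fert_budget - lo_n) / max(packed.fert_n(rates) - lo_n, 1e-300)
            rates = packed.lb + frac * (rates - packed.lb)
        lam = None
        method = "slsqp"

    prod = packed.production(rates)
    if problem.init is not None:
        init_rates = np.clip(
            problem.init.as_array(packed.keys), packed.lb, packed.ub
        )
        if packed.fert_n(init_rates) <= fert_budget * (1 + problem.tol_constraint):
            init_prod = packed.production(init_rates)
            if init_prod > prod * (1 + problem.tol_objective):
                logger.warning("optimizer returned below the initial point")
                converged = False
    fert = packed.fert_n(rates)
    return OptimizationResult(
        allocation=Allocation.from_arrays(packed.keys, rates),
        objective_value=prod,
        total_production_gcal=prod,
        total_n_kg=fert + packed.bnf_total,
        fert_n_kg=fert,
        converged=converged,
        n_evaluations=evals,
        method=method,
        shadow_price=lam,
    )


def optimize_min_input(problem: OptimizationProblem) -> OptimizationResult:
    """Minimize total nitrogen input under a calorie-production floor."""
    packed = _Packed(problem.responses)
    if problem.production_floor_gcal is None:
        raise ValueError("min_input requires production_floor_gcal")
    floor = problem.production_floor_gcal

    use_dual = problem.method in ("auto", "dual") and packed.all_concave()
    if use_dual:
        rates, lam, evals = _dual_min_input(
            packed, floor, problem.tol_constraint
        )
        converged, method = True, "dual"
    else:
        if packed.production(packed.ub) < floor * (1 - problem.tol_constraint):
            raise InfeasibleError(
                "production floor exceeds the maximum attainable at full bounds"
            )
        x0 = (
            np.clip(problem.init.as_array(packed.keys), packed.lb, packed.ub)
            if problem.init is not None
            else packed.ub.copy()
        )
        rates, converged, evals = _slsqp(
            packed, "min_input", None, floor, x0, problem.max_evaluations
        )
        lam = None
        method = "slsqp"

    fert = packed.fert_n(rates)
    prod = packed.production(rates)
    return OptimizationResult(
        allocation=Allocation.from_arrays(packed.keys, rates),
        objective_value=fert + packed.bnf_total,
        total_production_gcal=prod,
        total_n_kg=fert + packed.bnf_total,
        fert_n_kg=fert,
        converged=converged,
        n_evaluations=evals,
        method=method,
        shadow_price=lam,
    )


def kkt_equimarginal_check(
    result: OptimizationResult,
    responses: Sequence[UnitResponse],
    tol: float = 1e-3,
    bound_tol: float = 1e-6,
) -> pd.DataFrame:
    """Verify the equimarginal structure of a budget-constrained optimum.

    Interior (unit, crop) pairs must share a common marginal calorie
    product (the shadow price of nitrogen); pairs at their upper bound
    must have marginals at or above it, pairs at their lower bound at or
    below it.  Returns a per-pair report with a ``passes`` column; the
    check is skipped (all-NA report) when any response is non-concave.
    """
    packed = _Packed(responses)
    rates = result.allocation.as_array(packed.keys)
    report = pd.DataFrame(
        {
            "unit_id": [k[0] for k in packed.keys],
            "crop": [k[1] for k in packed.keys],
            "fert_rate_kg_ha": rates,
            "marginal_gcal_per_kg": packed.marginals(rates),
        }
    )
    if not packed.all_concave():
        logger.warning("KKT check skipped: non-concave responses present")
        report["status"] = "skipped"
        report["passes"] = pd.NA
        return report

    span = np.maximum(packed.ub - packed.lb, 1e-12)
    at_lb = rates <= packed.lb + bound_tol * span
    at_ub = rates >= packed.ub - bound_tol * span
    interior = ~(at_lb | at_ub)
    report["status"] = np.select(
        [interior, at_ub], ["interior", "upper_bound"], default="lower_bound"
    )

    m = report["marginal_gcal_per_kg"].to_numpy()
    if interior.any():
        lam = float(np.median(m[interior]))
    elif result.shadow_price is not None:
        lam = result.shadow_price
    else:
        lam = float(np.max(m[at_lb])) if at_lb.any() else float(np.min(m[at_ub]))
    scale = max(abs(lam), 1e-12)
    ok = np.empty(len(m), dtype=bool)
    ok[interior] = np.abs(m[interior] - lam) <= tol * scale
    ok[at_ub] = m[at_ub] >= lam - tol * scale
    ok[at_lb] = m[at_lb] <= lam + tol * scale
    report["passes"] = ok
    report.attrs["shadow_price"] = lam
    return report
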