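"""Scenario construction: optimization targets, reference distributions and
all reported summary quantities (production deltas, NUE, per-capita and
regional tables, ensemble uncertainty).

Three scenario families are supported, mirroring the analysis design:
(i) maximize production at the current total-nitrogen input, (ii) maximize
production at a reduced budget (a planetary-boundary share), and (iii)
minimize the nitrogen input that sustains current production.  Scenarios
are compared against the current distribution, an equal per-crop
distribution of the same budget, and an equal relative reduction of the
current distribution (for reduced budgets).

Budgets are total nitrogen (synthetic fertilizer plus biological fixation);
the optimizer's decision variables are fertilizer-only, so the fertilizer
budget is the scenario budget minus the global fixation total.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allocation_optimizer import (
    Allocation,
    OptimizationProblem,
    OptimizationResult,
    kkt_equimarginal_check,
    optimize_max_production,
    optimize_min_input,
    total_n_input,
    total_production,
)
from .crops import TG, get_crop
from .errors import InfeasibleError
from .response_model import ENSEMBLE, UnitResponse
from .synthetic_data import SyntheticWorld

logger = logging.getLogger(__name__)


@dataclass
class ScenarioSpec:
    """One scenario: an objective plus its budget or production floor.

    ``crop_budget_tg`` is the total-nitrogen budget (Tg/a, incl. BNF) for
    ``max_production``; ``production_floor`` is either the string
    ``"current"`` or an absolute Gcal value for ``min_input``.
    ``global_label_tg`` is purely descriptive (the global fixation total a
    crop budget was derived from) and is carried into outputs.
    """

    name: str
    objective: str  # "max_production" | "min_input"
    crop_budget_tg: float | None = None
    production_floor: str | float | None = None
    global_label_tg: float | None = None

    def __post_init__(self) -> None:
        if self.objective not in ("max_production", "min_input"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.objective == "max_production" and self.crop_budget_tg is None:
            raise ValueError(f"scenario {self.name}: crop_budget_tg required")
        if self.objective == "min_input" and self.production_floor is None:
            raise ValueError(f"scenario {self.name}: production_floor required")


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    table: pd.DataFrame  # per (unit, crop): rates, N, production, marginals
    totals: dict  # production_gcal, total_n_kg, fert_n_kg, nue
    references: dict[str, dict]  # name -> totals dict (+ allocation)
    deltas: dict[str, dict]  # name -> {production_gcal, total_n_kg, pct}
    optimization: OptimizationResult
    model_stats: pd.DataFrame | None = None


def nue(production_gcal: float, n_input_kg: float) -> float:
    """Nitrogen use efficiency in Gcal per kg N."""
    if n_input_kg <= 0:
        raise ValueError("nitrogen input must be positive for NUE")
    return production_gcal / n_input_kg


# ---------------------------------------------------------------------------
# reference allocations


def current_reference(world: SyntheticWorld) -> Allocation:
    """The world's current fertilizer distribution, bounds-checked."""
    alloc = Allocation(dict(world.current_allocation.rates))
    for (u, c), r in alloc.rates.items():
        cp = get_crop(c)
        b = world.unit_bnf_rate(u, c)
        lo, hi = max(0.0, cp.rate_min_total - b), cp.rate_max_total - b
        if not (lo - 1e-9 <= r <= hi + 1e-9):
            logger.warning(
                "current rate %.2f kg/ha for unit %s crop %s outside "
                "fertilizer bounds [%.2f, %.2f]", r, u, c, lo, hi
            )
    return alloc


def _unit_crop_frame(world: SyntheticWorld) -> pd.DataFrame:
    rows = []
    ds = world.grid
    units = ds["unit_id"].values
    for u in world.unit_ids:
        mask = units == u
        for c in world.crop_names:
            rows.append(
                (
                    int(u),
                    c,
                    float(ds["area_ha"].sel(crop=c).values[mask].sum()),
                    float(ds["bnf_rate"].sel(crop=c).values[mask][0]),
                )
            )
    return pd.DataFrame(rows, columns=["unit_id", "crop", "area_ha", "bnf_rate"])


def equal_reference(
    world: SyntheticWorld,
    crop_budgets: Mapping[str, float] | None = None,
) -> Allocation:
    """Equal per-crop total-N rate across all units, clamped to bounds.

    ``crop_budgets`` maps crop → total N in kg (incl. BNF); by default each
    crop keeps its current total.  Clamping-induced residual is
    redistributed by water-filling the common rate so the crop total is
    conserved; any clamping is logged.
    """
    from scipy.optimize import brentq

    uc = _unit_crop_frame(world)
    rates: dict[tuple[int, str], float] = {}
    for c in world.crop_names:
        cp = get_crop(c)
        sub = uc[uc["crop"] == c]
        area = sub["area_ha"].to_numpy()
        bnf = sub["bnf_rate"].to_numpy()
        lo = np.maximum(0.0, cp.rate_min_total - bnf)
        hi = cp.rate_max_total - bnf
        if crop_budgets is None:
            fert_target = world.crop_fert_total_kg(c)
        else:
            fert_target = crop_budgets[c] - float(area @ bnf)
        if fert_target >= float(area @ hi):
            logger.warning(
                "equal reference: crop %s target %.6g kg at/above the rate "
                "cap; all units clamped to the upper bound (residual %.6g kg)",
                c, fert_target, fert_target - float(area @ hi),
            )
            fert = hi.copy()
            clamped = np.ones_like(fert, dtype=bool)
        elif fert_target <= float(area @ lo):
            logger.warning(
                "equal reference: crop %s target %.6g kg at/below the rate "
                "floor; all units clamped to the lower bound (residual %.6g kg)",
                c, fert_target, fert_target - float(area @ lo),
            )
            fert = lo.copy()
            clamped = np.ones_like(fert, dtype=bool)
        else:

            def tot(big_r):  # big_r: common total-N rate
                return float(area @ np.clip(big_r - bnf, lo, hi)) - fert_target

            r_uniform = brentq(tot, 0.0, cp.rate_max_total + 1e-6, xtol=1e-12)
            fert = np.clip(r_uniform - bnf, lo, hi)
            clamped = (fert <= lo + 1e-12) | (fert >= hi - 1e-12)
            if clamped.any():
                logger.info(
                    "equal reference: crop %s common rate %.2f kg/ha clamped "
                    "for %d/%d units; residual redistributed", c, r_uniform,
                    int(clamped.sum()), len(fert),
                )
            # close any remaining residual on unclamped units
            free = ~clamped
            resid = fert_target - float(area @ fert)
            if free.any() and area[free].sum() > 0:
                fert[free] += resid / area[free].sum()
        for u, r in zip(sub["unit_id"], np.clip(fert, lo, hi)):
            rates[(int(u), c)] = float(r)
    return Allocation(rates)


def scaled_current_reference(
    world: SyntheticWorld,
    crop_budgets: Mapping[str, float],
) -> Allocation:
    """Equal relative reduction: every unit's fertilizer rate scaled by one
    factor per crop, then clamped to bounds (residual logged, not moved)."""
    uc = _unit_crop_frame(world)
    rates: dict[tuple[int, str], float] = {}
    for c in world.crop_names:
        cp = get_crop(c)
        sub = uc[uc["crop"] == c]
        area = sub["area_ha"].to_numpy()
        bnf = sub["bnf_rate"].to_numpy()
        lo = np.maximum(0.0, cp.rate_min_total - bnf)
        hi = cp.rate_max_total - bnf
        cur = np.array(
            [world.current_allocation.rates[(int(u), c)] for u in sub["unit_id"]]
        )
        cur_tot = float(area @ cur)
        if cur_tot <= 0:
            raise InfeasibleError(f"crop {c}: zero current fertilizer total")
        fert_target = crop_budgets[c] - float(area @ bnf)
        factor = fert_target / cur_tot
        fert = np.clip(factor * cur, lo, hi)
        resid = float(area @ fert) - fert_target
        if abs(resid) > 1e-9 * max(fert_target, 1.0):
            logger.info(
                "scaled-current reference: crop %s factor %.4f leaves a "
                "clamping residual of %.6g kg", c, factor, resid,
            )
        for u, r in zip(sub["unit_id"], fert):
            rates[(int(u), c)] = float(r)
    return Allocation(rates)


# ---------------------------------------------------------------------------
# scenario execution


def crop_budget_split(world: SyntheticWorld, budget_tg: float) -> dict[str, float]:
    """Split a global total-N budget across crops by current total-N shares."""
    cur = {
        c: world.crop_fert_total_kg(c) + world.bnf_total_kg(c)
        for c in world.crop_names
    }
    total = sum(cur.values())
    return {c: budget_tg * TG * v / total for c, v in cur.items()}


def _totals(alloc: Allocation, responses: Sequence[UnitResponse]) -> dict:
    prod = total_production(alloc, responses)
    n_tot = total_n_input(alloc, responses, include_bnf=True)
    return {
        "production_gcal": prod,
        "total_n_kg": n_tot,
        "fert_n_kg": total_n_input(alloc, responses, include_bnf=False),
        "nue_gcal_per_kg": nue(prod, n_tot),
    }


def run_scenario(
    spec: ScenarioSpec,
    world: SyntheticWorld,
    per_model: bool = False,
    per_model_mode: str = "reoptimize",  # or "evaluate"
    method: str = "auto",
) -> ScenarioResult:
    """Run one scenario on the ensemble-mean responses (optionally per model)."""
    responses = world.unit_responses(ENSEMBLE)
    current = current_reference(world)
    cur_totals = _totals(current, responses)

    def solve(resp: Sequence[UnitResponse]) -> OptimizationResult:
        if spec.objective == "max_production":
            budget = spec.crop_budget_tg * TG
            problem = OptimizationProblem(
                resp, "max_production", budget_kg=budget, init=current,
                method=method,
            )
            try:
                return optimize_max_production(problem)
            except InfeasibleError as e:
                raise InfeasibleError(f"scenario {spec.name}: {e}") from e
        floor = (
            total_production(current, resp)
            if spec.production_floor == "current"
            else float(spec.production_floor)
        )
        problem = OptimizationProblem(
            resp, "min_input", production_floor_gcal=floor, init=current,
            method=method,
        )
        try:
            return optimize_min_input(problem)
        except InfeasibleError as e:
            raise InfeasibleError(f"scenario {spec.name}: {e}") from e

    result = solve(responses)

    # references at the scenario's operative budget
    if spec.objective == "max_production":
        budgets = crop_budget_split(world, spec.crop_budget_tg)
    else:
        budgets = crop_budget_split(world, result.total_n_kg / TG)
    refs: dict[str, dict] = {"current": {**cur_totals, "allocation": current}}
    eq = equal_reference(world, budgets)
    refs["equal"] = {**_totals(eq, responses), "allocation": eq}
    sc = scaled_current_reference(world, budgets)
    refs["scaled_current"] = {**_totals(sc, responses), "allocation": sc}

    totals = _totals(result.allocation, responses)
    deltas = {
        name: {
            "production_gcal": totals["production_gcal"] - r["production_gcal"],
            "total_n_kg": totals["total_n_kg"] - r["total_n_kg"],
            "production_pct": 100.0
            * (totals["production_gcal"] / r["production_gcal"] - 1.0),
        }
        for name, r in refs.items()
    }

    kkt = kkt_equimarginal_check(result, responses)
    by_key = {
        (r.unit_id, r.crop.name): r for r in responses
    }
    rows = []
    for (u, c), rate in sorted(result.allocation.rates.items()):
        r = by_key[(u, c)]
        rows.append(
            {
                "unit_id": u,
                "crop": c,
                "fert_rate_kg_ha": rate,
                "current_rate_kg_ha": current.rates[(u, c)],
                "area_ha": r.total_area_ha,
                "bnf_rate_kg_ha": r.bnf_rate,
                "total_n_kg": r.total_area_ha * (rate + r.bnf_rate),
                "current_n_kg": r.total_area_ha
                * (current.rates[(u, c)] + r.bnf_rate),
                "production_gcal": r.total_area_ha * r.calorie_response(rate),
                "current_production_gcal": r.total_area_ha
                * r.calorie_response(current.rates[(u, c)]),
            }
        )
    table = pd.DataFrame(rows)
    table["marginal_gcal_per_kg"] = kkt["marginal_gcal_per_kg"].to_numpy()

    model_stats = None
    if per_model:
        recs = []
        for m in world.model_ids:
            resp_m = world.unit_responses(m)
            if per_model_mode == "reoptimize":
                res_m = solve(resp_m)
                alloc_m, prod_m = res_m.allocation, res_m.total_production_gcal
                n_m = res_m.total_n_kg
            else:
                alloc_m = result.allocation
                prod_m = total_production(alloc_m, resp_m)
                n_m = total_n_input(alloc_m, resp_m, include_bnf=True)
            recs.append(
                {
                    "model": m,
                    "production_gcal": prod_m,
                    "total_n_kg": n_m,
                    "nue_gcal_per_kg": nue(prod_m, n_m),
                }
            )
        model_stats = pd.DataFrame(recs).set_index("model")
        n_mod = len(model_stats)
        summary = {
            "mean": model_stats.mean(),
            "min": model_stats.min(),
            "max": model_stats.max(),
            "se": model_stats.std(ddof=1) / np.sqrt(n_mod),
        }
        model_stats = pd.concat(
            [model_stats, pd.DataFrame(summary).T]
        )

    return ScenarioResult(
        spec=spec,
        table=table,
        totals=totals,
        references=refs,
        deltas=deltas,
        optimization=result,
        model_stats=model_stats,
    )


# ---------------------------------------------------------------------------
# summary tables


def regional_summary(
    result: ScenarioResult, region_map: pd.DataFrame
) -> pd.DataFrame:
    """Per-region production and input deltas, ordered by decreasing |gain|."""
    t = result.table.merge(
        region_map[["unit_id", "region", "continent"]], on="unit_id"
    )
    g = t.groupby(["region", "continent"], as_index=False).agg(
        production_gcal=("production_gcal", "sum"),
        current_production_gcal=("current_production_gcal", "sum"),
        total_n_kg=("total_n_kg", "sum"),
        current_n_kg=("current_n_kg", "sum"),
    )
    g["production_delta_gcal"] = (
        g["production_gcal"] - g["current_production_gcal"]
    )
    g["n_delta_kg"] = g["total_n_kg"] - g["current_n_kg"]
    g = g.sort_values(
        "production_delta_gcal", key=lambda s: s.abs(), ascending=False
    ).reset_index(drop=True)
    return g


def per_capita(
    result: ScenarioResult,
    population: pd.Series,
    fi_prevalence: pd.Series | None = None,
    fi_threshold: float = 50.0,
) -> pd.DataFrame:
    """Per-unit production per capita under the scenario vs the current
    distribution; units with missing/zero population are flagged and
    excluded from aggregates.

    When ``fi_prevalence`` is given, an aggregate row ``fi_above_threshold``
    summarizes the units whose food-insecurity prevalence strictly exceeds
    ``fi_threshold`` (%) — production summed over units, then divided by
    their summed population.
    """
    t = result.table.groupby("unit_id", as_index=True).agg(
        production_gcal=("production_gcal", "sum"),
        current_production_gcal=("current_production_gcal", "sum"),
        total_n_kg=("total_n_kg", "sum"),
        current_n_kg=("current_n_kg", "sum"),
    )
    pop = population.reindex(t.index)
    t["population"] = pop
    t["excluded"] = ~(pop > 0)
    if t["excluded"].any():
        logger.warning(
            "per_capita: %d units with missing/zero population excluded",
            int(t["excluded"].sum()),
        )
    ok = ~t["excluded"]
    t.loc[ok, "percap_gcal"] = t.loc[ok, "production_gcal"] / pop[ok]
    t.loc[ok, "current_percap_gcal"] = (
        t.loc[ok, "current_production_gcal"] / pop[ok]
    )
    out = t.reset_index()
    if fi_prevalence is not None:
        fi = fi_prevalence.reindex(out["unit_id"]).to_numpy()
        grp = ok.to_numpy() & (fi > fi_threshold)
        if grp.any():
            sel = out[grp]
            row = {
                "unit_id": -1,
                "production_gcal": sel["production_gcal"].sum(),
                "current_production_gcal": sel["current_production_gcal"].sum(),
                "total_n_kg": sel["total_n_kg"].sum(),
                "current_n_kg": sel["current_n_kg"].sum(),
                "population": sel["population"].sum(),
                "excluded": False,
                "percap_gcal": sel["production_gcal"].sum()
                / sel["population"].sum(),
                "current_percap_gcal": sel["current_production_gcal"].sum()
                / sel["population"].sum(),
            }
            out = pd.concat(
                [out, pd.DataFrame([row], index=["fi_above_threshold"])]
            )
    return out
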