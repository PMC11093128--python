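"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from nredist import WorldConfig, generate_world
from nredist.crops import get_crop
from nredist.response_model import UnitResponse


def make_quadratic_response(
    unit_id: int,
    crop: str = "maize",
    a: float = 0.1,
    b: float = 1e-4,
    area: float = 1.0,
    bnf: float = 0.0,
) -> UnitResponse:
    """Concave quadratic calorie response g(t) = a·t − b·t² (Gcal/ha in
    total N); concave and increasing on [0, 200] whenever a > 400·b."""
    return UnitResponse(
        unit_id=unit_id,
        crop=get_crop(crop),
        model_id="ensemble",
        coeffs=np.array([[0.0, a, -b, 0.0]]),
        areas=np.array([area]),
        bnf_rate=bnf,
    )


def grid_search_max_production(responses, budget_fert_kg: float) -> float:
    """Exhaustive 1 kg/ha grid optimum for max-production (DP knapsack).

    Exact on the grid for separable objectives: rates are enumerated at
    1 kg/ha steps and the budget tracked in integer kg, which requires
    integer areas.  Independent of the solver under test.
    """
    areas = [int(round(r.total_area_ha)) for r in responses]
    assert all(abs(a - r.total_area_ha) < 1e-9 for a, r in zip(areas, responses))
    b_max = int(np.floor(budget_fert_kg + 1e-9))
    dp = np.full(b_max + 1, -np.inf)
    dp[0] = 0.0
    dp[:] = -np.inf
    dp[0] = 0.0
    for r, a in zip(responses, areas):
        lo, hi = r.fert_bounds
        rates = np.arange(int(np.ceil(lo - 1e-9)), int(np.floor(hi + 1e-9)) + 1)
        vals = a * r.calorie_response(rates.astype(float))
        new = np.full_like(dp, -np.inf)
        for rate, val in zip(rates, vals):
            cost = a * rate
            if cost > b_max:
                continue
            shifted = dp[: b_max + 1 - cost] + val
            new[cost:] = np.maximum(new[cost:], shifted)
        dp = new
    return float(np.max(dp))


def grid_search_min_input(responses, floor_gcal: float) -> float:
    """Exhaustive 1 kg/ha grid minimum total fertilizer meeting a
    production floor; full enumeration for exactly two responses."""
    assert len(responses) == 2
    (r1, r2) = responses
    g1 = np.arange(np.ceil(r1.fert_bounds[0]), np.floor(r1.fert_bounds[1]) + 1)
    g2 = np.arange(np.ceil(r2.fert_bounds[0]), np.floor(r2.fert_bounds[1]) + 1)
    p1 = r1.total_area_ha * r1.calorie_response(g1)
    p2 = r2.total_area_ha * r2.calorie_response(g2)
    prod = p1[:, None] + p2[None, :]
    cost = (r1.total_area_ha * g1)[:, None] + (r2.total_area_ha * g2)[None, :]
    ok = prod >= floor_gcal
    assert ok.any(), "floor unreachable on the grid"
    return float(cost[ok].min())


@pytest.fixture(scope="session")
def small_world():
    """A 25-unit default world shared by read-only tests."""
    return generate_world(WorldConfig(seed=11, n_units=25))


@pytest.fixture(scope="session")
def skewed_world():
    """A strongly input-skewed world (input concentrated in wealthy,
    food-secure units)."""
    return generate_world(WorldConfig(seed=0, n_units=200, input_skew=2.0))
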