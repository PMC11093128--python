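"""Nitrogen–yield response functions and their spatial/ensemble aggregation.

A grid cell carries a cubic polynomial mapping total nitrogen (kg/ha) to
yield (t DM/ha) for one crop, water regime and crop model.  Cells are
aggregated to administrative units as harvested-area-weighted means of their
calorie responses; because every member pixel of a unit receives the same
uniform fertilizer rate, unit-level aggregation is lossless with respect to
pixel-level accounting.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .crops import CropParams, N_DOMAIN_MAX, get_crop
from .errors import DegenerateUnitError, DomainError

ENSEMBLE = "ensemble"  # pseudo model id for the equal-weight ensemble mean


@dataclass
class GridCellResponse:
    """One pixel × crop × water-regime × model nitrogen→yield function.

    ``poly_coeffs`` are increasing-order cubic coefficients (c0..c3) of
    yield in t DM/ha as a function of *total* nitrogen in kg/ha; evaluated
    yields are clamped at zero.  ``bnf_rate`` is the biological-fixation
    contribution in kg/ha (nonzero only for rice).
    """

    pixel_id: int
    unit_id: int
    crop: str
    water_regime: str
    model_id: str
    poly_coeffs: np.ndarray
    area_ha: float
    bnf_rate: float = 0.0

    def __post_init__(self) -> None:
        self.poly_coeffs = np.asarray(self.poly_coeffs, dtype=float)
        if self.poly_coeffs.shape != (4,):
            raise ValueError("poly_coeffs must have exactly 4 entries")
        if self.area_ha < 0:
            raise ValueError("area_ha must be non-negative")


def evaluate_pixel_yield(cell: GridCellResponse, fert_rate: float) -> float:
    """Yield (t DM/ha) at a synthetic-fertilizer rate, clamped at zero.

    The polynomial is evaluated at total N = fertilizer + BNF, which must
    lie inside the emulation domain [0, 200] kg/ha.
    """
    total_n = fert_rate + cell.bnf_rate
    if not (0.0 <= total_n <= N_DOMAIN_MAX):
        raise DomainError(
            f"total N {total_n:.3f} kg/ha outside valid domain "
            f"[0, {N_DOMAIN_MAX:g}] for pixel {cell.pixel_id}"
        )
    c = cell.poly_coeffs
    y = c[0] + total_n * (c[1] + total_n * (c[2] + total_n * c[3]))
    return float(max(y, 0.0))


def yield_to_calories(y: float, crop: CropParams) -> float:
    """Convert yield (t DM/ha) to calorie production (Gcal/ha)."""
    if np.any(np.asarray(y) < 0):
        raise ValueError("yield must be non-negative")
    return y * crop.calorie_coeff


@dataclass
class UnitResponse:
    """Aggregated per-unit, per-crop calorie response to a uniform rate.

    ``coeffs`` holds one row of increasing-order cubic coefficients per
    member pixel-row (pixel × regime), already converted to Gcal/ha as a
    function of total N; ``areas`` are the matching harvested areas.  The
    response to a fertilizer rate r is the area-weighted mean of the
    member polynomials at total N = r + bnf_rate, each clamped at zero.
    Keeping the member polynomials (rather than a single pre-averaged
    curve) preserves exact derivative access and the clamping semantics.
    """

    unit_id: int
    crop: CropParams
    model_id: str
    coeffs: np.ndarray  # (n_members, 4), Gcal/ha vs total N
    areas: np.ndarray  # (n_members,)
    bnf_rate: float  # kg/ha, uniform within the unit

    total_area_ha: float = field(init=False)

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        self.areas = np.asarray(self.areas, dtype=float)
        self.total_area_ha = float(self.areas.sum())
        if self.total_area_ha <= 0:
            raise DegenerateUnitError(
                f"unit {self.unit_id}/{self.crop.name}: zero total area"
            )

    @property
    def mean_bnf_rate(self) -> float:
        return self.bnf_rate

    @property
    def fert_bounds(self) -> tuple[float, float]:
        """Bounds on the *fertilizer* rate implied by the total-N bounds."""
        lo = max(0.0, self.crop.rate_min_total - self.bnf_rate)
        hi = self.crop.rate_max_total - self.bnf_rate
        return lo, hi

    def _member_values(self, fert_rate) -> np.ndarray:
        t = np.atleast_1d(np.asarray(fert_rate, dtype=float)) + self.bnf_rate
        c = self.coeffs
        y = (
            c[:, 0][:, None]
            + np.outer(c[:, 1], t)
            + np.outer(c[:, 2], t**2)
            + np.outer(c[:, 3], t**3)
        )
        return np.maximum(y, 0.0)

    def calorie_response(self, fert_rate):
        """Gcal/ha at a uniform fertilizer rate (scalar or array)."""
        t = np.asarray(fert_rate, dtype=float) + self.bnf_rate
        if np.any(t < -1e-9) or np.any(t > N_DOMAIN_MAX + 1e-9):
            raise DomainError(
                f"total N outside [0, {N_DOMAIN_MAX:g}] for unit "
                f"{self.unit_id}/{self.crop.name}"
            )
        y = self._member_values(fert_rate)
        w = self.areas / self.total_area_ha
        out = w @ y
        return float(out[0]) if np.ndim(fert_rate) == 0 else out

    def marginal(self, fert_rate):
        """d(Gcal/ha)/d(kg N/ha); clamped members contribute zero."""
        t = np.atleast_1d(np.asarray(fert_rate, dtype=float)) + self.bnf_rate
        c = self.coeffs
        dy = (
            c[:, 1][:, None]
            + 2.0 * np.outer(c[:, 2], t)
            + 3.0 * np.outer(c[:, 3], t**2)
        )
        active = self._member_values(fert_rate) > 0.0
        w = self.areas / self.total_area_ha
        out = w @ (dy * active)
        return float(out[0]) if np.ndim(fert_rate) == 0 else out

    def aggregated_cubic(self) -> np.ndarray:
        """Area-weighted mean cubic in the *fertilizer* rate (no clamping).

        Valid whenever no member polynomial goes negative on the feasible
        interval; used by the concave fast path of the optimizer.
        """
        b = self.bnf_rate
        c = self.coeffs
        # shift variable: total N = r + b
        shifted = np.empty_like(c)
        shifted[:, 0] = c[:, 0] + c[:, 1] * b + c[:, 2] * b**2 + c[:, 3] * b**3
        shifted[:, 1] = c[:, 1] + 2 * c[:, 2] * b + 3 * c[:, 3] * b**2
        shifted[:, 2] = c[:, 2] + 3 * c[:, 3] * b
        shifted[:, 3] = c[:, 3]
        w = self.areas / self.total_area_ha
        return w @ shifted

    def is_concave_nonneg(self, n_check: int = 33) -> bool:
        """True if every member poly is ≥ 0 and the mean cubic is concave
        and non-decreasing on the feasible fertilizer interval."""
        lo, hi = self.fert_bounds
        grid = np.linspace(lo, hi, n_check)
        vals = self._member_values(grid)
        t = grid + self.bnf_rate
        c = self.coeffs
        raw = c[:, 0:1] + np.multiply.outer(c[:, 1], t) + np.multiply.outer(
            c[:, 2], t**2
        ) + np.multiply.outer(c[:, 3], t**3)
        if np.any(raw < -1e-12):
            return False
        _ = vals
        # the shifted mean cubic q is a function of the fertilizer rate
        q = self.aggregated_cubic()
        second = 2 * q[2] + 6 * q[3] * grid
        first = q[1] + 2 * q[2] * grid + 3 * q[3] * grid**2
        scale = max(abs(q[1]), 1e-12)
        return bool(
            np.all(second <= 1e-9 * scale) and np.all(first >= -1e-9 * scale)
        )


def aggregate_unit_response(
    cells: Iterable[GridCellResponse],
    crop: CropParams | str,
    ensemble: str = ENSEMBLE,
) -> UnitResponse:
    """Aggregate grid cells of one unit × crop into a :class:`UnitResponse`.

    ``ensemble`` is either a model id (use that model's cells only) or
    ``"ensemble"``: average the member polynomials across models with equal
    weight, pixel by pixel, before area weighting.
    """
    cells = list(cells)
    if not cells:
        raise DegenerateUnitError("no cells to aggregate")
    crop = get_crop(crop) if isinstance(crop, str) else crop
    unit_ids = {c.unit_id for c in cells}
    crops = {c.crop for c in cells}
    if len(unit_ids) != 1 or len(crops) != 1:
        raise ValueError("cells must share a single unit_id and crop")
    if crops.pop() != crop.name:
        raise ValueError("crop parameter does not match the cells' crop")

    if ensemble != ENSEMBLE:
        cells = [c for c in cells if c.model_id == ensemble]
        if not cells:
            raise ValueError(f"no cells for model {ensemble!r}")
        groups: dict[str, list[GridCellResponse]] = {ensemble: cells}
    else:
        groups = {}
        for c in cells:
            groups.setdefault(c.model_id, []).append(c)

    # members are (pixel, regime) rows; average coefficients across models
    keyed: dict[tuple[int, str], list[GridCellResponse]] = {}
    for model_cells in groups.values():
        for c in model_cells:
            keyed.setdefault((c.pixel_id, c.water_regime), []).append(c)

    rows, areas, bnfs = [], [], []
    for key in sorted(keyed, key=lambda k: (k[0], k[1])):
        members = keyed[key]
        a = {round(m.area_ha, 9) for m in members}
        if len(a) != 1:
            raise ValueError(f"inconsistent areas across models at {key}")
        rows.append(np.mean([m.poly_coeffs for m in members], axis=0))
        areas.append(members[0].area_ha)
        bnfs.append(members[0].bnf_rate)

    areas_arr = np.asarray(areas, float)
    if areas_arr.sum() <= 0:
        raise DegenerateUnitError(
            f"unit {unit_ids.pop()}/{crop.name}: zero total area"
        )
    bnf = float(np.average(bnfs, weights=areas_arr)) if areas_arr.sum() else 0.0
    if not np.allclose(bnfs, bnf, atol=1e-9):
        raise ValueError("bnf_rate must be uniform within a unit")
    coeffs = np.asarray(rows, float) * crop.calorie_coeff
    return UnitResponse(
        unit_id=cells[0].unit_id,
        crop=crop,
        model_id=ensemble,
        coeffs=coeffs,
        areas=areas_arr,
        bnf_rate=bnf,
    )
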