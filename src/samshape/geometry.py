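"""Paraboloid model of shoot apical meristem (SAM) shape.

The SAM dome is approximated by the paraboloid of revolution obtained by
rotating the parabola ``z(x) = h * (1 - x**2 / r**2)`` (apex up, height ``h``,
basal radius ``r``, both in micrometres) about the z-axis.  From the two
primary measures (height, radius) eight "parabolic estimators" of meristem
shape and size follow in closed form:

======================  =========  ==========================================
estimator               units      closed form
======================  =========  ==========================================
height                  μm         h
radius                  μm         r
H/R                     —          h / r
volume                  μm³        π r² h / 2
lateral surface area    μm²        π/(6 b²) · [(1 + 4 b² r²)^{3/2} − 1],
                                   b = h/r²
arc length              μm         r √(1 + a² r²) + asinh(a r)/a,  a = 2h/r²
parabolic coefficient   μm⁻¹       h / r²
cross-sectional area    μm²        4 h r / 3
======================  =========  ==========================================

Surface area is the lateral surface only (the meristem has no physical base
cap); cross-sectional area is the area enclosed between the median-section
parabola and its base chord.  Both conventions are pinned by the flat-disk
limits h → 0: arc length → 2r, surface → π r².
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SamMeasures",
    "ParabolicEstimators",
    "ParabolaFit",
    "ESTIMATOR_COLUMNS",
    "estimators_from_hr",
    "estimators_table",
    "fit_parabola",
]

#: Column names used in estimator output tables, in canonical order.
ESTIMATOR_COLUMNS = (
    "Height",
    "Radius",
    "H/R",
    "Vol.",
    "Surf. Area",
    "Arc Len.",
    "Para. Coeff.",
    "Area",
)


@dataclass(frozen=True)
class SamMeasures:
    """Primary SAM phenotypes for one measured plant: height and radius (μm)."""

    line_id: str
    replicate: str
    height: float
    radius: float

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class ParabolicEstimators:
    """The eight paraboloid-derived shape/size estimators (units in module docstring)."""

    height: float
    radius: float
    h_over_r: float
    volume: float
    surface_area: float
    arc_length: float
    parabolic_coefficient: float
    cross_sectional_area: float

    def as_tuple(self) -> tuple[float, ...]:
        """Values in :data:`ESTIMATOR_COLUMNS` order."""
        return (
            self.height,
            self.radius,
            self.h_over_r,
            self.volume,
            self.surface_area,
            self.arc_length,
            self.parabolic_coefficient,
            self.cross_sectional_area,
        )


@dataclass(frozen=True)
class ParabolaFit:
    """Least-squares parabola fitted to a median-section contour.

    ``success`` is False when no downward-opening parabola fits (fitted
    curvature ≥ 0); numeric fields are NaN in that case.  ``baseline_y`` is
    the base level implied by the fit (apex y minus height), so translating
    the contour shifts only ``apex_x`` and ``baseline_y``.
    """

    height: float
    radius: float
    parabolic_coefficient: float
    apex_x: float
    baseline_y: float
    r_squared: float
    success: bool = True


def _check_positive(name: str, value: float) -> None:
    if not (np.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a positive finite number, got {value}")


def estimators_from_hr(measures: SamMeasures | tuple[float, float]) -> ParabolicEstimators:
    """Derive all eight parabolic estimators from (height, radius).

    Accepts a :class:`SamMeasures` or a plain ``(height, radius)`` pair in μm.
    """
    if isinstance(measures, SamMeasures):
        h, r = measures.height, measures.radius
    else:
        h, r = measures
    _check_positive("height", h)
    _check_positive("radius", r)

    a = 2.0 * h / r**2  # |dz/dx| slope scale for the arc length
    b = h / r**2  # parabolic coefficient
    arc = r * math.sqrt(1.0 + a**2 * r**2) + math.asinh(a * r) / a
    # expm1/log1p keeps the flat limit h -> 0 (surface -> pi r^2) accurate
    surface = math.pi / (6.0 * b**2) * math.expm1(1.5 * math.log1p(4.0 * b**2 * r**2))
    return ParabolicEstimators(
        height=h,
        radius=r,
        h_over_r=h / r,
        volume=math.pi * r**2 * h / 2.0,
        surface_area=surface,
        arc_length=arc,
        parabolic_coefficient=b,
        cross_sectional_area=4.0 * h * r / 3.0,
    )


def estimators_table(measures: "Sequence[SamMeasures]"):
    """Estimator table for a set of measures: one row per (line_id, replicate).

    Returns a pandas DataFrame with ``line_id``, ``replicate`` and the eight
    estimator columns named as in :data:`ESTIMATOR_COLUMNS`.
    """
    import pandas as pd

    rows = []
    for m in measures:
        est = estimators_from_hr(m)
        rows.append((m.line_id, m.replicate, *est.as_tuple()))
    return pd.DataFrame(rows, columns=["line_id", "replicate", *ESTIMATOR_COLUMNS])


def _parabola_rss(x: np.ndarray, y: np.ndarray, apex_x: float) -> tuple[float, float, float]:
    """OLS of y on (x - apex_x)**2; returns (rss, curvature c, intercept)."""
    t = (x - apex_x) ** 2
    A = np.column_stack([np.ones_like(t), t])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(resid @ resid), float(coef[1]), float(coef[0])


def fit_parabola(contour) -> ParabolaFit:
    """Fit a downward-opening parabola ``y = apex_y + c (x - apex_x)²`` to a contour.

    The apex abscissa is initialised at the contour's maximal y and refined by
    1-D minimisation of the residual sum of squares; conditional on ``apex_x``
    the model is linear and solved by ordinary least squares.  Radius is half
    the contour's x-extent (its basal endpoints), height follows from the
    invariant ``height = |c| · radius²``, and ``r_squared`` is the coefficient
    of determination of the regression.
    """
    from scipy.optimize import minimize_scalar

    pts = np.asarray(getattr(contour, "points", contour), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("contour must provide >= 5 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]

    apex0 = float(x[np.argmax(y)])
    lo, hi = float(x.min()), float(x.max())
    res = minimize_scalar(
        lambda a: _parabola_rss(x, y, a)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10 * max(hi - lo, 1.0)},
    )
    apex_x = float(res.x)
    rss, c, apex_y = _parabola_rss(x, y, apex_x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 0.0

    if c >= 0:  # no downward-opening parabola: report failure, not an exception
        nan = float("nan")
        return ParabolaFit(nan, nan, nan, nan, nan, r2, success=False)

    radius = (hi - lo) / 2.0
    height = abs(c) * radius**2
    return ParabolaFit(
        height=height,
        radius=radius,
        parabolic_coefficient=abs(c),
        apex_x=apex_x,
        baseline_y=apex_y - height,
        r_squared=r2,
        success=True,
    )
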