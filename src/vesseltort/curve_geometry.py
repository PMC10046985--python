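"""Differential geometry of parametrized vessel centerlines.

A vessel segment is represented by its centerline, an ordered sequence of
2D points ``C(t) = (x(t), y(t))`` indexed by the integer pixel parameter
``t = 1..N``.  From the centerline this module estimates first and second
coordinate derivatives (weighted least squares on a second-order Taylor
expansion), the signed curvature

    kappa(t) = (y'' x' - y' x'') / (x'^2 + y'^2)^(3/2),

the four geometric parameters of the curve -- chord length ``D``, arc
length ``L``, total curvature ``TK`` and total squared curvature ``TSK``
-- and the eight local tortuosity indices built from them:

    DF = L/D,  T1 = L/D - 1,  T2 = TK,     T3 = TSK,
    T4 = TK/L, T5 = TSK/L,    T6 = TK/D,   T7 = TSK/D.

``L``, ``TK`` and ``TSK`` are line integrals of 1, |kappa| and kappa^2
against arc length, evaluated by the composite trapezoidal rule on the
integer parameter grid.  ``TK`` integrates the *absolute* curvature so
that an S-shaped vessel does not cancel its own turning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    CurveLengthError,
    DegenerateCurveError,
    DegenerateInputError,
    DomainError,
    ParameterError,
)

__all__ = [
    "MIN_CURVE_LENGTH",
    "DEFAULT_OFFSETS",
    "VesselCurve",
    "EstimationConfig",
    "DerivativeSeries",
    "CurvatureSeries",
    "GeometricParams",
    "TortuosityProfile",
    "smooth_curve",
    "estimate_derivatives",
    "compute_curvature",
    "geometric_parameters",
    "tortuosity_indices",
    "analyze_curve",
    "read_curve_csv",
    "write_curve_csv",
]

#: Minimum number of centerline points: the full one-sided stencil
#: (offsets +4..+20) must fit at an endpoint.
MIN_CURVE_LENGTH = 21

#: Signed parameter offsets used in the Taylor-expansion fit.
DEFAULT_OFFSETS = (-20, -16, -12, -8, -4, 4, 8, 12, 16, 20)

_SQRT2 = math.sqrt(2.0)
_STEP_TOL = 1e-6
#: Floor on speed^2 = x'^2 + y'^2 below which the curve is declared degenerate.
SPEED_SQ_FLOOR = 1e-6


@dataclass
class VesselCurve:
    """An ordered, regular vessel centerline in pixel coordinates.

    ``points`` has shape ``(N, 2)`` with columns ``(x, y)`` where ``x`` is
    the image column and ``y`` the image row.  Consecutive points must be
    8-neighbors or smoothed interpolants thereof (step <= sqrt(2)), with
    no repeated points, and ``N >= 21``.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ParameterError("points must be an (N, 2) array of (x, y) pairs")
        if len(pts) < MIN_CURVE_LENGTH:
            raise CurveLengthError(
                f"curve has {len(pts)} points; at least {MIN_CURVE_LENGTH} required"
            )
        if not np.all(np.isfinite(pts)):
            raise ParameterError("curve contains non-finite coordinates")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise DegenerateInputError("curve contains coincident consecutive points")
        if np.any(steps > _SQRT2 + _STEP_TOL):
            raise ParameterError(
                "consecutive points must be 8-neighbors or denser "
                f"(max step {steps.max():.3f} > sqrt(2))"
            )
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def reversed(self) -> "VesselCurve":
        return VesselCurve(self.points[::-1].copy())


@dataclass(frozen=True)
class EstimationConfig:
    """Configuration of the Taylor/WLS derivative estimator.

    ``offsets`` are the signed parameter offsets ``p``; each usable offset
    contributes one equation.  ``weight`` maps an offset to its (strictly
    positive) weight, by default ``1/|p|`` so that distant neighbors count
    less.  The four derivative sequences are smoothed afterwards with a
    centered moving average of ``smoothing_window`` terms.
    """

    offsets: tuple[int, ...] = DEFAULT_OFFSETS
    weight: Callable[[int], float] = field(default=lambda p: 1.0 / abs(p))
    smoothing_window: int = 3

    def __post_init__(self) -> None:
        if len(self.offsets) < 2:
            raise ParameterError("need at least two offsets")
        offs = tuple(int(p) for p in self.offsets)
        if any(p == 0 for p in offs):
            raise ParameterError("offset 0 is not allowed (the center is known)")
        if len(set(offs)) != len(offs):
            raise ParameterError("offsets must be distinct")
        if any(self.weight(p) <= 0 for p in offs):
            raise ParameterError("all weights must be strictly positive")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ParameterError("smoothing window must be a positive odd integer")
        object.__setattr__(self, "offsets", offs)


@dataclass
class DerivativeSeries:
    """Per-point first/second derivative estimates of both coordinates."""

    x1: np.ndarray
    x2: np.ndarray
    y1: np.ndarray
    y2: np.ndarray

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, dtype=float) for a in (self.x1, self.x2, self.y1, self.y2)]
        n = len(arrs[0])
        if any(len(a) != n for a in arrs):
            raise ParameterError("derivative series must share one length")
        if any(not np.all(np.isfinite(a)) for a in arrs):
            raise ParameterError("derivative series contain non-finite values")
        self.x1, self.x2, self.y1, self.y2 = arrs

    def __len__(self) -> int:
        return len(self.x1)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.x1, self.y1)


@dataclass
class CurvatureSeries:
    """Per-point signed curvature kappa(t)."""

    kappa: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.kappa, dtype=float)
        if not np.all(np.isfinite(k)):
            raise ParameterError("curvature contains non-finite values")
        self.kappa = k

    def __len__(self) -> int:
        return len(self.kappa)


@dataclass(frozen=True)
class GeometricParams:
    """Chord length D, arc length L (px), total curvature TK (rad) and
    total squared curvature TSK (1/px) of one centerline."""

    D: float
    L: float
    TK: float
    TSK: float

    def as_dict(self) -> dict[str, float]:
        return {"D": self.D, "L": self.L, "TK": self.TK, "TSK": self.TSK}


#: Canonical ordering of the eight indices throughout the package.
INDEX_NAMES = ("DF", "T1", "T2", "T3", "T4", "T5", "T6", "T7")


@dataclass(frozen=True)
class TortuosityProfile:
    """The eight local tortuosity indices of one vessel segment."""

    DF: float
    T1: float
    T2: float
    T3: float
    T4: float
    T5: float
    T6: float
    T7: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}

    def to_json(self) -> str:
        return json.dumps(self.as_dict())


def _moving_average_1d(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the ends."""
    n = len(values)
    half = window // 2
    if half == 0:
        return values.astype(float, copy=True)
    cs = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    i = np.arange(n)
    k = np.minimum(half, np.minimum(i, n - 1 - i))
    return (cs[i + k + 1] - cs[i - k]) / (2 * k + 1)


def smooth_curve(curve: VesselCurve, window: int = 3) -> VesselCurve:
    """Smooth both coordinates with a centered ``window``-term moving average.

    The window is truncated symmetrically at the two curve ends (no data is
    invented beyond the endpoints), so the length is unchanged and affine
    point sequences are preserved in the interior.
    """
    if window < 1 or window % 2 == 0:
        raise ParameterError("smoothing window must be a positive odd integer")
    pts = np.column_stack(
        [_moving_average_1d(curve.x, window), _moving_average_1d(curve.y, window)]
    )
    return VesselCurve(pts)


def _wls_solver(offsets: np.ndarray, weight: Callable[[int], float]) -> np.ndarray:
    """Return the 2 x k matrix mapping centered samples to (f', f'').

    Solves min_w sum_p w_p (f(m+p) - f(m) - f' p - f'' p^2/2)^2 in closed
    form; the same matrix applies to every point sharing the stencil.
    """
    p = offsets.astype(float)
    w = np.array([weight(int(q)) for q in offsets], dtype=float)
    A = np.column_stack([p, 0.5 * p * p])
    Aw = A * w[:, None]
    M = A.T @ Aw
    return np.linalg.solve(M, Aw.T)


def estimate_derivatives(
    curve: VesselCurve, cfg: EstimationConfig | None = None
) -> DerivativeSeries:
    """Estimate x', x'', y', y'' at every point by weighted least squares.

    For each point ``m`` and every offset ``p`` with ``m + p`` in range,
    the second-order Taylor expansion

        f(m+p) = f(m) + f'(m) p + f''(m) p^2 / 2 + eps

    gives one equation; the systems (one per coordinate, two unknowns
    each) are solved with weights ``1/|p|``.  With the default offsets
    ``+-4, +-8, ..., +-20`` interior points use 10 equations, decreasing
    to 5 one-sided equations at the extreme points.  The four resulting
    sequences are smoothed by a centered 3-term moving average.
    """
    if cfg is None:
        cfg = EstimationConfig()
    n = len(curve)
    if n < MIN_CURVE_LENGTH:
        raise CurveLengthError(f"need at least {MIN_CURVE_LENGTH} points, got {n}")

    offsets = np.array(sorted(cfg.offsets), dtype=int)
    pmin, pmax = offsets.min(), offsets.max()
    x, y = curve.x, curve.y
    out = {name: np.empty(n) for name in ("x1", "x2", "y1", "y2")}

    # Interior points share the full stencil: one solver matrix, applied in bulk.
    lo = max(0, -pmin)
    hi = n - 1 - max(0, pmax)  # inclusive
    if hi >= lo:
        solver = _wls_solver(offsets, cfg.weight)  # 2 x k
        m = np.arange(lo, hi + 1)
        idx = m[:, None] + offsets[None, :]
        bx = x[idx] - x[m, None]
        by = y[idx] - y[m, None]
        dx = bx @ solver.T  # (n_int, 2)
        dy = by @ solver.T
        out["x1"][lo : hi + 1], out["x2"][lo : hi + 1] = dx[:, 0], dx[:, 1]
        out["y1"][lo : hi + 1], out["y2"][lo : hi + 1] = dy[:, 0], dy[:, 1]

    # Boundary points: subset of usable offsets, solver cached per subset.
    cache: dict[tuple[int, ...], np.ndarray] = {}
    boundary = [m for m in range(n) if m < lo or m > hi]
    for m in boundary:
        usable = offsets[(m + offsets >= 0) & (m + offsets <= n - 1)]
        if len(usable) < 2:
            raise CurveLengthError(
                f"fewer than 2 usable Taylor equations at point {m}"
            )
        key = tuple(int(q) for q in usable)
        solver = cache.get(key)
        if solver is None:
            solver = cache[key] = _wls_solver(usable, cfg.weight)
        bx = x[m + usable] - x[m]
        by = y[m + usable] - y[m]
        out["x1"][m], out["x2"][m] = solver @ bx
        out["y1"][m], out["y2"][m] = solver @ by

    w = cfg.smoothing_window
    return DerivativeSeries(
        x1=_moving_average_1d(out["x1"], w),
        x2=_moving_average_1d(out["x2"], w),
        y1=_moving_average_1d(out["y1"], w),
        y2=_moving_average_1d(out["y2"], w),
    )


def compute_curvature(deriv: DerivativeSeries) -> CurvatureSeries:
    """Signed curvature from derivative estimates.

    kappa = (y'' x' - y' x'') / (x'^2 + y'^2)^(3/2).  A speed^2 below
    ``SPEED_SQ_FLOOR`` violates the regularity assumption C'(t) != 0 and
    is a hard error, not a clamp.
    """
    speed_sq = deriv.x1**2 + deriv.y1**2
    if np.any(speed_sq < SPEED_SQ_FLOOR):
        raise DegenerateCurveError(
            "estimated speed vanishes: curve is not regular (C'(t) == 0)"
        )
    kappa = (deriv.y2 * deriv.x1 - deriv.y1 * deriv.x2) / speed_sq**1.5
    return CurvatureSeries(kappa=kappa)


def geometric_parameters(
    curve: VesselCurve, kappa: CurvatureSeries, deriv: DerivativeSeries
) -> GeometricParams:
    """Chord length, arc length, total and total squared curvature.

    L, TK and TSK are the line integrals of 1, |kappa| and kappa^2 against
    arc length, evaluated with the composite trapezoidal rule on the unit
    parameter grid t = 1..N using the estimated speed sqrt(x'^2 + y'^2).
    """
    n = len(curve)
    if len(kappa) != n or len(deriv) != n:
        raise ParameterError("curve, curvature and derivative lengths must match")
    chord = float(np.linalg.norm(curve.points[-1] - curve.points[0]))
    if chord <= 0.0:
        raise DegenerateInputError("zero chord: closed curves are not supported")
    speed = deriv.speed
    L = float(np.trapezoid(speed))
    TK = float(np.trapezoid(np.abs(kappa.kappa) * speed))
    TSK = float(np.trapezoid(kappa.kappa**2 * speed))
    return GeometricParams(D=chord, L=L, TK=TK, TSK=TSK)


def tortuosity_indices(gp: GeometricParams) -> TortuosityProfile:
    """The eight local tortuosity indices from (D, L, TK, TSK)."""
    if gp.D <= 0 or gp.L <= 0:
        raise DomainError("chord and arc length must be strictly positive")
    df = gp.L / gp.D
    return TortuosityProfile(
        DF=df,
        T1=df - 1.0,
        T2=gp.TK,
        T3=gp.TSK,
        T4=gp.TK / gp.L,
        T5=gp.TSK / gp.L,
        T6=gp.TK / gp.D,
        T7=gp.TSK / gp.D,
    )


def analyze_curve(
    curve: VesselCurve, cfg: EstimationConfig | None = None
) -> tuple[GeometricParams, TortuosityProfile]:
    """Full chain: derivatives -> curvature -> parameters -> indices."""
    deriv = estimate_derivatives(curve, cfg)
    kappa = compute_curvature(deriv)
    gp = geometric_parameters(curve, kappa, deriv)
    return gp, tortuosity_indices(gp)


def write_curve_csv(curve: VesselCurve, path) -> None:
    """Write a centerline as a two-column CSV (x, y in float pixels)."""
    np.savetxt(path, curve.points, delimiter=",", header="x,y", comments="")


def read_curve_csv(path) -> VesselCurve:
    """Read a centerline from a two-column (x, y) CSV with a header row."""
    pts = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return VesselCurve(pts)
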