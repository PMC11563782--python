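"""Euler-Bernoulli bending of a hypha under flow load, forward and inverse.

A hypha emerging from the channel side wall is modeled as a clamped
cantilever of constant annular cross-section with bending stiffness k_b.
The distributed hydrodynamic load f(y), diminished by cos α₁ because in the
deflected equilibrium the flow no longer acts perpendicular to the hypha
axis, drives the beam equation

    d⁴w_f/dy′⁴ = cos(α₁) · f(y′) / k_b,   w(0) = w′(0) = 0,
                                          w″(L) = w‴(L) = 0,

solved by quadruple cumulative quadrature along the arc coordinate y′.  The
hemispherical-tip point force adds the classical cantilever end-load term,
giving the total tip deflection

    w_max = w_f,max + F_tip·L³/(3·k_b).

The inverse problem fits k_b to measured tip displacements across flow
rates: the measured in-flow (x) displacement is converted to the deflection
perpendicular to the hypha axis via 1/cos α₀, points violating the
small-deflection validity bound w_max/L ≤ 0.25 are excluded, and a
least-squares line through the origin in the predictor Q·cos α₁ yields k_b.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_simpson

from hyphabend import units
from hyphabend.channel_flow import (
    CENTER,
    ChannelGeometry,
    FlowCondition,
    Fluid,
)
from hyphabend.drag_model import DistributedLoad, distributed_load, tip_force
from hyphabend.errors import (
    ConvergenceError,
    DomainError,
    FitError,
    ValidationError,
)

__all__ = [
    "HyphaGeometry",
    "DeflectionMeasurement",
    "BendingFitResult",
    "FilterResult",
    "deflection_distributed",
    "tip_deflection_total",
    "unit_response",
    "forward_model",
    "fit_bending_stiffness",
    "validity_filter",
    "tip_force_neglect_bias",
    "read_measurement_table",
    "write_measurement_table",
    "read_hypha_table",
    "write_hypha_table",
]

#: validity bound on relative tip deflection for linear beam theory
MAX_RELATIVE_DEFLECTION = 0.25

#: default center-plane proximity tolerance (µm), center configuration
CENTER_PLANE_TOLERANCE = 10.0


@dataclass(frozen=True)
class HyphaGeometry:
    """Geometry of one specimen: the cantilever being bent.

    Parameters
    ----------
    radius : float
        Outer radius r in µm (~1.4 µm for *A. niger*).
    wall_thickness : float
        Cell-wall thickness t in µm (0 < t <= r).
    length : float
        Exposed length L in µm measured from the side wall (L > r).
    base_position : float
        Channel coordinate y₀ of the clamped base, µm from the side wall.
    alpha0 : float
        Initial in-plane tilt of the hypha axis against the spanwise axis,
        radians, |α₀| < π/2.
    dz : float
        Vertical offset of the hypha from the channel mid-height, µm.
    """

    radius: float
    wall_thickness: float
    length: float
    base_position: float = 0.0
    alpha0: float = 0.0
    dz: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.wall_thickness <= self.radius:
            raise ValidationError(
                f"wall thickness must satisfy 0 < t <= r, got "
                f"t={self.wall_thickness}, r={self.radius}"
            )
        if not self.length > self.radius:
            raise ValidationError(
                f"exposed length must exceed the tip radius, got "
                f"L={self.length}, r={self.radius}"
            )
        if not abs(self.alpha0) < math.pi / 2:
            raise ValidationError("|alpha0| must be < pi/2 rad")
        if self.base_position < 0:
            raise ValidationError("base_position must be >= 0")


@dataclass(frozen=True)
class DeflectionMeasurement:
    """One (flow rate, tip displacement, deflected angle) record.

    ``x_displacement`` is the measured tip displacement along the flow (x)
    direction in µm; ``alpha1`` is the deflected chord angle in radians as
    extracted from the images.
    """

    flow: FlowCondition
    x_displacement: float
    alpha1: float
    exclude: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if not abs(self.alpha1) < math.pi / 2:
            raise ValidationError("|alpha1| must be < pi/2 rad")


def _arc_load(load: DistributedLoad, hypha: HyphaGeometry):
    """Map the channel-coordinate load onto the hypha arc coordinate y′."""
    w = load.geometry.width
    c = math.cos(hypha.alpha0)
    reach = hypha.base_position + hypha.length * c
    if reach > w:
        raise DomainError(
            f"hypha extends beyond the far channel wall "
            f"(base + L·cos(alpha0) = {reach:.3g} µm > w = {w:.3g} µm)"
        )

    def f_arc(s):
        return load(hypha.base_position + np.asarray(s, dtype=float) * c)

    return f_arc


def deflection_distributed(
    load: DistributedLoad,
    k_b: float,
    hypha: HyphaGeometry,
    alpha1: float = 0.0,
    n_grid: int = 1201,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Deflection curve w_f(y′) under the distributed load alone.

    Integrates the cantilever equation four times with cumulative Simpson
    quadrature on a uniform arc grid, enforcing the clamped-base and
    free-end boundary conditions.  Returns ``(y_grid, w_curve, w_tip)``.
    """
    if not k_b > 0:
        raise ValidationError("bending stiffness k_b must be positive")
    f_arc = _arc_load(load, hypha)
    s = np.linspace(0.0, hypha.length, n_grid)
    q = math.cos(alpha1) * f_arc(s) / k_b
    c1 = cumulative_simpson(q, x=s, initial=0.0)
    w3 = c1 - c1[-1]                       # w‴, zero shear at the free end
    c2 = cumulative_simpson(w3, x=s, initial=0.0)
    w2 = c2 - c2[-1]                       # w″, zero moment at the free end
    w1 = cumulative_simpson(w2, x=s, initial=0.0)   # w′(0) = 0
    w = cumulative_simpson(w1, x=s, initial=0.0)    # w(0) = 0
    return s, w, float(w[-1])


class TipDeflection(NamedTuple):
    """Total tip deflection and its two superposed contributions (µm)."""

    w_max: float
    w_distributed: float
    w_tip_force: float
    tip_force: float


def tip_deflection_total(
    load: DistributedLoad,
    k_b: float,
    hypha: HyphaGeometry,
    alpha1: float = 0.0,
    n_grid: int = 1201,
    include_tip_force: bool = True,
) -> TipDeflection:
    """Tip deflection from the distributed load plus the tip point force.

    The point-force term uses the diminished load f* = cos(α₁)·f in the
    end-effect integral and the closed-form cantilever response F·L³/(3k_b).
    """
    _, _, w_f = deflection_distributed(load, k_b, hypha, alpha1, n_grid)
    if include_tip_force:
        f_tip = math.cos(alpha1) * tip_force(
            load,
            hypha.length,
            hypha.radius,
            y0=hypha.base_position,
            alpha0=hypha.alpha0,
        )
        w_F = f_tip * hypha.length**3 / (3.0 * k_b)
    else:
        f_tip = 0.0
        w_F = 0.0
    return TipDeflection(w_f + w_F, w_f, w_F, f_tip)


def unit_response(
    hypha: HyphaGeometry,
    geom: ChannelGeometry,
    fluid: Fluid,
    n_max: int = 11,
    include_tip_force: bool = True,
    n_grid: int = 1201,
) -> float:
    """Tip deflection per unit flow rate at unit stiffness, A (µm per µm³·s⁻¹).

    Because both the distributed load and the tip force are linear in Q and
    inversely proportional to k_b, the full model reduces to
    w_max = A·Q·cos(α₁)/k_b with A computed once per hypha.
    """
    load = distributed_load(geom, fluid, FlowCondition(1.0), hypha.radius, n_max)
    return tip_deflection_total(
        load, 1.0, hypha, 0.0, n_grid, include_tip_force
    ).w_max


class ForwardResult(NamedTuple):
    """Self-consistent deflected state of one hypha at one flow rate."""

    x_displacement: float
    alpha1: float
    w_max: float
    n_iterations: int


def forward_model(
    hypha: HyphaGeometry,
    geom: ChannelGeometry,
    fluid: Fluid,
    flow: FlowCondition,
    k_b: float,
    n_max: int = 11,
    include_tip_force: bool = True,
    tol: float = 1e-8,
    max_iter: int = 50,
    response: float | None = None,
) -> ForwardResult:
    """Predict the measured x-displacement and deflected angle α₁.

    The load factor cos α₁ depends on the deflected chord, which in turn
    depends on the load: the coupled pair is solved by fixed-point iteration
    starting from α₁ = α₀.  The measured in-flow displacement is the
    x-projection w_max·cos α₀ of the deflection perpendicular to the axis.

    ``response`` may carry a precomputed :func:`unit_response` to avoid
    re-solving the beam when sweeping flow rates for one hypha.
    """
    if not k_b > 0:
        raise ValidationError("bending stiffness k_b must be positive")
    if response is None:
        response = unit_response(hypha, geom, fluid, n_max, include_tip_force)
    L = hypha.length
    a0 = hypha.alpha0
    if flow.rate == 0.0:
        return ForwardResult(0.0, a0, 0.0, 0)
    alpha1 = a0
    w = 0.0
    for it in range(1, max_iter + 1):
        w = response * flow.rate * math.cos(alpha1) / k_b
        alpha1_new = math.atan2(
            L * math.sin(a0) + w * math.cos(a0),
            L * math.cos(a0) - w * math.sin(a0),
        )
        if abs(alpha1_new - alpha1) < tol:
            alpha1 = alpha1_new
            break
        alpha1 = alpha1_new
    else:
        raise ConvergenceError(
            f"deflection angle iteration did not converge in {max_iter} "
            "steps; the deflection is far outside small-angle validity"
        )
    w = response * flow.rate * math.cos(alpha1) / k_b
    return ForwardResult(w * math.cos(a0), alpha1, w, it)


class FilterResult(NamedTuple):
    """Partition of measurements into usable and excluded."""

    kept: tuple[DeflectionMeasurement, ...]
    excluded: tuple[tuple[DeflectionMeasurement, str], ...]
    hypha_valid: bool
    hypha_reason: str | None


def validity_filter(
    measurements: Sequence[DeflectionMeasurement],
    hypha: HyphaGeometry,
    configuration: str = CENTER,
    center_tolerance: float = CENTER_PLANE_TOLERANCE,
) -> FilterResult:
    """Apply the measurement-validity criteria.

    Points with relative tip deflection w_max/L > 0.25 (boundary inclusive:
    exactly 0.25 is kept) violate linear beam theory and are marked; points
    carrying a user exclusion flag are marked with their recorded reason.
    In the center configuration a hypha more than ``center_tolerance`` µm
    from the channel mid-plane is flagged invalid as a whole, since the
    mid-plane force estimate no longer applies.
    """
    hypha_valid = True
    hypha_reason = None
    if configuration == CENTER and abs(hypha.dz) > center_tolerance:
        hypha_valid = False
        hypha_reason = (
            f"hypha {abs(hypha.dz):.3g} µm from the center plane exceeds the "
            f"±{center_tolerance:g} µm tolerance"
        )
    kept: list[DeflectionMeasurement] = []
    excluded: list[tuple[DeflectionMeasurement, str]] = []
    cos_a0 = math.cos(hypha.alpha0)
    for m in measurements:
        if m.exclude:
            excluded.append((m, m.reason or "user flag"))
            continue
        w_obs = abs(m.x_displacement) / cos_a0
        if w_obs / hypha.length > MAX_RELATIVE_DEFLECTION:
            excluded.append(
                (
                    m,
                    f"validity filter: w_max/L = {w_obs / hypha.length:.3g} "
                    f"> {MAX_RELATIVE_DEFLECTION}",
                )
            )
            continue
        kept.append(m)
    return FilterResult(tuple(kept), tuple(excluded), hypha_valid, hypha_reason)


@dataclass(frozen=True)
class BendingFitResult:
    """Bending stiffness estimate for one hypha with fit diagnostics."""

    k_b: float
    k_b_stderr: float
    intercept: float | None
    points_used: tuple[DeflectionMeasurement, ...]
    points_excluded: tuple[tuple[DeflectionMeasurement, str], ...]
    residuals: np.ndarray
    predicted: np.ndarray

    @property
    def n_used(self) -> int:
        return len(self.points_used)

    @property
    def n_excluded(self) -> int:
        return len(self.points_excluded)


def fit_bending_stiffness(
    measurements: Sequence[DeflectionMeasurement],
    hypha: HyphaGeometry,
    geom: ChannelGeometry,
    fluid: Fluid,
    n_max: int = 11,
    include_tip_force: bool = True,
    intercept: bool = False,
    center_tolerance: float = CENTER_PLANE_TOLERANCE,
) -> BendingFitResult:
    """Estimate k_b from measured deflections across flow rates.

    The model w_max = (A/k_b)·Q·cos α₁ is linear through the origin in the
    predictor Q·cos α₁, with A the per-hypha unit response; ordinary least
    squares on 1/k_b gives the estimate.  Measured x-displacements are
    converted to axis-perpendicular deflections via 1/cos α₀, the deflected
    angles are taken from the measurement records as extracted from images,
    and the validity filter is applied first.  With ``intercept`` a free
    offset is added to diagnose adhesion artifacts (a stuck first point).
    """
    filt = validity_filter(
        measurements, hypha, geom.configuration, center_tolerance
    )
    if not filt.hypha_valid:
        raise FitError(f"hypha invalid: {filt.hypha_reason}")
    n_validity = sum(
        1 for _, r in filt.excluded if r.startswith("validity filter")
    )
    if not filt.kept and n_validity == len(measurements) and measurements:
        raise FitError(
            "all measurements excluded by the w_max/L validity filter"
        )
    usable = [m for m in filt.kept if m.flow.rate > 0]
    excluded = filt.excluded + tuple(
        (m, "zero flow rate (anchor point)")
        for m in filt.kept
        if m.flow.rate == 0
    )
    if len(usable) < 2:
        reasons = "; ".join(r for _, r in excluded) or "none"
        raise FitError(
            f"need >= 2 usable measurements with Q > 0, have {len(usable)} "
            f"(exclusions: {reasons})"
        )
    cos_a0 = math.cos(hypha.alpha0)
    signs = {math.copysign(1.0, m.x_displacement) for m in usable
             if m.x_displacement != 0.0}
    if len(signs) > 1:
        warnings.warn(
            "measured displacements change sign across flow rates; "
            "fitting absolute values",
            stacklevel=2,
        )
    response = unit_response(hypha, geom, fluid, n_max, include_tip_force)
    g = np.array([response * m.flow.rate * math.cos(m.alpha1) for m in usable])
    w_obs = np.array([abs(m.x_displacement) / cos_a0 for m in usable])
    if intercept:
        X = np.column_stack([g, np.ones_like(g)])
        coef, *_ = np.linalg.lstsq(X, w_obs, rcond=None)
        beta, c0 = float(coef[0]), float(coef[1])
        pred = X @ coef
        dof = len(usable) - 2
        xtx_inv_00 = float(np.linalg.inv(X.T @ X)[0, 0])
    else:
        beta = float(np.dot(g, w_obs) / np.dot(g, g))
        c0 = None
        pred = beta * g
        dof = len(usable) - 1
        xtx_inv_00 = 1.0 / float(np.dot(g, g))
    resid = w_obs - pred
    if beta <= 0:
        raise FitError(
            "fitted response is non-positive; deflections do not increase "
            "with flow rate"
        )
    s2 = float(np.dot(resid, resid)) / dof if dof > 0 else 0.0
    beta_se = math.sqrt(s2 * xtx_inv_00)
    k_b = 1.0 / beta
    k_b_stderr = beta_se / beta**2   # delta method
    return BendingFitResult(
        k_b=k_b,
        k_b_stderr=k_b_stderr,
        intercept=c0,
        points_used=tuple(usable),
        points_excluded=excluded,
        residuals=resid,
        predicted=pred,
    )


def tip_force_neglect_bias(
    hypha: HyphaGeometry,
    geom: ChannelGeometry,
    fluid: Fluid,
    n_max: int = 11,
) -> float:
    """Percent by which k_b is underestimated if the tip force is ignored.

    Fitting forward-model data without the end-effect point force scales the
    recovered stiffness by w_f/(w_f + w_F); the shortfall
    100·w_F/(w_f + w_F) is independent of Q and k_b and grows as the hypha
    shortens, because the tip segment then carries a larger share of the
    total load.
    """
    a_with = unit_response(hypha, geom, fluid, n_max, include_tip_force=True)
    a_without = unit_response(hypha, geom, fluid, n_max, include_tip_force=False)
    return (1.0 - a_without / a_with) * 100.0


# ---------------------------------------------------------------------------
# Tabular interfaces: comma-separated, header mandatory, angles in degrees.

MEASUREMENT_COLUMNS = [
    "hypha_id",
    "Q_uL_min",
    "x_disp_um",
    "alpha0_deg",
    "alpha1_deg",
    "exclude",
]

HYPHA_COLUMNS = [
    "hypha_id",
    "r_um",
    "t_um",
    "L_um",
    "y0_um",
    "alpha0_deg",
    "dz_um",
]


def read_measurement_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = set(MEASUREMENT_COLUMNS) - {"exclude"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"measurement table missing columns: {sorted(missing)}"
        )
    if "exclude" not in df.columns:
        df["exclude"] = 0
    df["exclude"] = df["exclude"].fillna(0).astype(int)
    return df


def write_measurement_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=[c for c in MEASUREMENT_COLUMNS
                                          if c in df.columns])


def measurements_from_frame(df: pd.DataFrame) -> list[DeflectionMeasurement]:
    """Rows of one hypha -> measurement records (angles converted to rad)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            DeflectionMeasurement(
                flow=FlowCondition.from_ul_min(float(row.Q_uL_min)),
                x_displacement=float(row.x_disp_um),
                alpha1=float(units.deg_to_rad(row.alpha1_deg)),
                exclude=bool(getattr(row, "exclude", 0)),
                reason="user flag" if getattr(row, "exclude", 0) else None,
            )
        )
    return out


def read_hypha_table(
    path: str | Path,
) -> dict[str, HyphaGeometry]:
    df = pd.read_csv(path)
    missing = set(HYPHA_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"hypha table missing columns: {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.hypha_id)] = HyphaGeometry(
            radius=float(row.r_um),
            wall_thickness=float(row.t_um),
            length=float(row.L_um),
            base_position=float(row.y0_um),
            alpha0=float(units.deg_to_rad(row.alpha0_deg)),
            dz=float(row.dz_um),
        )
    return out


def write_hypha_table(
    hyphae: dict[str, HyphaGeometry], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "hypha_id": list(hyphae.keys()),
            "r_um": [h.radius for h in hyphae.values()],
            "t_um": [h.wall_thickness for h in hyphae.values()],
            "L_um": [h.length for h in hyphae.values()],
            "y0_um": [h.base_position for h in hyphae.values()],
            "alpha0_deg": [units.rad_to_deg(h.alpha0) for h in hyphae.values()],
            "dz_um": [h.dz for h in hyphae.values()],
        }
    )
    df.to_csv(path, index=False)
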