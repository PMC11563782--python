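"""Pressure-driven laminar flow in a rectangular measurement chamber.

The velocity field of fully developed Poiseuille flow in a rectangular duct
is the classical odd-harmonic series: sine modes across the channel height
``h`` (vertical, z) and a cosh envelope across the width ``w`` (spanwise, y,
the axis along which hyphae grow from a side wall),

    u(y, z) = (4 G h² / π³ µ) Σ_{n odd} n⁻³ [1 − cosh(nπ(y−w/2)/h) /
              cosh(nπ w / 2h)] sin(nπ z / h),

with pressure gradient ``G`` along the flow axis.  The same series yields the
hydraulic resistance per unit length R_f (so that G = R_f·Q), the wall shear
gradient ∂u/∂z at the floor, and a one-parameter least-squares recovery of
the volumetric flow rate from measured µPIV velocity profiles.

Coordinates: y ∈ [0, w] with y = 0 at the side wall where the hyphae emerge;
z ∈ [0, h] with z = 0 at the channel floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from hyphabend import units
from hyphabend.errors import DomainError, FitError, ValidationError

__all__ = [
    "ChannelGeometry",
    "Fluid",
    "FlowCondition",
    "VelocityProfileSample",
    "FlowRateFit",
    "velocity_field",
    "wall_velocity_gradient",
    "resistance_per_length",
    "fit_flow_rate",
    "read_velocity_profiles",
    "write_velocity_profiles",
]

FLOOR = "floor"
CENTER = "center"


@dataclass(frozen=True)
class ChannelGeometry:
    """Cross-section of the measurement chamber.

    Parameters
    ----------
    width : float
        Spanwise extent w in µm; hyphae grow along this axis from a side wall.
    height : float
        Vertical extent h in µm.
    configuration : {"floor", "center"}
        Whether the specimen lies on the channel floor or sits at mid-height.
        A center-configuration chamber molded from the same design has twice
        the floor-configuration height.
    chamber_length : float, optional
        Streamwise chamber length in µm, used for total-resistance estimates.
    """

    width: float
    height: float
    configuration: str = CENTER
    chamber_length: float | None = None

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValidationError(
                f"channel width and height must be positive, got "
                f"w={self.width}, h={self.height}"
            )
        if self.configuration not in (FLOOR, CENTER):
            raise ValidationError(
                f"configuration must be 'floor' or 'center', got "
                f"{self.configuration!r}"
            )
        if self.chamber_length is not None and self.chamber_length <= 0:
            raise ValidationError("chamber_length must be positive")


@dataclass(frozen=True)
class Fluid:
    """Newtonian fluid; viscosity in µN·s·µm⁻² (water ≈ 1e-9)."""

    viscosity: float = units.WATER_VISCOSITY

    def __post_init__(self) -> None:
        if not self.viscosity > 0:
            raise ValidationError("viscosity must be positive")


@dataclass(frozen=True)
class FlowCondition:
    """A volumetric flow rate; stored in µm³·s⁻¹."""

    rate: float

    def __post_init__(self) -> None:
        if not self.rate >= 0:
            raise ValidationError("flow rate must be non-negative")

    @classmethod
    def from_ul_min(cls, q_ul_min: float) -> "FlowCondition":
        return cls(units.flow_ul_min_to_um3_s(q_ul_min))

    @property
    def rate_ul_min(self) -> float:
        return units.flow_um3_s_to_ul_min(self.rate)


@dataclass(frozen=True)
class VelocityProfileSample:
    """One µPIV velocity sample along the horizontal or vertical center line.

    ``axis`` is ``"H"`` for the horizontal profile (y across [0, w] at
    mid-height) or ``"V"`` for the vertical one (z across [0, h] at
    mid-width).
    """

    axis: str
    position: float
    velocity: float
    z_plane: float | None = None

    def __post_init__(self) -> None:
        if self.axis not in ("H", "V"):
            raise ValidationError(f"axis must be 'H' or 'V', got {self.axis!r}")
        if not np.isfinite(self.velocity):
            raise ValidationError("velocity must be finite")


def _odd_n(n_max: int) -> np.ndarray:
    if n_max < 1 or n_max % 2 == 0:
        raise ValidationError(f"n_max must be an odd integer >= 1, got {n_max}")
    return np.arange(1, n_max + 1, 2, dtype=float)


def _cosh_ratio(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """cosh(a)/cosh(b) for |a| <= b, overflow-safe for large arguments."""
    a = np.abs(a)
    return (np.exp(a - b) + np.exp(-a - b)) / (1.0 + np.exp(-2.0 * b))


def _span_envelope(n: np.ndarray, y: np.ndarray, w: float, h: float) -> np.ndarray:
    """1 − cosh(nπ(y−w/2)/h)/cosh(nπw/2h); shape (len(n),) × y.shape."""
    arg = n[:, None] * np.pi * (np.atleast_1d(y)[None, :] - w / 2.0) / h
    brg = n[:, None] * np.pi * w / (2.0 * h)
    return 1.0 - _cosh_ratio(arg, np.broadcast_to(brg, arg.shape))


def _check_coords(geom: ChannelGeometry, y, z=None) -> None:
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y > geom.width):
        raise DomainError(f"y must lie in [0, {geom.width}] µm")
    if z is not None:
        z = np.asarray(z, dtype=float)
        if np.any(z < 0) or np.any(z > geom.height):
            raise DomainError(f"z must lie in [0, {geom.height}] µm")


def resistance_per_length(
    geom: ChannelGeometry, fluid: Fluid, n_max: int = 51
) -> float:
    """Hydraulic resistance per unit channel length, µN·s·µm⁻⁴ per µm.

    R_f = 12µ/(h³w) / [1 − (192 h / π⁵ w) Σ_{n odd} n⁻⁵ tanh(nπw/2h)],
    the standard rectangular-duct series.  G = R_f · Q reproduces the
    pressure gradient that drives ``velocity_field``.
    """
    n = _odd_n(n_max)
    w, h = geom.width, geom.height
    series = np.sum(np.tanh(n * np.pi * w / (2.0 * h)) / n**5)
    correction = 1.0 - 192.0 * h / (np.pi**5 * w) * series
    return 12.0 * fluid.viscosity / (h**3 * w * correction)


def velocity_field(
    geom: ChannelGeometry,
    fluid: Fluid,
    flow: FlowCondition,
    y,
    z,
    n_max: int = 51,
):
    """Poiseuille velocity u(y, z) in µm·s⁻¹, normalized so ∫∫u dA = Q.

    The pressure gradient is fixed from ``resistance_per_length`` (converged
    series), so truncating ``n_max`` affects only the local field shape, not
    the overall flow-rate normalization.
    """
    _check_coords(geom, y, z)
    w, h = geom.width, geom.height
    n = _odd_n(n_max)
    grad_p = resistance_per_length(geom, fluid) * flow.rate
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    y_b, z_b = np.broadcast_arrays(y_arr, z_arr)
    env = _span_envelope(n, y_b.ravel(), w, h)
    modes = np.sin(n[:, None] * np.pi * z_b.ravel()[None, :] / h)
    series = np.sum(env * modes / n[:, None] ** 3, axis=0)
    u = 4.0 * grad_p * h**2 / (np.pi**3 * fluid.viscosity) * series
    u = u.reshape(y_b.shape)
    if np.isscalar(y) and np.isscalar(z):
        return float(u[()] if u.shape == () else u[0])
    return u


def wall_velocity_gradient(
    geom: ChannelGeometry,
    fluid: Fluid,
    flow: FlowCondition,
    y,
    n_max: int = 51,
):
    """∂u/∂z at the channel floor (z → 0), in s⁻¹.

    Obtained by term-wise differentiation of the velocity series; this is the
    shear gradient that sets the drag on a specimen lying on the floor.
    """
    _check_coords(geom, y)
    w, h = geom.width, geom.height
    n = _odd_n(n_max)
    grad_p = resistance_per_length(geom, fluid) * flow.rate
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    env = _span_envelope(n, y_arr.ravel(), w, h)
    series = np.sum(env / n[:, None] ** 2, axis=0)
    g = 4.0 * grad_p * h / (np.pi**2 * fluid.viscosity) * series
    g = g.reshape(y_arr.shape)
    if np.isscalar(y):
        return float(g[0])
    return g


@dataclass(frozen=True)
class FlowRateFit:
    """Result of recovering Q from a measured velocity profile."""

    flow: FlowCondition
    residual_norm: float
    samples_used: tuple[VelocityProfileSample, ...]
    samples_excluded: tuple[VelocityProfileSample, ...] = field(default=())

    @property
    def n_used(self) -> int:
        return len(self.samples_used)


def fit_flow_rate(
    samples: Sequence[VelocityProfileSample],
    geom: ChannelGeometry,
    fluid: Fluid,
    include_vertical: bool = False,
    n_max: int = 51,
) -> FlowRateFit:
    """Least-squares estimate of the volumetric flow rate from a profile.

    The analytical profile at the measured positions, evaluated at unit flow
    rate, serves as the single regressor; the fitted scale factor is Q.  By
    default only horizontal (mid-height) samples enter the fit: the vertical
    profile is biased near the walls by the depth-of-field of the imaging
    system (apparent velocities of ~30 % of the maximum persist at the
    walls), so it is excluded unless ``include_vertical`` is set.
    """
    used = [s for s in samples if s.axis == "H" or include_vertical]
    excluded = [s for s in samples if s.axis == "V" and not include_vertical]
    if len(used) < 3:
        raise FitError(
            "no usable samples: need >= 3 samples on included axes "
            f"(got {len(used)}; vertical samples are excluded by default)"
        )
    v_meas = np.array([s.velocity for s in used])
    if np.allclose(v_meas, 0.0):
        raise FitError("degenerate profile: all measured velocities are zero")
    unit = FlowCondition(1.0)
    basis = np.empty(len(used))
    for i, s in enumerate(used):
        if s.axis == "H":
            basis[i] = velocity_field(
                geom, fluid, unit, s.position, geom.height / 2.0, n_max
            )
        else:
            basis[i] = velocity_field(
                geom, fluid, unit, geom.width / 2.0, s.position, n_max
            )
    q_hat = float(np.dot(basis, v_meas) / np.dot(basis, basis))
    resid = float(np.linalg.norm(v_meas - q_hat * basis))
    return FlowRateFit(
        flow=FlowCondition(max(q_hat, 0.0)),
        residual_norm=resid,
        samples_used=tuple(used),
        samples_excluded=tuple(excluded),
    )


# ---------------------------------------------------------------------------
# Tabular interface: comma-separated, header mandatory.
# Columns: axis {H,V}, position_um, velocity_um_s, z_plane_um (optional).

def read_velocity_profiles(path: str | Path) -> list[VelocityProfileSample]:
    df = pd.read_csv(path)
    required = {"axis", "position_um", "velocity_um_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"profile table missing columns: {sorted(missing)}")
    samples = []
    for row in df.itertuples(index=False):
        z_plane = getattr(row, "z_plane_um", None)
        if z_plane is not None and pd.isna(z_plane):
            z_plane = None
        samples.append(
            VelocityProfileSample(
                axis=str(row.axis),
                position=float(row.position_um),
                velocity=float(row.velocity_um_s),
                z_plane=None if z_plane is None else float(z_plane),
            )
        )
    return samples


def write_velocity_profiles(
    samples: Iterable[VelocityProfileSample], path: str | Path
) -> None:
    samples = list(samples)
    df = pd.DataFrame(
        {
            "axis": [s.axis for s in samples],
            "position_um": [s.position for s in samples],
            "velocity_um_s": [s.velocity for s in samples],
            "z_plane_um": [s.z_plane for s in samples],
        }
    )
    df.to_csv(path, index=False)
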