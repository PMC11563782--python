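"""Seeded synthetic experiment: virtual hyphae, deflections, µPIV profiles.

This module stands in for the wet lab.  It draws a population of hyphae
with realistic geometry (radius ≈ 1.4 µm, exposed lengths 30–150 µm,
growing from a side wall near the channel mid-height), pushes each one
through the forward bending model at a schedule of flow rates, adds Gaussian
measurement noise to the tip displacements, and emits the same delimited
tables the analysis side reads — plus a truth table of the underlying
bending stiffnesses for recovery scoring.  Velocity profiles mimic µPIV
output, optionally with the depth-of-field artifact that keeps the apparent
near-wall velocity of the vertical profile at ~30 % of the maximum.

Everything is reproducible from integer seeds; population draws and
measurement noise use separate sub-streams so either stage can be
regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hyphabend import units
from hyphabend.beam_mechanics import (
    HyphaGeometry,
    forward_model,
    unit_response,
)
from hyphabend.channel_flow import (
    ChannelGeometry,
    FlowCondition,
    Fluid,
    VelocityProfileSample,
    velocity_field,
)
from hyphabend.errors import ConvergenceError, ValidationError

__all__ = [
    "SyntheticExperimentConfig",
    "generate_hypha_population",
    "simulate_bending_experiment",
    "simulate_velocity_profiles",
    "truth_table",
]

#: apparent near-wall velocity floor of the vertical µPIV profile,
#: as a fraction of the center-line maximum (depth-of-field artifact)
ARTIFACT_FLOOR = 0.30


def _default_geometry() -> ChannelGeometry:
    return ChannelGeometry(width=500.0, height=90.0, configuration="center")


@dataclass(frozen=True)
class SyntheticExperimentConfig:
    """Study conditions for a simulated bending-test campaign.

    Defaults emulate the experimental envelope of the on-chip assay:
    exposed lengths uniform on 30–150 µm (hyphae shorter than 30 µm are not
    measured), radii normal around 1.4 µm, true stiffness log-normal around
    the published center-configuration mean of 18.3 µN·µm² with the
    published coefficient of variation (8.7/18.3), flow rates within the
    0–50 µL·min⁻¹ pump range, and Gaussian noise on the extracted tip
    displacement.  The chamber cross-section (w = 500 µm, h = 90 µm center /
    45 µm floor) is an assumption, not a published value, and is exposed
    here for exactly that reason.
    """

    geometry: ChannelGeometry = field(default_factory=_default_geometry)
    fluid: Fluid = field(default_factory=Fluid)
    n_hyphae: int = 20
    length_range: tuple[float, float] = (30.0, 150.0)
    radius_mean: float = 1.4
    radius_sd: float = 0.1
    wall_thickness: float = 0.287
    alpha0_sd_deg: float = 5.0
    dz_sd: float = 3.0
    kb_mean: float = 18.3
    kb_cv: float = 8.7 / 18.3
    kb_length_slope: float = 0.0       # µN·µm² per µm of exposed length
    flow_rates_ul_min: tuple[float, ...] | None = None
    n_flow_rates: int = 6
    max_flow_ul_min: float = 50.0
    target_relative_deflection: float = 0.2
    noise_sd: float = 0.2              # µm, on the measured x-displacement
    n_max: int = 11

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo < hi):
            raise ValidationError("length_range must be increasing and positive")
        for name in ("radius_mean", "radius_sd", "wall_thickness", "kb_mean",
                     "kb_cv", "max_flow_ul_min", "target_relative_deflection"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.noise_sd < 0 or self.dz_sd < 0 or self.alpha0_sd_deg < 0:
            raise ValidationError("spread parameters must be non-negative")
        if self.n_hyphae < 0:
            raise ValidationError("n_hyphae must be >= 0")
        if self.n_flow_rates < 1:
            raise ValidationError("need at least one flow rate")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _truncated_normal(
    rng: np.random.Generator, mean, sd, low, high, size
) -> np.ndarray:
    """Normal draws truncated to (low, high) by resampling."""
    if sd == 0.0:
        return np.full(size, mean, dtype=float)
    out = rng.normal(mean, sd, size)
    bad = (out <= low) | (out >= high)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= low) | (out >= high)
    return out


def generate_hypha_population(
    config: SyntheticExperimentConfig, seed
) -> tuple[list[HyphaGeometry], np.ndarray]:
    """Draw a reproducible population and its true bending stiffnesses.

    The true k_b is log-normal around ``kb_mean`` with coefficient of
    variation ``kb_cv``; a non-zero ``kb_length_slope`` adds a linear
    dependence on exposed length (centered on the mid-range length, so the
    population mean stays at ``kb_mean``), emulating cell-wall maturation
    along older, longer hyphae.
    """
    rng = _rng(seed)
    n = config.n_hyphae
    lo, hi = config.length_range
    h = config.geometry.height
    lengths = rng.uniform(lo, hi, n)
    radii = _truncated_normal(
        rng, config.radius_mean, config.radius_sd,
        2.0 * config.wall_thickness, np.inf, n,
    )
    alpha0 = _truncated_normal(
        rng, 0.0, math.radians(config.alpha0_sd_deg),
        -math.pi / 2, math.pi / 2, n,
    )
    dz = _truncated_normal(rng, 0.0, config.dz_sd, -h / 2, h / 2, n)

    sigma2 = math.log(1.0 + config.kb_cv**2)
    mu = math.log(config.kb_mean) - sigma2 / 2.0
    kb = rng.lognormal(mu, math.sqrt(sigma2), n)
    if config.kb_length_slope != 0.0:
        kb = kb + config.kb_length_slope * (lengths - (lo + hi) / 2.0)
        kb = np.maximum(kb, 0.1 * config.kb_mean)

    hyphae = [
        HyphaGeometry(
            radius=float(radii[i]),
            wall_thickness=config.wall_thickness,
            length=float(lengths[i]),
            base_position=0.0,
            alpha0=float(alpha0[i]),
            dz=float(dz[i]),
        )
        for i in range(n)
    ]
    return hyphae, kb


def _flow_schedule_ul_min(
    config: SyntheticExperimentConfig,
    hypha: HyphaGeometry,
    kb: float,
    response: float,
) -> np.ndarray:
    """Per-hypha flow rates (µL·min⁻¹), excluding the Q = 0 anchor.

    With no explicit schedule, the top rate is chosen so the predicted tip
    deflection reaches ``target_relative_deflection``·L — mirroring how an
    experimenter dials the pump per specimen — and capped at the pump range.
    """
    if config.flow_rates_ul_min is not None:
        return np.asarray(config.flow_rates_ul_min, dtype=float)
    q_target = config.target_relative_deflection * hypha.length * kb / response
    q_max = min(units.flow_um3_s_to_ul_min(q_target), config.max_flow_ul_min)
    steps = np.arange(1, config.n_flow_rates + 1) / config.n_flow_rates
    return q_max * steps


def simulate_bending_experiment(
    population: list[HyphaGeometry],
    true_kb: np.ndarray,
    config: SyntheticExperimentConfig,
    seed,
) -> pd.DataFrame:
    """Forward-model deflections plus noise, as a measurement table.

    For every hypha a Q = 0 anchor row (displacement = noise only) precedes
    the scheduled flow rates.  The deflected angle α₁ is recorded from the
    noiseless forward solve, matching how angles are read from images
    independently of the tip-coordinate noise.  Rows whose forward solve
    fails to converge are flagged excluded rather than dropped.
    """
    if len(population) != len(true_kb):
        raise ValidationError(
            f"population ({len(population)}) and truth ({len(true_kb)}) "
            "lengths differ"
        )
    rng = _rng(seed)
    rows = []
    for i, (hypha, kb) in enumerate(zip(population, true_kb)):
        hid = f"h{i:03d}"
        response = unit_response(
            hypha, config.geometry, config.fluid, config.n_max
        )
        alpha0_deg = float(units.rad_to_deg(hypha.alpha0))
        rates = _flow_schedule_ul_min(config, hypha, kb, response)
        for q_ul in np.concatenate([[0.0], rates]):
            flow = FlowCondition.from_ul_min(float(q_ul))
            try:
                res = forward_model(
                    hypha, config.geometry, config.fluid, flow, kb,
                    n_max=config.n_max, response=response,
                )
                x_disp = res.x_displacement + rng.normal(0.0, config.noise_sd)
                alpha1_deg = float(units.rad_to_deg(res.alpha1))
                failed = 0
            except ConvergenceError:
                x_disp = float("nan")
                alpha1_deg = float("nan")
                failed = 1
            rows.append(
                {
                    "hypha_id": hid,
                    "Q_uL_min": float(q_ul),
                    "x_disp_um": x_disp,
                    "alpha0_deg": alpha0_deg,
                    "alpha1_deg": alpha1_deg,
                    "exclude": failed,
                }
            )
    columns = ["hypha_id", "Q_uL_min", "x_disp_um", "alpha0_deg",
               "alpha1_deg", "exclude"]
    return pd.DataFrame(rows, columns=columns)


def truth_table(true_kb: np.ndarray) -> pd.DataFrame:
    """Truth table (hypha_id, true_kb) for recovery scoring."""
    return pd.DataFrame(
        {
            "hypha_id": [f"h{i:03d}" for i in range(len(true_kb))],
            "true_kb": np.asarray(true_kb, dtype=float),
        }
    )


def simulate_velocity_profiles(
    geom: ChannelGeometry,
    fluid: Fluid,
    flow: FlowCondition,
    artifact_on: bool = True,
    noise_rel: float = 0.0,
    seed=None,
    n_points: int = 41,
) -> list[VelocityProfileSample]:
    """µPIV-like horizontal and vertical center-line velocity profiles.

    The horizontal profile (across the width at mid-height) follows the
    exact series solution plus multiplicative Gaussian noise.  The vertical
    profile (across the height at mid-width) is optionally clamped from
    below at 30 % of the center maximum — the simplest model of the
    depth-of-field artifact, by which out-of-focus particles keep the
    apparent velocity from reaching zero at the horizontal walls.
    """
    if noise_rel < 0:
        raise ValidationError("noise_rel must be >= 0")
    rng = _rng(seed)
    w, h = geom.width, geom.height
    u_max = velocity_field(geom, fluid, flow, w / 2.0, h / 2.0)
    samples: list[VelocityProfileSample] = []

    y_pos = np.linspace(0.0, w, n_points)
    u_h = np.atleast_1d(velocity_field(geom, fluid, flow, y_pos, h / 2.0))
    if noise_rel > 0:
        u_h = u_h * (1.0 + rng.normal(0.0, noise_rel, u_h.shape))
    for p, v in zip(y_pos, u_h):
        samples.append(
            VelocityProfileSample("H", float(p), float(v), z_plane=h / 2.0)
        )

    z_pos = np.linspace(0.0, h, n_points)
    u_v = np.atleast_1d(velocity_field(geom, fluid, flow, w / 2.0, z_pos))
    if artifact_on:
        u_v = np.maximum(u_v, ARTIFACT_FLOOR * u_max)
    if noise_rel > 0:
        u_v = u_v * (1.0 + rng.normal(0.0, noise_rel, u_v.shape))
    for p, v in zip(z_pos, u_v):
        samples.append(VelocityProfileSample("V", float(p), float(v)))
    return samples
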