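"""End-to-end orchestration: configuration, runs, and the study report.

A run is driven by one structured YAML configuration (command-line options
override file values, which override defaults).  ``run_simulate`` writes a
full synthetic experiment to disk; ``run_fit`` reads measurement and hypha
tables, fits every specimen, converts stiffnesses to cell-wall moduli,
summarizes the population and regresses bending stiffness on exposed length
(ordinary least squares, two-sided slope test); ``run_flow_fit`` recovers
the flow rate from a velocity-profile table; ``run_design`` sizes the
loading serpentine and sweeps channel blocking.

Reports carry provenance (config hash, seed, package version) and contain
no timestamps, so re-running an identical configuration reproduces the
report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

import hyphabend
from hyphabend import units
from hyphabend.beam_mechanics import (
    BendingFitResult,
    fit_bending_stiffness,
    measurements_from_frame,
    read_hypha_table,
    read_measurement_table,
    write_hypha_table,
    write_measurement_table,
)
from hyphabend.cell_wall import population_modulus, second_moment_annulus
from hyphabend.channel_flow import (
    ChannelGeometry,
    Fluid,
    fit_flow_rate,
    read_velocity_profiles,
    write_velocity_profiles,
)
from hyphabend.errors import FitError, ValidationError
from hyphabend.loading_circuit import (
    LoadingDesign,
    blocking_sweep,
    loading_flow_ratio,
    serpentine_resistance_for_ratio,
)
from hyphabend.synthetic_data import (
    SyntheticExperimentConfig,
    generate_hypha_population,
    simulate_bending_experiment,
    simulate_velocity_profiles,
    truth_table,
)

__all__ = [
    "RunConfig",
    "StudyReport",
    "run_fit",
    "run_simulate",
    "run_flow_fit",
    "run_design",
    "summarize_per_hypha",
]

logger = logging.getLogger("hyphabend")


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run, with file/CLI override semantics."""

    seed: int = 0
    out_dir: str = "results"
    geometry: ChannelGeometry = field(
        default_factory=lambda: ChannelGeometry(500.0, 90.0, "center")
    )
    fluid: Fluid = field(default_factory=Fluid)
    synthetic: SyntheticExperimentConfig = field(
        default_factory=SyntheticExperimentConfig
    )
    design: LoadingDesign = field(default_factory=LoadingDesign)
    n_max: int = 11
    include_tip_force: bool = True
    intercept: bool = False
    center_tolerance: float = 10.0
    measurements_path: str | None = None
    hyphae_path: str | None = None
    profiles_path: str | None = None

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        if "geometry" in raw:
            kwargs["geometry"] = ChannelGeometry(**raw.pop("geometry"))
        if "fluid" in raw:
            kwargs["fluid"] = Fluid(**raw.pop("fluid"))
        if "synthetic" in raw:
            syn = dict(raw.pop("synthetic"))
            if "geometry" in syn:
                syn["geometry"] = ChannelGeometry(**syn["geometry"])
            elif "geometry" in kwargs:
                syn["geometry"] = kwargs["geometry"]
            if "fluid" in syn:
                syn["fluid"] = Fluid(**syn["fluid"])
            if "flow_rates_ul_min" in syn and syn["flow_rates_ul_min"] is not None:
                syn["flow_rates_ul_min"] = tuple(syn["flow_rates_ul_min"])
            kwargs["synthetic"] = SyntheticExperimentConfig(**syn)
        elif "geometry" in kwargs:
            kwargs["synthetic"] = SyntheticExperimentConfig(
                geometry=kwargs["geometry"]
            )
        if "design" in raw:
            kwargs["design"] = LoadingDesign(**raw.pop("design"))
        if "paths" in raw:
            paths = raw.pop("paths")
            for key in ("measurements", "hyphae", "profiles"):
                if key in paths:
                    kwargs[f"{key}_path"] = paths[key]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def override(self, **kwargs: Any) -> "RunConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        def convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            return obj

        return convert(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class StudyReport:
    """Per-hypha results plus recomputable population summaries."""

    per_hypha: pd.DataFrame
    summary: dict[str, Any]
    regression: dict[str, Any]
    exclusions: list[dict[str, Any]]
    provenance: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "per_hypha": self.per_hypha.to_dict(orient="records"),
            "summary": self.summary,
            "regression": self.regression,
            "exclusions": self.exclusions,
            "provenance": self.provenance,
        }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report_path = out / "report.json"
        table_path = out / "per_hypha.csv"
        report_path.write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        self.per_hypha.to_csv(table_path, index=False)
        return {"report": report_path, "per_hypha": table_path}


def _kb_length_regression(per_hypha: pd.DataFrame) -> dict[str, Any]:
    """OLS of fitted k_b on exposed length with a two-sided slope test."""
    if len(per_hypha) < 3:
        return {
            "n": int(len(per_hypha)),
            "slope": None,
            "intercept": None,
            "slope_p_value": None,
            "r_squared": None,
            "note": "fewer than 3 hyphae; regression skipped",
        }
    x = sm.add_constant(per_hypha["L_um"].to_numpy())
    model = sm.OLS(per_hypha["k_b"].to_numpy(), x).fit()
    return {
        "n": int(len(per_hypha)),
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "slope_p_value": float(model.pvalues[1]),
        "r_squared": float(model.rsquared),
    }


def summarize_per_hypha(per_hypha: pd.DataFrame) -> dict[str, Any]:
    """Population summary recomputable from the per-hypha rows."""
    if per_hypha.empty:
        return {"n_hyphae": 0}
    kb = per_hypha["k_b"].to_numpy()
    e = per_hypha["E_MPa"].to_numpy()
    return {
        "n_hyphae": int(len(per_hypha)),
        "kb_mean": float(np.mean(kb)),
        "kb_sd": float(np.std(kb, ddof=1)) if len(kb) > 1 else 0.0,
        "E_mean_MPa": float(np.mean(e)),
        "E_sd_MPa": float(np.std(e, ddof=1)) if len(e) > 1 else 0.0,
        "E_of_mean_kb_MPa": float(
            np.mean(kb)
            / second_moment_annulus(
                float(per_hypha["r_um"].mean()),
                float(per_hypha["t_um"].mean()),
            )
        ),
        "points_used_total": int(per_hypha["n_points_used"].sum()),
        "points_excluded_total": int(per_hypha["n_points_excluded"].sum()),
    }


def run_fit(config: RunConfig) -> StudyReport:
    """Fit every hypha in the measurement table and assemble the report."""
    if config.measurements_path is None or config.hyphae_path is None:
        raise ValidationError(
            "run_fit requires paths.measurements and paths.hyphae"
        )
    measurements = read_measurement_table(config.measurements_path)
    hyphae = read_hypha_table(config.hyphae_path)
    rows = []
    exclusions: list[dict[str, Any]] = []
    for hid, group in measurements.groupby("hypha_id", sort=True):
        hid = str(hid)
        if hid not in hyphae:
            exclusions.append(
                {"hypha_id": hid, "reason": "no geometry record"}
            )
            logger.warning("hypha %s: no geometry record; skipped", hid)
            continue
        hypha = hyphae[hid]
        clean = group.dropna(subset=["x_disp_um", "alpha1_deg"])
        n_dropped = len(group) - len(clean)
        if n_dropped:
            logger.warning(
                "hypha %s: %d unparseable rows dropped", hid, n_dropped
            )
        try:
            records = measurements_from_frame(clean)
            fit = fit_bending_stiffness(
                records,
                hypha,
                config.geometry,
                config.fluid,
                n_max=config.n_max,
                include_tip_force=config.include_tip_force,
                intercept=config.intercept,
                center_tolerance=config.center_tolerance,
            )
        except (FitError, ValidationError) as exc:
            exclusions.append({"hypha_id": hid, "reason": str(exc)})
            logger.warning("hypha %s: %s", hid, exc)
            continue
        i_annulus = second_moment_annulus(hypha.radius, hypha.wall_thickness)
        rows.append(
            {
                "hypha_id": hid,
                "L_um": hypha.length,
                "r_um": hypha.radius,
                "t_um": hypha.wall_thickness,
                "k_b": fit.k_b,
                "k_b_stderr": fit.k_b_stderr,
                "intercept_um": fit.intercept,
                "I_um4": i_annulus,
                "E_MPa": fit.k_b / i_annulus,
                "n_points_used": fit.n_used,
                "n_points_excluded": fit.n_excluded + n_dropped,
            }
        )
    per_hypha = pd.DataFrame(
        rows,
        columns=[
            "hypha_id", "L_um", "r_um", "t_um", "k_b", "k_b_stderr",
            "intercept_um", "I_um4", "E_MPa", "n_points_used",
            "n_points_excluded",
        ],
    )
    if per_hypha.empty:
        raise FitError(
            "zero fittable hyphae; exclusions: "
            + "; ".join(f"{e['hypha_id']}: {e['reason']}" for e in exclusions)
        )
    summary = summarize_per_hypha(per_hypha)
    pop = population_modulus(
        per_hypha["k_b"].to_numpy(),
        float(per_hypha["r_um"].mean()),
        float(per_hypha["t_um"].mean()),
    )
    summary["E_aggregation_routes"] = {
        k: v for k, v in pop.items() if k != "second_moment_um4"
    }
    report = StudyReport(
        per_hypha=per_hypha,
        summary=summary,
        regression=_kb_length_regression(per_hypha),
        exclusions=exclusions,
        provenance={
            "config_hash": config.digest(),
            "seed": config.seed,
            "version": hyphabend.__version__,
        },
    )
    return report


def run_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate a full synthetic experiment on disk.

    Uses separated sub-streams of the master seed for the population draw,
    the measurement noise and the velocity profiles, so fixed seeds yield
    identical files run over run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    syn = config.synthetic
    population, true_kb = generate_hypha_population(syn, seeds[0])
    measurements = simulate_bending_experiment(
        population, true_kb, syn, seeds[1]
    )
    profiles = simulate_velocity_profiles(
        syn.geometry,
        syn.fluid,
        # a representative mid-range measurement flow for the µPIV emulation
        flow=_representative_flow(measurements),
        artifact_on=True,
        noise_rel=0.02,
        seed=seeds[2],
    )
    hyphae = {f"h{i:03d}": h for i, h in enumerate(population)}
    paths = {
        "hyphae": out / "hyphae.csv",
        "measurements": out / "measurements.csv",
        "truth": out / "truth.csv",
        "profiles": out / "profiles.csv",
    }
    write_hypha_table(hyphae, paths["hyphae"])
    write_measurement_table(measurements, paths["measurements"])
    truth_table(true_kb).to_csv(paths["truth"], index=False)
    write_velocity_profiles(profiles, paths["profiles"])
    logger.info(
        "simulated %d hyphae (seed=%s, config=%s)",
        len(population),
        config.seed,
        config.digest(),
    )
    return paths


def _representative_flow(measurements: pd.DataFrame):
    from hyphabend.channel_flow import FlowCondition

    if measurements.empty:
        return FlowCondition.from_ul_min(10.0)
    q = measurements.loc[measurements["Q_uL_min"] > 0, "Q_uL_min"]
    return FlowCondition.from_ul_min(float(q.median()) if len(q) else 10.0)


def run_flow_fit(config: RunConfig, include_vertical: bool = False) -> dict:
    """Recover the flow rate from a velocity-profile table."""
    if config.profiles_path is None:
        raise ValidationError("run_flow_fit requires paths.profiles")
    samples = read_velocity_profiles(config.profiles_path)
    fit = fit_flow_rate(
        samples, config.geometry, config.fluid, include_vertical=include_vertical
    )
    return {
        "Q_uL_min": fit.flow.rate_ul_min,
        "Q_um3_s": fit.flow.rate,
        "residual_norm_um_s": fit.residual_norm,
        "n_samples_used": fit.n_used,
        "n_samples_excluded": len(fit.samples_excluded),
    }


def run_design(config: RunConfig) -> dict[str, Any]:
    """Serpentine sizing, flow-ratio summary and the blocking sweep."""
    design = config.design
    fluid = config.fluid
    r_serp = (
        design.serpentine_resistance
        if design.serpentine_resistance is not None
        else serpentine_resistance_for_ratio(design, fluid)
    )
    ratio, p_chamber = loading_flow_ratio(design, fluid)
    sweep = blocking_sweep(design, fluid)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sweep_path = out / "blocking_sweep.csv"
    sweep.to_csv(sweep_path, index=False)
    return {
        "serpentine_resistance": r_serp,
        "flow_ratio_initial": ratio,
        "chamber_pressure_pa_initial": p_chamber * units.MPA_TO_PA,
        "sweep_path": sweep_path,
        "ratio_monotone_decreasing": bool(
            np.all(np.diff(sweep["flow_ratio"].to_numpy()) <= 1e-12)
        ),
        "pressure_monotone_increasing": bool(
            np.all(np.diff(sweep["chamber_pressure_pa"].to_numpy()) >= -1e-12)
        ),
    }
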