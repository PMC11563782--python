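"""Cell-wall elasticity from bending stiffness.

The hyphal cross-section is an annulus: cell wall of thickness t around a
lumen, outer radius r.  Its second moment of area is

    I = (π/4)·(r⁴ − (r − t)⁴),

and since the bending stiffness of a slender beam is k_b = E·I, the
longitudinal Young's modulus of the wall material follows as E = k_b/I.
In canonical units (k_b in µN·µm², I in µm⁴) E emerges directly in MPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hyphabend.errors import ValidationError

__all__ = [
    "WallElasticityResult",
    "second_moment_annulus",
    "youngs_modulus",
    "population_modulus",
]


@dataclass(frozen=True)
class WallElasticityResult:
    """Second moment of area and derived Young's modulus, inputs echoed."""

    second_moment: float       # µm⁴
    youngs_modulus: float      # MPa
    bending_stiffness: float   # µN·µm²
    radius: float              # µm
    wall_thickness: float      # µm


def second_moment_annulus(r: float, t: float) -> float:
    """Second moment of area I (µm⁴) of an annular cross-section.

    ``t = r`` degenerates to the solid circle πr⁴/4; small t approaches the
    thin-wall limit πr³t.
    """
    if not 0 < t <= r:
        raise ValidationError(
            f"wall thickness must satisfy 0 < t <= r, got t={t}, r={r}"
        )
    return float(np.pi / 4.0 * (r**4 - (r - t) ** 4))


def youngs_modulus(k_b: float, r: float, t: float) -> WallElasticityResult:
    """Longitudinal Young's modulus E = k_b/I of the cell wall, in MPa."""
    if not k_b > 0:
        raise ValidationError("bending stiffness k_b must be positive")
    i = second_moment_annulus(r, t)
    return WallElasticityResult(
        second_moment=i,
        youngs_modulus=k_b / i,
        bending_stiffness=k_b,
        radius=r,
        wall_thickness=t,
    )


def population_modulus(
    k_b_values, r: float, t: float
) -> dict[str, float]:
    """Population-level modulus by two aggregation routes.

    ``E_of_mean_kb`` divides the mean stiffness by I (the route that
    reproduces published center-configuration values); ``mean_of_E``
    averages per-specimen moduli.  The two differ only through sampling
    spread, but with few specimens the difference can be material, so both
    are reported.
    """
    k_b_values = np.asarray(k_b_values, dtype=float)
    if k_b_values.size == 0:
        raise ValidationError("empty bending-stiffness sample")
    i = second_moment_annulus(r, t)
    return {
        "second_moment_um4": i,
        "E_of_mean_kb_MPa": float(np.mean(k_b_values)) / i,
        "mean_of_E_MPa": float(np.mean(k_b_values / i)),
        "sd_of_E_MPa": float(np.std(k_b_values / i, ddof=1))
        if k_b_values.size > 1
        else 0.0,
    }
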