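"""Unit conventions and conversion helpers.

Canonical internal units are µm (length), s (time) and µN (force).  Derived
units then come out as:

* pressure: µN·µm⁻² ≡ MPa
* dynamic viscosity: µN·s·µm⁻² (water at 20 °C ≈ 1.0e-9)
* volumetric flow rate: µm³·s⁻¹
* bending stiffness: µN·µm²
* Young's modulus: µN·µm⁻² ≡ MPa

Flow rates are accepted at the interface in µL·min⁻¹ (the unit used on
syringe pumps) and converted on construction; forces per unit length are
reported in pN·µm⁻¹ at interfaces.
"""

import numpy as np

#: 1 µL·min⁻¹ in µm³·s⁻¹ (1 µL = 1e9 µm³).
UL_PER_MIN = 1.0e9 / 60.0

#: Dynamic viscosity of water at 20 °C in µN·s·µm⁻² (= 1.0 mPa·s).
WATER_VISCOSITY = 1.0e-9

#: 1 µN·µm⁻¹ in pN·µm⁻¹.
UN_PER_UM_TO_PN_PER_UM = 1.0e6

#: 1 µN·µm⁻² (MPa) in Pa.
MPA_TO_PA = 1.0e6


def flow_ul_min_to_um3_s(q_ul_min: float) -> float:
    """Convert a volumetric flow rate from µL·min⁻¹ to µm³·s⁻¹."""
    return float(q_ul_min) * UL_PER_MIN


def flow_um3_s_to_ul_min(q_um3_s: float) -> float:
    """Convert a volumetric flow rate from µm³·s⁻¹ to µL·min⁻¹."""
    return float(q_um3_s) / UL_PER_MIN


def deg_to_rad(angle_deg):
    return np.deg2rad(angle_deg)


def rad_to_deg(angle_rad):
    return np.rad2deg(angle_rad)
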