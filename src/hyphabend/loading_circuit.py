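"""Equivalent fluidic-circuit model of the spore-loading design.

During spore loading, the flow entering the loading chamber splits between a
serpentine bypass to one outlet and N parallel growth channels (the cell
traps) toward the measurement side.  Hydraulic resistances compose like
electrical ones, so the design reduces to a small resistor network: solving
the nodal equations gives the flow partition and the chamber pressure.

The serpentine is dimensioned so its resistance is a fixed multiple
(20 by default) of the parallel resistance of all open growth channels;
with ideal outlets this makes the growth-to-serpentine flow ratio equal to
that multiple at the start of loading.  As spores plug channels the parallel
resistance rises, the ratio falls and the chamber pressure climbs — up to a
finite maximum when every channel is blocked, which is what makes the
loading step safe against overpressure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from hyphabend import units
from hyphabend.channel_flow import ChannelGeometry, Fluid, resistance_per_length
from hyphabend.errors import NetworkError, ValidationError

__all__ = [
    "Resistor",
    "FluidicNetwork",
    "NetworkSolution",
    "LoadingDesign",
    "growth_channel_resistance",
    "build_network",
    "solve_network",
    "loading_flow_ratio",
    "blocking_sweep",
    "serpentine_resistance_for_ratio",
]


@dataclass(frozen=True)
class Resistor:
    """A hydraulic resistor between two nodes; R in µN·s·µm⁻⁵ (MPa·s·µm⁻³)."""

    name: str
    node_a: str
    node_b: str
    resistance: float

    def __post_init__(self) -> None:
        if not self.resistance > 0:
            raise ValidationError(
                f"resistance of {self.name!r} must be positive, "
                f"got {self.resistance}"
            )
        if self.node_a == self.node_b:
            raise ValidationError(f"resistor {self.name!r} shorts a node to itself")


@dataclass(frozen=True)
class FluidicNetwork:
    """Resistor network with imposed inflows and one reference-pressure node."""

    resistors: tuple[Resistor, ...]
    inflows: dict[str, float] = field(default_factory=dict)
    reference: str = "outlet"

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.resistors:
            seen.setdefault(r.node_a)
            seen.setdefault(r.node_b)
        seen.setdefault(self.reference)
        for n in self.inflows:
            seen.setdefault(n)
        return list(seen)


@dataclass(frozen=True)
class NetworkSolution:
    """Node pressures (MPa, relative to reference) and branch flows (µm³·s⁻¹).

    Branch flows are positive from ``node_a`` to ``node_b`` of each resistor.
    """

    pressures: dict[str, float]
    flows: dict[str, float]
    conservation_residual: float


def solve_network(network: FluidicNetwork) -> NetworkSolution:
    """Nodal analysis: solve for pressures and branch flows.

    Builds the conductance (weighted-Laplacian) system for all non-reference
    nodes and solves it densely; mass conservation then holds at every node
    to linear-solver accuracy.
    """
    nodes = network.nodes
    unknown = [n for n in nodes if n != network.reference]
    idx = {n: i for i, n in enumerate(unknown)}

    # connectivity to the reference node
    adjacency: dict[str, set[str]] = {n: set() for n in nodes}
    for r in network.resistors:
        adjacency[r.node_a].add(r.node_b)
        adjacency[r.node_b].add(r.node_a)
    reached = {network.reference}
    stack = [network.reference]
    while stack:
        for nb in adjacency[stack.pop()]:
            if nb not in reached:
                reached.add(nb)
                stack.append(nb)
    floating = [n for n in nodes if n not in reached]
    if floating:
        raise NetworkError(
            f"network is disconnected: nodes {floating} have no resistive "
            "path to the reference node"
        )

    g = np.zeros((len(unknown), len(unknown)))
    rhs = np.zeros(len(unknown))
    for r in network.resistors:
        c = 1.0 / r.resistance
        for a, b in ((r.node_a, r.node_b), (r.node_b, r.node_a)):
            if a in idx:
                g[idx[a], idx[a]] += c
                if b in idx:
                    g[idx[a], idx[b]] -= c
    for node, q in network.inflows.items():
        if node in idx:
            rhs[idx[node]] += q
    p_unknown = np.linalg.solve(g, rhs) if unknown else np.array([])

    pressures = {network.reference: 0.0}
    pressures.update({n: float(p_unknown[i]) for n, i in idx.items()})
    flows = {
        r.name: (pressures[r.node_a] - pressures[r.node_b]) / r.resistance
        for r in network.resistors
    }

    # conservation check: net flow at each node vs imposed injections
    residual = 0.0
    total_in = sum(abs(q) for q in network.inflows.values()) or 1.0
    for n in unknown:
        net = network.inflows.get(n, 0.0)
        for r in network.resistors:
            if r.node_a == n:
                net -= flows[r.name]
            elif r.node_b == n:
                net += flows[r.name]
        residual = max(residual, abs(net) / total_in)
    return NetworkSolution(pressures, flows, residual)


@dataclass(frozen=True)
class LoadingDesign:
    """Parameters of the spore-loading fluidic design.

    The growth channels are modeled as square ducts with side equal to the
    hydraulic diameter (2.8 µm; the fabricated funnel shape is approximated
    away).  The serpentine resistance is either given explicitly or derived
    from the design rule ``serpentine_factor`` × (parallel resistance of all
    N open channels).  Downstream chamber/outlet resistances default to zero
    (ideal outlets), matching the simplified design circuit.
    """

    n_channels: int = 80
    channel_hydraulic_diameter: float = 2.8    # µm
    channel_length: float = 100.0              # µm (assumed; cancels in ratio)
    serpentine_factor: float | None = 20.0
    serpentine_resistance: float | None = None
    chamber_resistance: float = 0.0
    outlet_resistance: float = 0.0
    blocked: int = 0
    loading_flow_ul_min: float = 108.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValidationError("need at least one growth channel")
        if not 0 <= self.blocked <= self.n_channels:
            raise ValidationError(
                f"blocked must lie in [0, {self.n_channels}], got {self.blocked}"
            )
        if self.chamber_resistance < 0 or self.outlet_resistance < 0:
            raise ValidationError("downstream resistances must be >= 0")


def growth_channel_resistance(design: LoadingDesign, fluid: Fluid) -> float:
    """Hydraulic resistance of one open growth channel (square-duct model)."""
    d = design.channel_hydraulic_diameter
    geom = ChannelGeometry(width=d, height=d, configuration="floor")
    return resistance_per_length(geom, fluid) * design.channel_length


def serpentine_resistance_for_ratio(
    design: LoadingDesign, fluid: Fluid, ratio: float | None = None
) -> float:
    """Serpentine resistance sized as ``ratio`` × the N-channel parallel value."""
    if ratio is None:
        ratio = design.serpentine_factor
    r_single = growth_channel_resistance(design, fluid)
    return float(ratio) * r_single / design.n_channels


def build_network(design: LoadingDesign, fluid: Fluid) -> FluidicNetwork:
    """Assemble the loading-design resistor network.

    Loading-chamber node with the imposed loading inflow; serpentine branch
    to Outlet 1; the open growth channels as one equivalent parallel
    resistor toward the measurement chamber and Outlet 2.  Blocked channels
    are removed outright (spores as perfect plugs).  Zero-valued downstream
    resistors are collapsed by wiring the branch straight to the outlet
    reference node, which keeps every stored resistance strictly positive.
    """
    n_open = design.n_channels - design.blocked
    if design.serpentine_resistance is not None:
        r_serp = design.serpentine_resistance
    elif design.serpentine_factor is not None:
        r_serp = serpentine_resistance_for_ratio(design, fluid)
    else:
        r_serp = None
    if n_open == 0 and r_serp is None:
        raise NetworkError(
            "all growth channels blocked and no serpentine: the loading "
            "inlet has no path to any outlet"
        )
    resistors: list[Resistor] = []
    if r_serp is not None:
        resistors.append(Resistor("serpentine", "chamber", "outlet", r_serp))
    if n_open > 0:
        r_par = growth_channel_resistance(design, fluid) / n_open
        downstream = design.chamber_resistance + design.outlet_resistance
        if downstream > 0:
            resistors.append(Resistor("growth", "chamber", "measurement", r_par))
            resistors.append(
                Resistor("downstream", "measurement", "outlet", downstream)
            )
        else:
            resistors.append(Resistor("growth", "chamber", "outlet", r_par))
    inflow = units.flow_ul_min_to_um3_s(design.loading_flow_ul_min)
    return FluidicNetwork(
        resistors=tuple(resistors),
        inflows={"chamber": inflow},
        reference="outlet",
    )


def loading_flow_ratio(
    design: LoadingDesign, fluid: Fluid
) -> tuple[float, float]:
    """Growth-to-serpentine flow ratio and mean chamber pressure (MPa).

    With the serpentine sized by the 20× rule and ideal outlets the ratio is
    exactly the sizing factor at the start of loading (no channels blocked).
    """
    sol = solve_network(build_network(design, fluid))
    q_growth = sol.flows.get("growth", 0.0)
    q_serp = sol.flows.get("serpentine", 0.0)
    ratio = q_growth / q_serp if q_serp != 0.0 else float("inf")
    return ratio, sol.pressures["chamber"]


def blocking_sweep(
    design: LoadingDesign, fluid: Fluid, blocked=None
) -> pd.DataFrame:
    """Solve the network for each blocking count.

    Returns a table of (blocked, flow_ratio, chamber_pressure_pa); the ratio
    decreases and the pressure increases monotonically as spores fill the
    traps, with the pressure maximal when every channel is blocked.
    """
    if blocked is None:
        blocked = range(design.n_channels + 1)
    rows = []
    for b in blocked:
        ratio, p_chamber = loading_flow_ratio(replace(design, blocked=int(b)), fluid)
        rows.append(
            {
                "blocked": int(b),
                "flow_ratio": ratio,
                "chamber_pressure_pa": p_chamber * units.MPA_TO_PA,
            }
        )
    return pd.DataFrame(rows)
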