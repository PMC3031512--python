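"""Closed-form characterization of the microfluidic flow regime.

Analytic, empty-channel approximations to the quantities that determine
whether a co-flow channel can hold a sharp laminar interface over a tissue
explant without shearing it off:

* mean velocity ``U = Q/(w*h)``;
* Reynolds number ``Re = rho*U*D_h/mu`` with hydraulic diameter
  ``D_h = 4wh/(2(w+h))`` — Re < 1 means strictly viscous flow;
* Peclet number ``Pe = U*L/D`` — large Pe means a sharp inter-stream
  interface (characteristic length defaults to the channel width, the scale
  governing cross-stream interface integrity; height or hydraulic diameter
  can be passed instead);
* bottom-wall shear rate ``6Q/(w*h^2)`` (infinite-parallel-plate
  approximation, adequate for wide slots, here w/h = 5) — the explants sit
  on the bottom wall;
* hydraulic resistance of a rectangular duct,
  ``R = 12*mu*L / (w*h^3*(1 - 0.63*h/w))`` (one-term series approximation,
  valid for h <= w);
* downstream diffusive broadening of the laminar interface from the 1D
  depth-averaged solution ``C(y) = 0.5*erfc(y / (2*sqrt(D*x/U)))``, reported
  as the full width between the two cross-stream positions where the mass
  fraction passes a threshold (convention: 10%).

The 3D obstruction of the explant itself is not modeled; these formulas
bound the empty channel. The diffusion width here is depth-averaged and
therefore wider than a mid-plane finite-element value would be.

Units follow microfluidics practice: geometry in µm (length in mm), flow
rate in µl/min, density kg/m^3, viscosity Pa*s, diffusivity m^2/s. All
quantities are converted to SI internally, so dimensionless outputs are
unit-consistent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import erfcinv

from .errors import InvalidArgumentError

__all__ = [
    "ChannelSpec",
    "FlowConditions",
    "mean_velocity",
    "reynolds",
    "peclet",
    "wall_shear_rate",
    "rect_resistance",
    "diffusion_width",
    "flow_report",
    "MAIN_CHANNEL",
    "WATER",
]

UM = 1e-6
MM = 1e-3
UL_PER_MIN = 1e-9 / 60.0  # m^3/s


@dataclass(frozen=True)
class ChannelSpec:
    """Rectangular channel geometry: width, height in µm; length in mm."""

    width_um: float
    height_um: float
    length_mm: float

    def __post_init__(self) -> None:
        if min(self.width_um, self.height_um, self.length_mm) <= 0:
            raise InvalidArgumentError("channel dimensions must be positive")

    @property
    def area_m2(self) -> float:
        return (self.width_um * UM) * (self.height_um * UM)

    @property
    def hydraulic_diameter_m(self) -> float:
        w, h = self.width_um * UM, self.height_um * UM
        return 4.0 * w * h / (2.0 * (w + h))


@dataclass(frozen=True)
class FlowConditions:
    """Flow rate (µl/min) and fluid/transport properties (SI)."""

    q_ul_min: float
    rho: float = 1000.0  # kg/m^3, water at room temperature
    mu: float = 1.0e-3  # Pa*s
    d: float = 2.2e-10  # m^2/s, small-solute diffusivity in water

    def __post_init__(self) -> None:
        if self.q_ul_min < 0:
            raise InvalidArgumentError("flow rate must be nonnegative")
        if min(self.rho, self.mu, self.d) <= 0:
            raise InvalidArgumentError("fluid properties must be positive")

    @property
    def q_m3_s(self) -> float:
        return self.q_ul_min * UL_PER_MIN


#: Main explant channel: 1500 µm wide, 300 µm high, 10 mm long.
MAIN_CHANNEL = ChannelSpec(width_um=1500.0, height_um=300.0, length_mm=10.0)
#: Water at room temperature with the default small-solute diffusivity.
WATER = FlowConditions(q_ul_min=30.0)


def mean_velocity(chan: ChannelSpec, flow: FlowConditions) -> float:
    """Cross-section mean velocity U = Q/(w*h), in mm/s."""
    return flow.q_m3_s / chan.area_m2 / MM


def reynolds(chan: ChannelSpec, flow: FlowConditions) -> float:
    """Re = rho*U*D_h/mu with the hydraulic diameter as length scale."""
    u = mean_velocity(chan, flow) * MM  # m/s
    return flow.rho * u * chan.hydraulic_diameter_m / flow.mu


def peclet(
    chan: ChannelSpec, flow: FlowConditions, l_char_um: float | None = None
) -> float:
    """Pe = U*L/D; characteristic length defaults to the channel width (µm)."""
    if l_char_um is None:
        l_char_um = chan.width_um
    if l_char_um <= 0:
        raise InvalidArgumentError("characteristic length must be positive")
    u = mean_velocity(chan, flow) * MM
    return u * (l_char_um * UM) / flow.d


def wall_shear_rate(chan: ChannelSpec, flow: FlowConditions) -> float:
    """Bottom-wall shear rate 6Q/(w*h^2) in s^-1 (wide-slot approximation)."""
    w, h = chan.width_um * UM, chan.height_um * UM
    return 6.0 * flow.q_m3_s / (w * h * h)


def rect_resistance(chan: ChannelSpec, flow: FlowConditions) -> float:
    """Hydraulic resistance of a rectangular duct in Pa*s/m^3.

    R = 12*mu*L / (w*h^3*(1 - 0.63 h/w)). The formula assumes h <= w; if the
    stated height exceeds the width the two are swapped (the physics does not
    care which side is called "width").
    """
    w, h = chan.width_um * UM, chan.height_um * UM
    if h > w:
        w, h = h, w
    length = chan.length_mm * MM
    return 12.0 * flow.mu * length / (w * h**3 * (1.0 - 0.63 * h / w))


def series_resistance(segments: list[tuple[ChannelSpec, FlowConditions]]) -> float:
    """Total resistance of channel segments in series (Pa*s/m^3)."""
    if not segments:
        raise InvalidArgumentError("no segments supplied")
    return sum(rect_resistance(c, f) for c, f in segments)


def diffusion_width(
    chan: ChannelSpec,
    flow: FlowConditions,
    x_downstream_mm: float,
    threshold: float = 0.1,
) -> float:
    """Full width (µm) of the diffusively blurred interface at a station x.

    From the 1D cross-stream solution C(y)/C0 = 0.5*erfc(y/(2*sqrt(D*x/U))),
    the mass fraction falls to ``threshold`` at
    y* = 2*sqrt(D*x/U)*erfcinv(2*threshold); by symmetry the full blurred
    zone (threshold to 1-threshold) spans 2*y*. Grows as sqrt(x), shrinks
    with flow rate.
    """
    if not 0.0 < threshold < 0.5:
        raise InvalidArgumentError("threshold must lie in (0, 0.5)")
    if x_downstream_mm < 0:
        raise InvalidArgumentError("downstream distance must be nonnegative")
    u = mean_velocity(chan, flow) * MM
    if u == 0:
        raise InvalidArgumentError("diffusion width undefined at zero flow")
    sigma = math.sqrt(flow.d * (x_downstream_mm * MM) / u)
    return 2.0 * sigma * float(erfcinv(2.0 * threshold)) / UM


def flow_report(
    chan: ChannelSpec, flow: FlowConditions, x_downstream_mm: float | None = None
) -> dict:
    """JSON-ready summary of the flow regime for a geometry/flow pair."""
    if x_downstream_mm is None:
        x_downstream_mm = chan.length_mm
    return {
        "U_mm_s": mean_velocity(chan, flow),
        "Re": reynolds(chan, flow),
        "Pe": peclet(chan, flow),
        "shear_s_inv": wall_shear_rate(chan, flow),
        "R_hyd_Pa_s_m3": rect_resistance(chan, flow),
        "diffusion_width_um": diffusion_width(chan, flow, x_downstream_mm),
    }
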