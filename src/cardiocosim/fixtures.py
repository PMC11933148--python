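"""Analytic verification fixtures.

The main fixture is a three-element Windkessel driven by a half-sine
inflow: its periodic pressure response has a closed form, giving an
independent oracle for the RK4 solver at the shipped substep size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

from .lpm import (
    BoundaryAttachment,
    BoundarySet,
    CirculationModel,
    ComplianceNode,
    ConstantNode,
    Resistor,
)

__all__ = ["WindkesselFixture", "make_windkessel_fixture"]


@dataclass(frozen=True)
class WindkesselFixture:
    """Single-bed open-loop model plus its closed-form periodic solution."""

    model: CirculationModel
    R: float
    C: float
    R_d: float
    T: float
    amplitude: float
    inflow: Callable[[float], float]
    node_pressure: Callable[[float], float]      # P at the compliance node
    boundary_pressure: Callable[[float], float]  # node pressure + R·Q(t)

    @property
    def periodic_initial_pressure(self) -> float:
        return self.node_pressure(0.0)


def make_windkessel_fixture(R: float, C: float, R_d: float, T: float,
                            amplitude: float) -> WindkesselFixture:
    """Three-element Windkessel (R proximal, C, R_d to ground) under a
    half-sine inflow of the given amplitude and period.

    The inflow is Q(t) = amplitude·sin(2πt/T) during the first half of each
    period and zero during the second half.  The compliance-node pressure
    obeys dP/dt = Q/C − P/(R_d·C); its unique periodic solution is assembled
    from the particular sinusoidal response plus exponentials matched for
    continuity and periodicity.
    """
    if min(R, C, R_d, T, amplitude) <= 0:
        raise ValueError("all Windkessel fixture parameters must be positive")
    a = 1.0 / (R_d * C)
    Ts = 0.5 * T
    w = math.pi / Ts  # = 2π/T
    denom = a * a + w * w
    A = amplitude

    def inflow(t: float) -> float:
        tau = math.fmod(t, T)
        return A * math.sin(w * tau) if tau < Ts else 0.0

    # particular solution during systole: (A/C)(a sin wt − w cos wt)/(a²+w²)
    K = (A / C) * w / denom
    c1 = K * (1.0 + math.exp(-a * Ts)) / (1.0 - math.exp(-2.0 * a * Ts))

    def node_pressure(t: float) -> float:
        tau = math.fmod(t, T)
        if tau < Ts:
            part = (A / C) * (a * math.sin(w * tau) - w * math.cos(w * tau)) / denom
            return c1 * math.exp(-a * tau) + part
        p_ts = c1 * math.exp(-a * Ts) + K
        return p_ts * math.exp(-a * (tau - Ts))

    def boundary_pressure(t: float) -> float:
        return node_pressure(t) + R * inflow(t)

    boundaries = BoundarySet(names=("inlet",), orientation={"inlet": +1})
    model = CirculationModel(
        chambers=(),
        nodes=[ComplianceNode("bed", C)],
        constants=[ConstantNode("ground", 0.0)],
        resistors=[Resistor("bed", "ground", R_d)],
        boundaries=boundaries,
        attachments=[BoundaryAttachment("inlet", "bed", R_prox=R)],
    )
    return WindkesselFixture(
        model=model, R=R, C=C, R_d=R_d, T=T, amplitude=A,
        inflow=inflow, node_pressure=node_pressure,
        boundary_pressure=boundary_pressure,
    )
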