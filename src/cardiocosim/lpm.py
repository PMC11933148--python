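"""Closed-loop univentricular lumped-parameter circulation (the follower).

The circulation is a 0D circuit: chambers (a time-varying-elastance single
ventricle and a passive atrium), compliance nodes, resistive and valve
links, optional inductive branches, and a set of named coupling boundaries
where an external domain injects or withdraws flow.  The model compiles its
topology into flat index lists so the right-hand side is cheap enough to be
evaluated hundreds of thousands of times per simulated run.

Units: mmHg, mL, s throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import BOUNDARIES, ORIENTATION, LPMConfig
from .errors import ConfigurationError, StructuralError

__all__ = [
    "ElastanceParams",
    "RCRBlock",
    "ValveParams",
    "BoundarySet",
    "CirculationModel",
    "elastance",
    "valve_flow",
    "lpm_rhs",
    "build_norwood_lpm",
]


# ---------------------------------------------------------------------------
# parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElastanceParams:
    """Time-varying elastance ventricle: P = E(t)·(V − V0).

    ``E(t)`` rises from ``E_min`` to ``E_max`` at ``t_peak`` and relaxes back
    by end-systole (1.5·t_peak), staying at ``E_min`` through diastole.
    """

    E_max: float  # mmHg/mL
    E_min: float  # mmHg/mL
    T: float      # s
    t_peak: float  # s
    V0: float = 0.0  # mL

    def __post_init__(self):
        if not (self.E_max >= self.E_min > 0):
            raise ConfigurationError("elastance requires E_max >= E_min > 0")
        if not (0 < self.t_peak < self.T):
            raise ConfigurationError("elastance requires 0 < t_peak < T")
        if self.V0 < 0:
            raise ConfigurationError("elastance requires V0 >= 0")


@dataclass(frozen=True)
class RCRBlock:
    """Three-element Windkessel: proximal R, compliance, distal R to P_ref."""

    R_prox: float  # mmHg·s/mL
    C: float       # mL/mmHg
    R_dist: float  # mmHg·s/mL
    P_ref: float = 0.0  # mmHg

    def __post_init__(self):
        if self.R_prox < 0 or self.R_dist <= 0 or self.C <= 0:
            raise ConfigurationError("RCR block requires R_prox >= 0, R_dist > 0, C > 0")


@dataclass(frozen=True)
class ValveParams:
    """Ideal-diode valve with optional smooth regularization of width eps."""

    R_open: float  # mmHg·s/mL
    eps: float = 0.0  # mmHg

    def __post_init__(self):
        if self.R_open <= 0:
            raise ConfigurationError("valve requires R_open > 0")
        if self.eps < 0:
            raise ConfigurationError("valve requires eps >= 0")


@dataclass(frozen=True)
class BoundarySet:
    """Ordered coupling-boundary labels with flow-orientation signs."""

    names: Tuple[str, ...] = BOUNDARIES
    orientation: Dict[str, int] = field(default_factory=lambda: dict(ORIENTATION))

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ConfigurationError("boundary labels must be unique")
        for b in self.names:
            if self.orientation.get(b) not in (+1, -1):
                raise ConfigurationError(f"boundary {b!r} needs orientation +1 or -1")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _activation(tau: float, t_peak: float, T: float) -> float:
    """Normalized double-cosine activation e(tau) in [0, 1], tau in [0, T)."""
    t_sys = min(1.5 * t_peak, T)
    if tau < t_peak:
        return 0.5 * (1.0 - math.cos(math.pi * tau / t_peak))
    if tau < t_sys:
        return 0.5 * (1.0 + math.cos(math.pi * (tau - t_peak) / (t_sys - t_peak)))
    return 0.0


def elastance(t: float, p: ElastanceParams) -> float:
    """Instantaneous ventricular elastance E(t) (mmHg/mL), T-periodic."""
    if t < 0:
        raise ConfigurationError("elastance requires t >= 0")
    tau = math.fmod(t, p.T)
    return p.E_min + (p.E_max - p.E_min) * _activation(tau, p.t_peak, p.T)


def valve_flow(dP: float, v: ValveParams) -> float:
    """Flow through a valve under pressure difference dP (mL/s).

    With ``eps == 0`` this is an ideal diode, Q = max(dP, 0)/R_open.  With
    ``eps > 0`` the corner is smoothed: Q = (dP + sqrt(dP² + eps²))/(2·R_open),
    which is positive, monotone, and within eps/R_open of the ideal diode.
    """
    if not math.isfinite(dP):
        raise StructuralError("valve_flow requires finite dP")
    if v.eps == 0.0:
        return dP / v.R_open if dP > 0.0 else 0.0
    return (dP + math.sqrt(dP * dP + v.eps * v.eps)) / (2.0 * v.R_open)


# ---------------------------------------------------------------------------
# circulation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chamber:
    name: str
    kind: str  # "elastance" | "passive"
    elastance: Optional[ElastanceParams] = None
    C: Optional[float] = None
    V0: float = 0.0


@dataclass(frozen=True)
class ComplianceNode:
    name: str
    C: float


@dataclass(frozen=True)
class ConstantNode:
    name: str
    P: float


@dataclass(frozen=True)
class Resistor:
    from_node: str
    to_node: str
    R: float


@dataclass(frozen=True)
class Valve:
    from_node: str
    to_node: str
    params: ValveParams


@dataclass(frozen=True)
class Inductor:
    from_node: str
    to_node: str
    R: float
    L: float


@dataclass(frozen=True)
class BoundaryAttachment:
    boundary: str
    node: str
    R_prox: float = 0.0


class CirculationModel:
    """A compiled lumped-parameter circulation.

    State layout: chamber volumes, then compliance-node pressures, then
    inductor flows.  The model exposes its right-hand side (``rhs``),
    exported boundary pressures, and total-volume bookkeeping.
    """

    def __init__(
        self,
        chambers: Sequence[Chamber],
        nodes: Sequence[ComplianceNode],
        constants: Sequence[ConstantNode] = (),
        resistors: Sequence[Resistor] = (),
        valves: Sequence[Valve] = (),
        inductors: Sequence[Inductor] = (),
        boundaries: BoundarySet = BoundarySet(),
        attachments: Sequence[BoundaryAttachment] = (),
    ):
        self.chambers = list(chambers)
        self.nodes = list(nodes)
        self.constants = list(constants)
        self.resistors = list(resistors)
        self.valves = list(valves)
        self.inductors = list(inductors)
        self.boundaries = boundaries
        self.attachments = list(attachments)
        self._compile()

    # -- structure ---------------------------------------------------
    def _compile(self) -> None:
        names: List[str] = []
        self._pidx: Dict[str, int] = {}
        for ch in self.chambers:
            self._pidx[ch.name] = len(self._pidx)
            names.append(f"V_{ch.name}")
        for nd in self.nodes:
            self._pidx[nd.name] = len(self._pidx)
            names.append(f"P_{nd.name}")
        self._n_dynamic = len(self._pidx)
        for cn in self.constants:
            self._pidx[cn.name] = len(self._pidx)
        if len(self._pidx) != len(self.chambers) + len(self.nodes) + len(self.constants):
            raise StructuralError("node names must be unique")
        for ind in self.inductors:
            names.append(f"Q_{ind.from_node}_{ind.to_node}")
        self.state_names = tuple(names)
        self.n_states = len(self.chambers) + len(self.nodes) + len(self.inductors)

        def pidx(name: str) -> int:
            try:
                return self._pidx[name]
            except KeyError:
                raise StructuralError(f"unknown node {name!r} in model wiring") from None

        self._res = [(pidx(r.from_node), pidx(r.to_node), 1.0 / r.R) for r in self.resistors]
        self._val = [
            (pidx(v.from_node), pidx(v.to_node), 1.0 / v.params.R_open, v.params.eps)
            for v in self.valves
        ]
        self._ind = [
            (pidx(i.from_node), pidx(i.to_node), i.R, i.L,
             len(self.chambers) + len(self.nodes) + j)
            for j, i in enumerate(self.inductors)
        ]
        att = {a.boundary: a for a in self.attachments}
        if sorted(att) != sorted(self.boundaries.names):
            raise StructuralError(
                "every boundary must be attached exactly once; "
                f"got {sorted(att)} vs {sorted(self.boundaries.names)}"
            )
        self._bnd = [
            (pidx(att[b].node), self.boundaries.orientation[b], att[b].R_prox)
            for b in self.boundaries.names
        ]
        self._nodeC = [nd.C for nd in self.nodes]
        self._constP = [cn.P for cn in self.constants]
        self._nch = len(self.chambers)
        self._nnd = len(self.nodes)
        # flattened chamber parameters for the hot path
        self._ch_el = []   # (idx, E_min, dE, T, t_peak, t_sys, V0)
        self._ch_pa = []   # (idx, 1/C, V0)
        for i, ch in enumerate(self.chambers):
            if ch.kind == "elastance":
                p = ch.elastance
                self._ch_el.append(
                    (i, p.E_min, p.E_max - p.E_min, p.T, p.t_peak,
                     min(1.5 * p.t_peak, p.T), p.V0)
                )
            else:
                self._ch_pa.append((i, 1.0 / ch.C, ch.V0))
        self.rhs_list = self._codegen_rhs()

    def _codegen_rhs(self):
        """Generate a straight-line derivative function for this topology.

        The circuit is fixed once compiled, so the per-call loops over
        links can be unrolled into generated source with all parameters
        baked in as literals.  The generated function is numerically
        identical to :meth:`rhs_reference` (same operations in the same
        order), which remains the plain-Python reference used in tests.
        """
        lines = ["def _rhs(y, t, q_in, cos=_cos, sqrt=_sqrt, pi=_pi):"]
        nd = self._n_dynamic
        P = [f"P{i}" for i in range(nd + len(self._constP))]
        for n, (i, E_min, dE, T, t_peak, t_sys, V0) in enumerate(self._ch_el):
            lines += [
                f"    tau{n} = t % {T!r}",
                f"    if tau{n} < {t_peak!r}:",
                f"        act{n} = 0.5 * (1.0 - cos(pi * tau{n} / {t_peak!r}))",
                f"    elif tau{n} < {t_sys!r}:",
                f"        act{n} = 0.5 * (1.0 + cos(pi * (tau{n} - {t_peak!r}) / {(t_sys - t_peak)!r}))",
                "    else:",
                f"        act{n} = 0.0",
                f"    P{i} = ({E_min!r} + {dE!r} * act{n}) * (y[{i}] - {V0!r})",
            ]
        for i, invC, V0 in self._ch_pa:
            lines.append(f"    P{i} = (y[{i}] - {V0!r}) * {invC!r}")
        for j in range(self._nnd):
            i = self._nch + j
            lines.append(f"    P{i} = y[{i}]")
        for j, p in enumerate(self._constP):
            lines.append(f"    P{nd + j} = {p!r}")
        net: List[List[str]] = [[] for _ in range(nd)]
        for k, (fi, ti, invR) in enumerate(self._res):
            lines.append(f"    qr{k} = (P{fi} - P{ti}) * {invR!r}")
            if fi < nd:
                net[fi].append(f"- qr{k}")
            if ti < nd:
                net[ti].append(f"+ qr{k}")
        for k, (fi, ti, invR, eps) in enumerate(self._val):
            if eps == 0.0:
                lines.append(f"    dPv{k} = P{fi} - P{ti}")
                lines.append(f"    qv{k} = dPv{k} * {invR!r} if dPv{k} > 0.0 else 0.0")
            else:
                lines.append(f"    dPv{k} = P{fi} - P{ti}")
                lines.append(
                    f"    qv{k} = (dPv{k} + sqrt(dPv{k} * dPv{k} + {eps!r} * {eps!r}))"
                    f" * 0.5 * {invR!r}"
                )
            if fi < nd:
                net[fi].append(f"- qv{k}")
            if ti < nd:
                net[ti].append(f"+ qv{k}")
        dq_exprs = []
        for k, (fi, ti, R, L, si) in enumerate(self._ind):
            lines.append(f"    qi{k} = y[{si}]")
            if fi < nd:
                net[fi].append(f"- qi{k}")
            if ti < nd:
                net[ti].append(f"+ qi{k}")
            dq_exprs.append(f"(P{fi} - P{ti} - {R!r} * qi{k}) / {L!r}")
        for k, (ni, orient, _) in enumerate(self._bnd):
            net[ni].append(("+ " if orient > 0 else "- ") + f"q_in[{k}]")
        out = []
        for i in range(self._nch):
            out.append(" ".join(net[i]).lstrip("+ ") or "0.0")
        for j in range(self._nnd):
            i = self._nch + j
            body = " ".join(net[i]).lstrip("+ ") or "0.0"
            out.append(f"({body}) / {self._nodeC[j]!r}")
        out.extend(dq_exprs)
        lines.append("    return [" + ", ".join(out) + "]")
        ns = {"_cos": math.cos, "_sqrt": math.sqrt, "_pi": math.pi}
        exec("\n".join(lines), ns)
        return ns["_rhs"]

    @property
    def n_boundaries(self) -> int:
        return len(self.boundaries)

    def variable_names(self) -> Dict[str, int]:
        """Map from state-variable name to its index in the state vector."""
        return {n: i for i, n in enumerate(self.state_names)}

    # -- pressures ---------------------------------------------------
    def _pressures(self, y: Sequence[float], t: float) -> List[float]:
        P = [0.0] * (self._n_dynamic + len(self.constants))
        for i, ch in enumerate(self.chambers):
            if ch.kind == "elastance":
                P[i] = elastance(t, ch.elastance) * (y[i] - ch.elastance.V0)
            else:
                P[i] = (y[i] - ch.V0) / ch.C
        base = self._nch
        for j in range(self._nnd):
            P[base + j] = y[base + j]
        cbase = self._n_dynamic
        for j, p in enumerate(self._constP):
            P[cbase + j] = p
        return P

    # -- dynamics ----------------------------------------------------
    def rhs_reference(self, y: Sequence[float], t: float, q_in: Sequence[float]) -> List[float]:
        """Right-hand side evaluated by explicit loops over the topology.

        ``q_in`` holds one exchanged flow per boundary, in the exchange
        convention; the boundary orientation is applied internally.  The
        compiled ``rhs_list`` attribute is the generated equivalent used in
        production; this method is the readable reference it is checked
        against.
        """
        nd = self._n_dynamic
        P = [0.0] * (nd + len(self._constP))
        cos = math.cos
        pi = math.pi
        for i, E_min, dE, T, t_peak, t_sys, V0 in self._ch_el:
            tau = t % T
            if tau < t_peak:
                act = 0.5 * (1.0 - cos(pi * tau / t_peak))
            elif tau < t_sys:
                act = 0.5 * (1.0 + cos(pi * (tau - t_peak) / (t_sys - t_peak)))
            else:
                act = 0.0
            P[i] = (E_min + dE * act) * (y[i] - V0)
        for i, invC, V0 in self._ch_pa:
            P[i] = (y[i] - V0) * invC
        base = self._nch
        for j in range(self._nnd):
            P[base + j] = y[base + j]
        cbase = nd
        for j, p in enumerate(self._constP):
            P[cbase + j] = p
        net = [0.0] * nd
        for fi, ti, invR in self._res:
            q = (P[fi] - P[ti]) * invR
            if fi < nd:
                net[fi] -= q
            if ti < nd:
                net[ti] += q
        for fi, ti, invR, eps in self._val:
            dP = P[fi] - P[ti]
            if eps == 0.0:
                q = dP * invR if dP > 0.0 else 0.0
            else:
                q = (dP + math.sqrt(dP * dP + eps * eps)) * 0.5 * invR
            if fi < nd:
                net[fi] -= q
            if ti < nd:
                net[ti] += q
        dq: List[float] = []
        for fi, ti, R, L, si in self._ind:
            q = y[si]
            if fi < nd:
                net[fi] -= q
            if ti < nd:
                net[ti] += q
            dq.append((P[fi] - P[ti] - R * q) / L)
        for (ni, orient, _), q in zip(self._bnd, q_in):
            net[ni] += orient * q
        out = net  # reuse: chambers keep dV/dt = net flow
        base = self._nch
        for j in range(self._nnd):
            out[base + j] = net[base + j] / self._nodeC[j]
        out.extend(dq)
        return out

    def rhs(self, y: np.ndarray, t: float, q_in: Sequence[float]) -> np.ndarray:
        if len(y) != self.n_states:
            raise StructuralError(
                f"state has {len(y)} entries, model expects {self.n_states}"
            )
        if len(q_in) != self.n_boundaries:
            raise StructuralError(
                f"q_in has {len(q_in)} entries, model expects {self.n_boundaries}"
            )
        return np.asarray(self.rhs_list([float(v) for v in y], t, q_in))

    def boundary_pressures(self, y: Sequence[float], t: float, q_in: Sequence[float]) -> List[float]:
        """Pressure exported at each boundary (mmHg), in boundary order.

        The proximal (characteristic) resistance of the attached bed shifts
        the interface pressure away from the node pressure by R_prox times
        the entering flow.
        """
        P = self._pressures(y, t)
        return [
            P[ni] + rp * orient * q
            for (ni, orient, rp), q in zip(self._bnd, q_in)
        ]

    # -- bookkeeping -------------------------------------------------
    def total_volume(self, y: Sequence[float]) -> float:
        """Blood volume held in chambers plus compliance-stored volume (mL).

        Stored volume at a compliance node is C·P relative to zero pressure;
        only differences matter for conservation checks.
        """
        v = sum(float(y[i]) for i in range(self._nch))
        base = self._nch
        for j, C in enumerate(self._nodeC):
            v += C * float(y[base + j])
        return v


def lpm_rhs(s: np.ndarray, q_in: Sequence[float], t: float, m: CirculationModel) -> np.ndarray:
    """Derivative of the circulation state (chambers' dV/dt, nodes' dP/dt,
    inductors' dQ/dt) under exchanged boundary flows ``q_in``."""
    return m.rhs(np.asarray(s, dtype=float), t, q_in)


# ---------------------------------------------------------------------------
# the Norwood (stage-1, MBTS) follower
# ---------------------------------------------------------------------------

def build_norwood_lpm(cfg: LPMConfig) -> CirculationModel:
    """Assemble the closed-loop Norwood circulation from its configuration.

    Topology: elastance single ventricle -> aortic valve -> aortic-root node
    (aortic_root boundary, flow drawn by the leader); five return boundaries
    feed Windkessel beds (three upper-body, one descending-aorta, two
    pulmonary); systemic beds drain to a systemic venous node and pulmonary
    beds to a pulmonary venous node, both returning to the common atrium,
    which fills the ventricle through the AV valve.
    """
    h = cfg.heart
    ep = ElastanceParams(E_max=h.E_max, E_min=h.E_min, T=h.T, t_peak=h.t_peak, V0=h.V0)
    chambers = [
        Chamber("sv", "elastance", elastance=ep),
        Chamber("atrium", "passive", C=cfg.atrium.C, V0=cfg.atrium.V0),
    ]
    nodes = [ComplianceNode("aortic_root", cfg.aortic_root_C)]
    resistors: List[Resistor] = []
    attachments = [BoundaryAttachment("aortic_root", "aortic_root", R_prox=0.0)]
    for b in BOUNDARIES[1:]:
        bed = cfg.beds[b]
        nodes.append(ComplianceNode(b, bed.C))
        venous = "venous_pulmonary" if b in ("lpa", "rpa") else "venous_systemic"
        resistors.append(Resistor(b, venous, bed.R_dist))
        attachments.append(BoundaryAttachment(b, b, R_prox=bed.R_prox))
    nodes.append(ComplianceNode("venous_systemic", cfg.venous_systemic.C))
    nodes.append(ComplianceNode("venous_pulmonary", cfg.venous_pulmonary.C))
    resistors.append(Resistor("venous_systemic", "atrium", cfg.venous_systemic.R_return))
    resistors.append(Resistor("venous_pulmonary", "atrium", cfg.venous_pulmonary.R_return))
    valves = [
        Valve("atrium", "sv", ValveParams(cfg.av_valve.R_open, cfg.av_valve.eps)),
        Valve("sv", "aortic_root", ValveParams(cfg.aortic_valve.R_open, cfg.aortic_valve.eps)),
    ]
    return CirculationModel(
        chambers=chambers,
        nodes=nodes,
        resistors=resistors,
        valves=valves,
        boundaries=BoundarySet(),
        attachments=attachments,
    )


def initial_state(model: CirculationModel, cfg: LPMConfig) -> np.ndarray:
    """Initial state vector from the config's initial-condition block."""
    ini = cfg.initial
    values = {
        "V_sv": ini.V_sv,
        "V_atrium": ini.V_a,
        "P_aortic_root": ini.P_aortic_root,
        "P_innominate": ini.P_innominate,
        "P_l_carotid": ini.P_l_carotid,
        "P_l_subclavian": ini.P_l_subclavian,
        "P_dao": ini.P_dao,
        "P_lpa": ini.P_lpa,
        "P_rpa": ini.P_rpa,
        "P_venous_systemic": ini.P_venous_systemic,
        "P_venous_pulmonary": ini.P_venous_pulmonary,
    }
    try:
        return np.array([values[n] for n in model.state_names], dtype=float)
    except KeyError as exc:
        raise StructuralError(f"no initial value for state {exc.args[0]!r}") from None
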