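"""Coupling driver: the leader/follower advancement scheme.

Each macro step the leader advances its network under the last exported
follower pressures, passes the resulting boundary flows to the follower,
commands the follower's do-step (internally subdivided to ≤ h_max), and
reads back the refreshed boundary pressures — an explicit staggered
(Gauss–Seidel) exchange, leader first.  An optional inner repetition of the
exchange within the macro step is available for a tighter coupling.

``run_monolithic_oracle`` integrates leader and follower merged into one
ODE system with a single RK4 at the follower's substep size; it carries no
co-simulation splitting and serves as the verification reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import BOUNDARIES, RunConfig
from .cosim import CosimSlave, StepStatus
from .errors import NumericalError
from .leader import INTERNAL_NODES, LeaderNetwork, LeaderState, adapt_timestep
from .metrics import WaveformSeries, cycle_average, qp_qs
from .solver import SubdivisionPolicy

log = logging.getLogger(__name__)

__all__ = ["BoundaryExchange", "SimulationResult", "run_coupled", "run_monolithic_oracle"]


@dataclass(frozen=True)
class BoundaryExchange:
    """One accepted macro step's exchanged data (flows leader→follower,
    pressures follower→leader) plus solver diagnostics."""

    t: float
    dt: float
    Q: Tuple[float, ...]  # mL/s, anatomical branch direction, boundary order
    P: Tuple[float, ...]  # mmHg, follower boundary pressures, boundary order
    n_substeps: int
    h_substep: float
    residual: float
    iterations: int
    error_est: float


@dataclass
class SimulationResult:
    waveforms: Dict[str, WaveformSeries]
    exchanges: List[BoundaryExchange]
    cycles_completed: int
    final_cycle_window: Tuple[float, float]
    volume_start: float
    volume_end: float
    config: RunConfig

    @property
    def volume_drift_percent(self) -> float:
        return 100.0 * abs(self.volume_end - self.volume_start) / self.volume_start

    def final_cycle_averages(self) -> Dict[str, float]:
        """Cycle-averaged hemodynamics over the final cardiac cycle."""
        win = self.final_cycle_window
        mean = lambda name: cycle_average(self.waveforms[name], win)
        q_ub = (mean("Q_innominate") + mean("Q_l_carotid") + mean("Q_l_subclavian"))
        q_dao = mean("Q_dao")
        q_sh = mean("Q_shunt")
        return {
            "CO": mean("Q_aortic_root"),
            "Q_UB": q_ub,
            "Q_DAO": q_dao,
            "Q_SH": q_sh,
            "Qp_Qs": qp_qs(q_sh, q_ub, q_dao),
            "P_AO": mean("P_aortic_root"),
            "P_PUL": mean("P_pulmonary"),
        }

    def dt_statistics(self) -> Dict[str, float]:
        if not self.exchanges:
            return {}
        dts = np.array([e.dt for e in self.exchanges])
        return {
            "dt_min": float(dts.min()),
            "dt_max": float(dts.max()),
            "dt_mean": float(dts.mean()),
            "n_steps": int(dts.size),
            "max_substep": float(max(e.h_substep for e in self.exchanges)),
            "max_iterations": int(max(e.iterations for e in self.exchanges)),
        }


class _Recorder:
    """Accumulates per-macro-step samples into waveform arrays."""

    def __init__(self, monitors: List[str]):
        self.names = (
            [f"P_{b}" for b in BOUNDARIES]
            + [f"Q_{b}" for b in BOUNDARIES]
            + list(monitors)
        )
        self.t: List[float] = []
        self.data: Dict[str, List[float]] = {n: [] for n in self.names}

    def sample(self, t: float, values: Dict[str, float]) -> None:
        self.t.append(t)
        for n in self.names:
            self.data[n].append(values[n])

    def waveforms(self, T: float, n_cycles: int) -> Dict[str, WaveformSeries]:
        t = np.array(self.t)
        cyc = np.minimum(np.floor(t / T + 1e-9).astype(int), n_cycles - 1)
        units = {}
        for n in self.names:
            units[n] = "mmHg" if n.startswith("P_") else ("mL" if n.startswith("V_") else "mL/s")
        return {
            n: WaveformSeries(t, np.array(self.data[n]), unit=units[n], cycle_index=cyc)
            for n in self.names
        }


def _leader_monitor_values(net: LeaderNetwork, st: LeaderState) -> Dict[str, float]:
    pj = dict(zip(INTERNAL_NODES, st.P_junction))
    return {
        "Q_shunt": st.Q[net.branch_index["shunt"]],
        "P_pulmonary": pj["pulm_j"],
        "P_arch": pj["arch"],
    }


def _collect(slave: CosimSlave, net: LeaderNetwork, lst: LeaderState,
             q_enter: Dict[str, float], monitors: List[str]) -> Dict[str, float]:
    vals: Dict[str, float] = {}
    for b, p in zip(BOUNDARIES, slave.boundary_pressure_vector()):
        vals[f"P_{b}"] = p
    for b in BOUNDARIES:
        # exchanged flows are already in the anatomical branch direction
        vals[f"Q_{b}"] = q_enter[b]
    lead = _leader_monitor_values(net, lst)
    for m in monitors:
        vals[m] = lead[m] if m in lead else slave.get(m)
    return vals


def run_coupled(cfg: RunConfig) -> SimulationResult:
    """Run the coupled leader/follower simulation over cfg.coupling.n_cycles
    cardiac cycles and record all exchanged data."""
    T = cfg.period
    n_cycles = cfg.coupling.n_cycles
    t_end = n_cycles * T
    slave = CosimSlave(cfg.lpm)
    net = LeaderNetwork(cfg.leader)
    foh = cfg.coupling.input_hold == "first"

    P_bound = slave.boundary_pressure_vector()
    lst = net.steady_state(P_bound)
    q_enter = net.boundary_flows(lst)
    for b in BOUNDARIES:
        slave.set(f"Q_{b}", q_enter[b])
    slave._refresh_outputs()
    P_bound = slave.boundary_pressure_vector()

    rec = _Recorder(cfg.monitors)
    rec.sample(0.0, _collect(slave, net, lst, q_enter, cfg.monitors))
    vol0 = slave.model.total_volume(slave.state)

    exchanges: List[BoundaryExchange] = []
    t = 0.0
    dt = max(net.dt_min, min(net.dt_max, 10.0 * net.dt_min))
    next_cycle_log = 1
    while t < t_end - 1e-12:
        dt_step = min(dt, t_end - t)
        prev_Q = q_enter
        prev_state = (slave.state.copy(), slave.clock)
        for inner in range(cfg.coupling.exchange_iterations):
            if inner > 0:
                slave.state, slave.clock = prev_state[0].copy(), prev_state[1]
            new_lst, flows, residual, iters = net.step(lst, P_bound, dt_step)
            # local-error estimate: implicit update vs explicit predictor
            rate = net.explicit_rate(list(lst.Q), P_bound, list(lst.P_junction))
            q_pred = [q + dt_step * r for q, r in zip(lst.Q, rate)]
            scale = max(1.0, max(abs(q) for q in new_lst.Q))
            error_est = max(abs(qn - qp) for qn, qp in zip(new_lst.Q, q_pred)) / scale
            if foh:
                q_end = [flows[b] for b in BOUNDARIES]
                status = slave.do_step(t, dt_step, inputs_end=q_end)
            else:
                slave.set_boundary_flows([flows[b] for b in BOUNDARIES])
                status = slave.do_step(t, dt_step)
            if status is not StepStatus.OK:
                raise NumericalError(
                    f"follower failed at t={t:.6f}, dt={dt_step:.3e}: {slave.last_error}"
                )
            P_new = slave.boundary_pressure_vector()
            if not all(math.isfinite(p) for p in P_new):
                raise NumericalError(f"non-finite boundary pressure at t={t:.6f}")
            P_bound = P_new
        lst = new_lst
        q_enter = flows
        t += dt_step
        n_sub, h_sub = slave.last_substeps
        exchanges.append(BoundaryExchange(
            t=t, dt=dt_step,
            Q=tuple(flows[b] for b in BOUNDARIES),
            P=tuple(P_bound),
            n_substeps=n_sub, h_substep=h_sub,
            residual=residual, iterations=iters, error_est=error_est,
        ))
        rec.sample(t, _collect(slave, net, lst, q_enter, cfg.monitors))
        dt = adapt_timestep(dt, error_est, cfg.leader.error_tol,
                            dt_min=net.dt_min, dt_max=net.dt_max)
        if t >= next_cycle_log * T - 1e-9 and log.isEnabledFor(logging.INFO):
            _log_cycle(rec, T, next_cycle_log, exchanges)
            next_cycle_log += 1

    result = SimulationResult(
        waveforms=rec.waveforms(T, n_cycles),
        exchanges=exchanges,
        cycles_completed=n_cycles,
        final_cycle_window=((n_cycles - 1) * T, n_cycles * T),
        volume_start=vol0,
        volume_end=slave.model.total_volume(slave.state),
        config=cfg,
    )
    return result


def _log_cycle(rec: _Recorder, T: float, cycle: int, exchanges: List[BoundaryExchange]) -> None:
    t0, t1 = (cycle - 1) * T, cycle * T
    try:
        w = WaveformSeries(np.array(rec.t), np.array(rec.data["Q_aortic_root"]))
        co = cycle_average(w, (t0, t1))
        dts = [e.dt for e in exchanges if t0 < e.t <= t1]
        log.info(
            "cycle %d: mean CO %.2f mL/s, macro steps %d, dt %.1f-%.1f us",
            cycle, co, len(dts), 1e6 * min(dts), 1e6 * max(dts),
        )
    except Exception:  # logging must never kill the run
        pass


def run_monolithic_oracle(cfg: RunConfig, sample_interval: float = 1e-3) -> SimulationResult:
    """Integrate follower + leader as one ODE system (no co-simulation split).

    The leader's junction pressures are algebraic (index-1 constraint:
    net junction flow stays zero) and are eliminated inside the right-hand
    side; the whole system is advanced by the same classical RK4 at the
    follower's substep size.
    """
    T = cfg.period
    n_cycles = cfg.coupling.n_cycles
    t_end = n_cycles * T
    slave = CosimSlave(cfg.lpm)  # reuse model construction + monitors
    model = slave.model
    net = LeaderNetwork(cfg.leader)

    P_bound0 = slave.boundary_pressure_vector()
    lst0 = net.steady_state(P_bound0)
    nyl = model.n_states
    nbr = len(net.branches)
    inv_L = [1.0 / br.L for br in net.branches]

    from .leader import BOUNDARY_BRANCH

    def q_enter_of(Q: List[float]) -> List[float]:
        return [Q[net.branch_index[BOUNDARY_BRANCH[b]]] for b in BOUNDARIES]

    def junction_pressures(Q: List[float], Pb: List[float]) -> List[float]:
        w = inv_L
        c = []
        for i, br in enumerate(net.branches):
            cf = -br.R * Q[i] - br.k * Q[i] * abs(Q[i])
            f, tno = net._from[i], net._to[i]
            if f < net._n_bound:
                cf += Pb[f]
            if tno < net._n_bound:
                cf -= Pb[tno]
            c.append(cf)
        return net._solve_junctions(w, c)

    def rhs(y: List[float], t: float) -> List[float]:
        yl = y[:nyl]
        Q = y[nyl:]
        q_in = q_enter_of(Q)
        Pb = model.boundary_pressures(yl, t, q_in)
        Pj = junction_pressures(Q, Pb)
        dy = model.rhs_list(yl, t, q_in)
        dy.extend(net.explicit_rate(Q, Pb, Pj))
        return dy

    pol = SubdivisionPolicy(h_max=cfg.lpm.h_max_us * 1e-6)
    n_total, h = pol.substeps(t_end)
    every = max(1, round(sample_interval / h))

    y = list(slave.state) + list(lst0.Q)
    vol0 = model.total_volume(y[:nyl])
    rec = _Recorder(cfg.monitors)

    def sample(t: float, y: List[float]) -> None:
        yl, Q = y[:nyl], y[nyl:]
        q_in = q_enter_of(Q)
        Pb = model.boundary_pressures(yl, t, q_in)
        Pj = junction_pressures(Q, Pb)
        slave.state = np.asarray(yl)
        slave.clock = t
        for b, qv in zip(BOUNDARIES, q_in):
            slave._values[slave._by_name[f"Q_{b}"].value_reference] = qv
        slave._refresh_outputs()
        lst = LeaderState(Q=tuple(Q), P_junction=tuple(Pj), t=t, dt=h)
        vals = _collect(slave, net, lst, dict(zip(BOUNDARIES, q_in)), cfg.monitors)
        rec.sample(t, vals)

    sample(0.0, y)
    m = nyl + nbr
    half = 0.5 * h
    sixth = h / 6.0
    for i in range(n_total):
        t = i * h
        k1 = rhs(y, t)
        y2 = [y[j] + half * k1[j] for j in range(m)]
        k2 = rhs(y2, t + half)
        y3 = [y[j] + half * k2[j] for j in range(m)]
        k3 = rhs(y3, t + half)
        y4 = [y[j] + h * k3[j] for j in range(m)]
        k4 = rhs(y4, t + h)
        y = [y[j] + sixth * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) for j in range(m)]
        if (i + 1) % every == 0 or i == n_total - 1:
            tn = (i + 1) * h if i < n_total - 1 else t_end
            if not all(math.isfinite(v) for v in y):
                raise NumericalError(f"non-finite state at t={tn:.6f} in monolithic run")
            sample(tn, y)

    return SimulationResult(
        waveforms=rec.waveforms(T, n_cycles),
        exchanges=[],
        cycles_completed=n_cycles,
        final_cycle_window=((n_cycles - 1) * T, n_cycles * T),
        volume_start=vol0,
        volume_end=model.total_volume(y[:nyl]),
        config=cfg,
    )
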