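"""0D surrogate of the 3D arch/shunt domain (the leader subsystem).

The region the imaging-based CFD model would occupy — aortic arch, arch
branches, descending aorta take-off, MBTS shunt and proximal pulmonary
arteries — is represented as a network of inertial branches with linear and
quadratic pressure losses, joined at rigid internal junctions.  The leader
receives boundary pressures from the follower, advances its branch flows
over an adaptive macro step (backward Euler with a fixed-point junction
solve), and returns the boundary flows.  A real 3D solver could replace
this module behind the same pressure-in/flow-out contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .config import BOUNDARIES, LEADER_BRANCHES, LeaderConfig
from .errors import ConfigurationError, ConvergenceError, StructuralError

__all__ = [
    "BranchElement",
    "LeaderState",
    "LeaderNetwork",
    "steady_flow_solve",
    "adapt_timestep",
]

INTERNAL_NODES: Tuple[str, ...] = ("arch", "inn_j", "pulm_j")

#: branch name -> (from node, to node); boundary names double as node names.
TOPOLOGY: Dict[str, Tuple[str, str]] = {
    "aortic_root": ("aortic_root", "arch"),
    "brachiocephalic": ("arch", "inn_j"),
    "innominate": ("inn_j", "innominate"),
    "l_carotid": ("arch", "l_carotid"),
    "l_subclavian": ("arch", "l_subclavian"),
    "dao": ("arch", "dao"),
    "shunt": ("inn_j", "pulm_j"),
    "lpa": ("pulm_j", "lpa"),
    "rpa": ("pulm_j", "rpa"),
}

#: branch whose flow is exchanged at each boundary.  Exchanged flows are in
#: the anatomical branch direction (ejection into the arch positive at the
#: aortic root, delivery toward the boundary positive elsewhere); the
#: follower's BoundarySet orientation converts them to entering flows.
BOUNDARY_BRANCH: Dict[str, str] = {
    "aortic_root": "aortic_root",
    "innominate": "innominate",
    "l_carotid": "l_carotid",
    "l_subclavian": "l_subclavian",
    "dao": "dao",
    "lpa": "lpa",
    "rpa": "rpa",
}


@dataclass(frozen=True)
class BranchElement:
    """Inertial branch with linear (R) and quadratic (k) pressure loss."""

    R: float  # mmHg·s/mL
    L: float  # mmHg·s²/mL
    k: float = 0.0  # mmHg·s²/mL²
    from_node: str = ""
    to_node: str = ""

    def __post_init__(self):
        if self.R < 0 or self.k < 0 or self.L <= 0:
            raise ConfigurationError("branch requires R >= 0, k >= 0, L > 0")


@dataclass(frozen=True)
class LeaderState:
    """Branch flows, junction pressures and current adaptive macro step."""

    Q: Tuple[float, ...]        # mL/s, one per branch in LEADER_BRANCHES order
    P_junction: Tuple[float, ...]  # mmHg, one per INTERNAL_NODES
    t: float = 0.0
    dt: float = 1e-4


def steady_flow_solve(branch: BranchElement, dP: float) -> float:
    """Unique steady flow through a branch: R·Q + k·Q·|Q| = dP.

    Sign of Q follows the sign of dP; with k = 0 this is Ohm's law.
    """
    if branch.R == 0.0 and branch.k == 0.0:
        raise StructuralError("degenerate branch: R = k = 0 has no steady solution")
    if dP == 0.0:
        return 0.0
    mag = abs(dP)
    if branch.k == 0.0:
        q = mag / branch.R
    else:
        # rationalised quadratic root: stable as k -> 0 (no cancellation)
        q = 2.0 * mag / (branch.R + math.sqrt(branch.R * branch.R + 4.0 * branch.k * mag))
    return math.copysign(q, dP)


def adapt_timestep(
    dt: float,
    error_est: float,
    tol: float,
    dt_min: float = 1e-5,
    dt_max: float = 2e-3,
    safety: float = 0.9,
) -> float:
    """Clamped proportional step controller.

    Shrinks (by at most a factor 2) when the local error estimate exceeds
    ``tol``; grows (by at most a factor 2) when it is below ``tol``/4; the
    dead band in between leaves the step unchanged.  The result is clamped
    to [dt_min, dt_max].
    """
    if error_est > tol:
        factor = max(0.5, safety * math.sqrt(tol / error_est))
    elif error_est < 0.25 * tol:
        if error_est <= 0.0:
            factor = 2.0
        else:
            factor = min(2.0, safety * math.sqrt(tol / error_est))
    else:
        factor = 1.0
    return min(dt_max, max(dt_min, dt * factor))


class LeaderNetwork:
    """Compiled branch network with a backward-Euler fixed-point stepper."""

    def __init__(self, cfg: LeaderConfig):
        self.cfg = cfg
        self.branches: List[BranchElement] = []
        node_ids = {b: i for i, b in enumerate(BOUNDARIES)}
        for j, n in enumerate(INTERNAL_NODES):
            node_ids[n] = len(BOUNDARIES) + j
        self._n_bound = len(BOUNDARIES)
        self._from: List[int] = []
        self._to: List[int] = []
        for name in LEADER_BRANCHES:
            p = cfg.branches[name]
            f, t = TOPOLOGY[name]
            self.branches.append(BranchElement(R=p.R, L=p.L, k=p.k, from_node=f, to_node=t))
            self._from.append(node_ids[f])
            self._to.append(node_ids[t])
        self.branch_index = {name: i for i, name in enumerate(LEADER_BRANCHES)}
        # incidence of branches on internal junctions: +1 into, -1 out of
        self._inc: List[List[Tuple[int, float]]] = [[] for _ in INTERNAL_NODES]
        for i in range(len(self.branches)):
            f, t = self._from[i], self._to[i]
            if f >= self._n_bound:
                self._inc[f - self._n_bound].append((i, -1.0))
            if t >= self._n_bound:
                self._inc[t - self._n_bound].append((i, +1.0))
        self.dt_min = cfg.dt_min_us * 1e-6
        self.dt_max = cfg.dt_max_us * 1e-6

    # ------------------------------------------------------------------
    def _node_pressures(self, P_bound: Sequence[float], Pj: Sequence[float]) -> List[float]:
        return list(P_bound) + list(Pj)

    def _solve_junctions(self, w: Sequence[float], c: Sequence[float]) -> List[float]:
        """Junction pressures making net junction flow zero.

        Branch flows are affine in the junction pressures,
        Q_i = w_i·(c_i + P_from − P_to); the three junction balances give a
        small linear system, solved in place by Gaussian elimination with
        partial pivoting (cheaper than a LAPACK call at this size).
        """
        nj = len(INTERNAL_NODES)
        A = [[0.0] * (nj + 1) for _ in range(nj)]
        nb = self._n_bound
        for j in range(nj):
            row = A[j]
            for i, s in self._inc[j]:
                f, t = self._from[i], self._to[i]
                sw = s * w[i]
                row[nj] -= sw * c[i]
                if f >= nb:
                    row[f - nb] += sw
                if t >= nb:
                    row[t - nb] -= sw
        # Gaussian elimination, partial pivoting
        for col in range(nj):
            piv = max(range(col, nj), key=lambda r: abs(A[r][col]))
            if piv != col:
                A[col], A[piv] = A[piv], A[col]
            prow = A[col]
            inv = 1.0 / prow[col]
            for r in range(col + 1, nj):
                fac = A[r][col] * inv
                if fac != 0.0:
                    rr = A[r]
                    for cc in range(col, nj + 1):
                        rr[cc] -= fac * prow[cc]
        x = [0.0] * nj
        for r in range(nj - 1, -1, -1):
            acc = A[r][nj]
            for cc in range(r + 1, nj):
                acc -= A[r][cc] * x[cc]
            x[r] = acc / A[r][r]
        return x

    def step(
        self,
        st: LeaderState,
        P_bound: Sequence[float],
        dt: float,
        tol: float | None = None,
        max_iter: int | None = None,
    ) -> Tuple[LeaderState, Dict[str, float], float, int]:
        """Advance branch flows over ``dt`` under fixed boundary pressures.

        Backward-Euler in each branch; the quadratic loss is handled by
        Newton relinearisation (k·Q·|Q| ≈ k·|Q₀|·(2Q − Q₀)) and junction
        pressures are re-solved each sweep so that net junction flow
        vanishes.  Returns the new state, the exchanged flow per boundary,
        the final relative junction residual, and the iteration count.
        """
        if dt <= 0:
            raise StructuralError("leader step requires dt > 0")
        if len(P_bound) != self._n_bound:
            raise StructuralError("one boundary pressure required per boundary")
        tol = self.cfg.residual_tol if tol is None else tol
        max_iter = self.cfg.max_iterations if max_iter is None else max_iter
        nb = len(self.branches)
        Q = list(st.Q)
        Pj = list(st.P_junction)
        inv_dt = 1.0 / dt
        base = [self.branches[i].L * inv_dt * st.Q[i] for i in range(nb)]
        w = [0.0] * nb
        c = [0.0] * nb
        cb = [0.0] * nb
        for i in range(nb):
            cf = base[i]
            f, t = self._from[i], self._to[i]
            if f < self._n_bound:
                cf += P_bound[f]
            if t < self._n_bound:
                cf -= P_bound[t]
            cb[i] = cf
        branches = self.branches
        residual = math.inf
        it = 0
        for it in range(1, max_iter + 1):
            for i in range(nb):
                br = branches[i]
                q0 = Q[i]
                aq = q0 if q0 >= 0.0 else -q0
                w[i] = 1.0 / (br.L * inv_dt + br.R + 2.0 * br.k * aq)
                c[i] = cb[i] + br.k * aq * q0
            Pj = self._solve_junctions(w, c)
            dPj = [0.0] * nb
            for i in range(nb):
                f, t = self._from[i], self._to[i]
                if f >= self._n_bound:
                    dPj[i] += Pj[f - self._n_bound]
                if t >= self._n_bound:
                    dPj[i] -= Pj[t - self._n_bound]
            Q = [w[i] * (c[i] + dPj[i]) for i in range(nb)]
            # the solve enforces junction balance exactly for the current
            # linearisation; convergence is judged by re-evaluating the
            # balance with the quadratic loss refreshed at the new flows
            chk = [
                (cb[i] + dPj[i])
                / (branches[i].L * inv_dt + branches[i].R
                   + branches[i].k * abs(Q[i]))
                for i in range(nb)
            ]
            residual = self._junction_residual(chk)
            if residual < tol:
                break
        if residual >= tol:
            raise ConvergenceError(
                f"leader junction solve stalled at residual {residual:.3e} "
                f"after {it} iterations (tol {tol:.1e})",
                residual=residual,
            )
        flows = {b: Q[self.branch_index[name]] for b, name in BOUNDARY_BRANCH.items()}
        new_state = LeaderState(Q=tuple(Q), P_junction=tuple(Pj), t=st.t + dt, dt=dt)
        return new_state, flows, residual, it

    def _junction_residual(self, Q: Sequence[float]) -> float:
        """Max net junction flow, relative to the mean branch-flow scale.

        The 1e-6 mL/s floor keeps the measure meaningful in quiescent
        states where the absolute roundoff of the junction solve dominates.
        """
        scale = sum(abs(q) for q in Q) / len(Q) + 1e-6
        worst = 0.0
        for j in range(len(INTERNAL_NODES)):
            net = sum(s * Q[i] for i, s in self._inc[j])
            worst = max(worst, abs(net))
        return worst / scale

    def explicit_rate(self, Q: Sequence[float], P_bound: Sequence[float],
                      Pj: Sequence[float]) -> List[float]:
        """dQ/dt of every branch at the given flows and pressures."""
        P = self._node_pressures(P_bound, Pj)
        out = []
        for i, br in enumerate(self.branches):
            dP = P[self._from[i]] - P[self._to[i]]
            out.append((dP - br.R * Q[i] - br.k * Q[i] * abs(Q[i])) / br.L)
        return out

    def steady_state(self, P_bound: Sequence[float]) -> LeaderState:
        """Steady flows/junction pressures consistent with boundary pressures.

        Computed with the same fixed-point machinery in the dt → ∞ limit so
        that initialization and stepping share one solve path.
        """
        st = LeaderState(Q=(0.0,) * len(self.branches),
                         P_junction=(float(np.mean(P_bound)),) * len(INTERNAL_NODES))
        huge = 1e9
        new, _, _, _ = self.step(st, P_bound, huge, tol=1e-7, max_iter=500)
        return LeaderState(Q=new.Q, P_junction=new.P_junction, t=0.0, dt=self.dt_min)

    def boundary_flows(self, st: LeaderState) -> Dict[str, float]:
        return {b: st.Q[self.branch_index[name]] for b, name in BOUNDARY_BRANCH.items()}

    def kinetic_energy(self, st: LeaderState) -> float:
        """Inertial energy-like quantity Σ L·Q²/2 (mmHg·mL)."""
        return sum(0.5 * br.L * q * q for br, q in zip(self.branches, st.Q))
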