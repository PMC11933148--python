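"""Fixed-step RK4 integration with macro-step subdivision.

The follower advances over each communication (macro) step commanded by the
leader; internally the macro step is tiled into equal RK4 substeps no longer
than ``h_max`` (default 100 µs), with boundary inputs held across the step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .errors import NumericalError, StructuralError


@dataclass(frozen=True)
class SubdivisionPolicy:
    """Equal-substep tiling of a macro step: n = ceil(Δt/h_max), h = Δt/n."""

    h_max: float = 1e-4  # s

    def __post_init__(self):
        if self.h_max <= 0:
            raise StructuralError("h_max must be positive")

    def substeps(self, dt: float) -> Tuple[int, float]:
        """Number and size of substeps tiling ``dt`` exactly.

        The ceiling is taken with a relative guard so that a macro step that
        is an exact multiple of ``h_max`` up to roundoff does not gain a
        spurious extra substep.
        """
        if dt <= 0:
            raise StructuralError("macro step must be positive")
        n = max(1, math.ceil((dt / self.h_max) * (1.0 - 1e-12)))
        return n, dt / n


RHS = Callable[[np.ndarray, float], np.ndarray]


def rk4_step(rhs: RHS, s: np.ndarray, t: float, h: float) -> np.ndarray:
    """One classical fourth-order Runge–Kutta update of size ``h``."""
    if h <= 0:
        raise StructuralError("step size must be positive")
    k1 = np.asarray(rhs(s, t))
    k2 = np.asarray(rhs(s + (0.5 * h) * k1, t + 0.5 * h))
    k3 = np.asarray(rhs(s + (0.5 * h) * k2, t + 0.5 * h))
    k4 = np.asarray(rhs(s + h * k3, t + h))
    out = s + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(out)):
        bad = int(np.argmax(~np.isfinite(out)))
        raise NumericalError(f"non-finite value in state component {bad} at t={t}")
    return out


def integrate_macro_step(
    rhs,
    s: np.ndarray,
    t: float,
    dt: float,
    pol: SubdivisionPolicy,
    inputs: Optional[Sequence[float]] = None,
    inputs_end: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Advance the state from ``t`` to exactly ``t + dt``.

    ``rhs`` is called as ``rhs(s, t, q)`` when inputs are supplied, else as
    ``rhs(s, t)``.  With only ``inputs`` given they are zero-order-held over
    the whole macro step; with ``inputs_end`` also given they ramp linearly
    from ``inputs`` at ``t`` to ``inputs_end`` at ``t + dt`` (first-order
    hold).
    """
    if dt <= 0:
        raise StructuralError("macro step must be positive")
    n, h = pol.substeps(dt)
    y = np.asarray(s, dtype=float)
    if inputs is None:
        f = rhs
    elif inputs_end is None:
        q = tuple(inputs)
        f = lambda yy, tt: rhs(yy, tt, q)
    else:
        q0 = np.asarray(inputs, dtype=float)
        q1 = np.asarray(inputs_end, dtype=float)
        inv_dt = 1.0 / dt

        def f(yy, tt):
            w = min(max((tt - t) * inv_dt, 0.0), 1.0)
            return rhs(yy, tt, (1.0 - w) * q0 + w * q1)

    for i in range(n):
        # substep times from the macro-step anchor to avoid accumulation drift
        y = rk4_step(f, y, t + i * h, h)
    return y


def integrate_macro_step_fast(model, y0, t: float, dt: float, pol: SubdivisionPolicy,
                              q, q_end=None):
    """Macro step specialised to a :class:`CirculationModel` float-list RHS.

    Numerically identical update formula to :func:`rk4_step` applied via
    :func:`integrate_macro_step`, but operating on Python lists to keep the
    per-substep overhead low.  ``q``/``q_end`` follow the same hold rules.
    """
    n, h = pol.substeps(dt)
    y = list(y0)
    m = len(y)
    rhs = model.rhs_list
    half = 0.5 * h
    sixth = h / 6.0
    ramp = q_end is not None
    if ramp:
        q0 = list(q)
        dq = [(b - a) / dt for a, b in zip(q0, q_end)]
    for i in range(n):
        ti = t + i * h
        if ramp:
            w0 = ti - t
            wm = w0 + half
            w1 = w0 + h
            qa = [a + d * w0 for a, d in zip(q0, dq)]
            qm = [a + d * wm for a, d in zip(q0, dq)]
            qb = [a + d * w1 for a, d in zip(q0, dq)]
        else:
            qa = qm = qb = q
        k1 = rhs(y, ti, qa)
        y2 = [y[j] + half * k1[j] for j in range(m)]
        k2 = rhs(y2, ti + half, qm)
        y3 = [y[j] + half * k2[j] for j in range(m)]
        k3 = rhs(y3, ti + half, qm)
        y4 = [y[j] + h * k3[j] for j in range(m)]
        k4 = rhs(y4, ti + h, qb)
        y = [y[j] + sixth * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) for j in range(m)]
    for v in y:
        if not math.isfinite(v):
            bad = next(j for j, vv in enumerate(y) if not math.isfinite(vv))
            raise NumericalError(
                f"non-finite value in state component {bad} "
                f"({model.state_names[bad]}) at t={t}"
            )
    return y
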