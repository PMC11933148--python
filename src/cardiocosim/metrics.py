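"""Waveform analytics: cycle averages, Qp/Qs, percent differences,
range-normalized RMSE and pressure-volume loop metrics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import StructuralError

__all__ = [
    "WaveformSeries",
    "ClinicalTargets",
    "cycle_average",
    "qp_qs",
    "percent_difference",
    "normalized_rmse",
    "pv_loop_metrics",
]


@dataclass
class WaveformSeries:
    """A time-stamped signal spanning one or more cardiac cycles."""

    t: np.ndarray
    y: np.ndarray
    unit: str = ""
    cycle_index: Optional[np.ndarray] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise StructuralError("waveform t and y must be 1-D and equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise StructuralError("waveform times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    def value_at(self, t: float) -> float:
        return float(np.interp(t, self.t, self.y))

    def windowed(self, t0: float, t1: float) -> "WaveformSeries":
        """Restriction to [t0, t1] with interpolated endpoint samples."""
        if not (self.t[0] - 1e-12 <= t0 < t1 <= self.t[-1] + 1e-12):
            raise StructuralError(
                f"window [{t0}, {t1}] outside waveform support "
                f"[{self.t[0]}, {self.t[-1]}]"
            )
        t0 = max(t0, float(self.t[0]))
        t1 = min(t1, float(self.t[-1]))
        inner = (self.t > t0) & (self.t < t1)
        tt = np.concatenate(([t0], self.t[inner], [t1]))
        yy = np.concatenate(([self.value_at(t0)], self.y[inner], [self.value_at(t1)]))
        return WaveformSeries(tt, yy, unit=self.unit)


@dataclass(frozen=True)
class ClinicalTargets:
    """Cycle-averaged hemodynamic targets for the parallel circulation.

    Flows in mL/s, pressures in mmHg, Qp_Qs dimensionless; all positive.
    """

    CO: float
    Q_UB: float
    Q_DAO: float
    Q_SH: float
    Qp_Qs: float
    P_AO: float
    P_PUL: float

    def __post_init__(self):
        for name, v in self.as_dict().items():
            if not (v > 0 and math.isfinite(v)):
                raise StructuralError(f"clinical target {name} must be positive, got {v}")

    def as_dict(self) -> Dict[str, float]:
        return {k: getattr(self, k) for k in
                ("CO", "Q_UB", "Q_DAO", "Q_SH", "Qp_Qs", "P_AO", "P_PUL")}


def cycle_average(w: WaveformSeries, window: Tuple[float, float]) -> float:
    """Time-weighted (trapezoidal) mean of ``w`` over ``window``."""
    t0, t1 = window
    if not t1 > t0:
        raise StructuralError("averaging window must have positive length")
    ww = w.windowed(t0, t1)
    if len(ww) < 2:
        raise StructuralError("averaging window holds fewer than 2 samples")
    return float(np.trapezoid(ww.y, ww.t) / (t1 - t0))


def qp_qs(q_sh_mean: float, q_ub_mean: float, q_dao_mean: float) -> float:
    """Pulmonary-to-systemic flow ratio, Qp = shunt flow, Qs = upper body +
    descending aorta."""
    qs = q_ub_mean + q_dao_mean
    if qs <= 0:
        raise StructuralError("systemic flow must be positive for Qp/Qs")
    return q_sh_mean / qs


def percent_difference(model_val: float, clinical_val: float,
                       ndigits: Optional[int] = 1) -> float:
    """Absolute percent difference of a model value from a clinical value.

    Reported rounded to one decimal by default (the table convention);
    pass ``ndigits=None`` for the raw value.
    """
    if clinical_val == 0:
        raise StructuralError("clinical value must be nonzero for a percent difference")
    pd = abs(100.0 * (model_val - clinical_val) / clinical_val)
    return pd if ndigits is None else round(pd, ndigits)


def normalized_rmse(sim: WaveformSeries, ref: WaveformSeries) -> float:
    """RMSE of sim vs ref on their overlapping support, normalized by the
    reference peak-to-peak range, in percent.

    Both signals are linearly resampled onto the finer of the two grids.
    """
    t0 = max(float(sim.t[0]), float(ref.t[0]))
    t1 = min(float(sim.t[-1]), float(ref.t[-1]))
    if not t1 > t0:
        raise StructuralError("waveforms have no overlapping time support")
    sw = sim.windowed(t0, t1)
    rw = ref.windowed(t0, t1)
    grid = sw.t if len(sw) >= len(rw) else rw.t
    ys = np.interp(grid, sw.t, sw.y)
    yr = np.interp(grid, rw.t, rw.y)
    rng = float(np.max(rw.y) - np.min(rw.y))
    if rng <= 0:
        raise StructuralError("reference waveform is flat; range normalization undefined")
    return float(100.0 * np.sqrt(np.mean((ys - yr) ** 2)) / rng)


def pv_loop_metrics(P_v: WaveformSeries, V_v: WaveformSeries,
                    window: Tuple[float, float]) -> Dict[str, float]:
    """Stroke volume and loop area of the ventricular pressure-volume loop.

    Stroke volume is max(V) − min(V) over the window; the loop area |∮P dV|
    (stroke work, mmHg·mL) is evaluated by the shoelace rule on the sampled
    loop, closing it between the last and first sample.  A loop that fails
    to return near its start point is flagged (``open_loop``) rather than
    rejected.
    """
    pw = P_v.windowed(*window)
    vw = V_v.windowed(*window)
    grid = pw.t if len(pw) >= len(vw) else vw.t
    p = np.interp(grid, pw.t, pw.y)
    v = np.interp(grid, vw.t, vw.y)
    area = 0.5 * abs(float(np.sum(p * np.roll(v, -1) - v * np.roll(p, -1))))
    sv = float(np.max(v) - np.min(v))
    gap = math.hypot(p[-1] - p[0], v[-1] - v[0])
    scale = math.hypot(float(np.ptp(p)) + 1e-12, sv + 1e-12)
    return {
        "stroke_volume": sv,
        "loop_area": area,
        "open_loop": bool(gap > 0.05 * scale),
    }
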