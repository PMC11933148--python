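"""Waveform analytics: averages, ratios, errors, PV-loop metrics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cardiocosim.errors import StructuralError
from cardiocosim.metrics import (
    ClinicalTargets,
    WaveformSeries,
    cycle_average,
    normalized_rmse,
    percent_difference,
    pv_loop_metrics,
    qp_qs,
)


def _wave(f, t0=0.0, t1=1.0, n=1001):
    t = np.linspace(t0, t1, n)
    return WaveformSeries(t, np.array([f(x) for x in t]))


class TestCycleAverage:
    def test_constant_signal(self):
        assert cycle_average(_wave(lambda t: 5.0), (0.0, 1.0)) == pytest.approx(5.0)

    def test_zero_mean_oscillation(self):
        T = 0.8
        w = _wave(lambda t: math.sin(2 * math.pi * t / T) + 3.0, 0.0, T, 4001)
        assert cycle_average(w, (0.0, T)) == pytest.approx(3.0, abs=1e-6)

    def test_piecewise_linear_against_dense_oracle(self):
        rng = np.random.default_rng(11)
        t = np.sort(rng.uniform(0, 1, 40))
        t[0], t[-1] = 0.0, 1.0
        y = rng.uniform(-5, 5, 40)
        w = WaveformSeries(t, y)
        # resampling oracle: dense uniform grid augmented with the exact
        # breakpoints, so the trapezoid rule is exact for the piecewise-
        # linear signal
        tg = np.union1d(np.linspace(0.2, 0.9, 20_001), t[(t > 0.2) & (t < 0.9)])
        oracle = np.trapezoid(np.interp(tg, t, y), tg) / 0.7
        assert cycle_average(w, (0.2, 0.9)) == pytest.approx(oracle, abs=1e-9)

    def test_empty_window_rejected(self):
        w = _wave(lambda t: 1.0)
        with pytest.raises(StructuralError):
            cycle_average(w, (0.5, 0.5))


class TestQpQs:
    def test_printed_model_flows(self):
        # shunt 10.18 over upper-body 5.79 + descending-aorta 6.04
        assert qp_qs(10.18, 5.79, 6.04) == pytest.approx(0.86, abs=0.005)

    def test_balanced_circulation(self):
        assert qp_qs(8.0, 5.0, 3.0) == 1.0

    def test_zero_shunt(self):
        assert qp_qs(0.0, 5.0, 3.0) == 0.0

    def test_nonpositive_systemic_rejected(self):
        with pytest.raises(StructuralError):
            qp_qs(1.0, 0.0, 0.0)


class TestPercentDifference:
    @pytest.mark.parametrize("model, clinical, expected", [
        (22.0, 21.0, 4.8),
        (5.79, 5.6, 3.4),
        (54.6, 52.0, 5.0),
        (3.0, 3.0, 0.0),
    ])
    def test_table_convention(self, model, clinical, expected):
        assert percent_difference(model, clinical) == expected

    def test_reported_as_absolute(self):
        assert percent_difference(19.0, 21.0) == percent_difference(23.0, 21.0) == 9.5

    @given(st.floats(0.1, 1e3), st.floats(0.1, 1e3), st.floats(0.01, 100.0))
    def test_scale_invariance(self, m, c, s):
        a = percent_difference(m, c, ndigits=None)
        b = percent_difference(m * s, c * s, ndigits=None)
        assert b == pytest.approx(a, rel=1e-9)

    def test_zero_clinical_rejected(self):
        with pytest.raises(StructuralError):
            percent_difference(1.0, 0.0)


class TestNormalizedRMSE:
    def test_identical_signals(self):
        w = _wave(lambda t: math.sin(6 * t))
        assert normalized_rmse(w, w) == 0.0

    def test_constant_offset_closed_form(self):
        ref = _wave(lambda t: math.sin(2 * math.pi * t))  # range 2
        sim = WaveformSeries(ref.t, ref.y + 0.5)
        assert normalized_rmse(sim, ref) == pytest.approx(100 * 0.5 / 2.0, rel=1e-9)

    def test_unit_rescaling_invariance(self):
        ref = _wave(lambda t: math.cos(3 * t) + 2)
        sim = _wave(lambda t: math.cos(3 * t) + 2.1)
        a = normalized_rmse(sim, ref)
        b = normalized_rmse(WaveformSeries(sim.t, 7.5 * sim.y),
                            WaveformSeries(ref.t, 7.5 * ref.y))
        assert abs(a - b) < 1e-12

    def test_positive_unless_identical(self):
        ref = _wave(lambda t: math.sin(5 * t))
        sim = WaveformSeries(ref.t, ref.y + 1e-6)
        assert normalized_rmse(sim, ref) > 0.0

    def test_flat_reference_rejected(self):
        ref = _wave(lambda t: 1.0)
        with pytest.raises(StructuralError):
            normalized_rmse(ref, ref)


class TestPVLoop:
    def test_rectangular_loop_area(self):
        # traverse the rectangle P in {10,50}, V in {20,40}: area 800
        t = np.linspace(0, 1, 5)
        P = WaveformSeries(t, np.array([10.0, 50.0, 50.0, 10.0, 10.0]))
        V = WaveformSeries(t, np.array([20.0, 20.0, 40.0, 40.0, 20.0]))
        out = pv_loop_metrics(P, V, (0.0, 1.0))
        assert out["loop_area"] == pytest.approx(800.0)
        assert out["stroke_volume"] == pytest.approx(20.0)

    def test_elliptical_loop_area(self):
        a, b = 25.0, 12.0
        th = np.linspace(0, 2 * math.pi, 10_001)
        t = np.linspace(0, 1, 10_001)
        P = WaveformSeries(t, 40 + a * np.cos(th))
        V = WaveformSeries(t, 30 + b * np.sin(th))
        out = pv_loop_metrics(P, V, (0.0, 1.0))
        assert out["loop_area"] == pytest.approx(math.pi * a * b, rel=1e-3)
        assert not out["open_loop"]

    def test_stroke_volume_of_sinusoid(self):
        t = np.linspace(0, 1, 2001)
        V = WaveformSeries(t, 30 + 10 * np.sin(2 * math.pi * t))
        P = WaveformSeries(t, 40 + 5 * np.cos(2 * math.pi * t))
        out = pv_loop_metrics(P, V, (0.0, 1.0))
        assert out["stroke_volume"] == pytest.approx(20.0, rel=1e-4)

    def test_open_loop_flagged(self):
        t = np.linspace(0, 1, 100)
        P = WaveformSeries(t, 10 + 40 * t)
        V = WaveformSeries(t, 20 + 20 * t)
        assert pv_loop_metrics(P, V, (0.0, 1.0))["open_loop"]


class TestClinicalTargets:
    def test_positive_required(self):
        with pytest.raises(StructuralError):
            ClinicalTargets(CO=21, Q_UB=5.6, Q_DAO=5.7, Q_SH=-1,
                            Qp_Qs=0.9, P_AO=52, P_PUL=12)
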