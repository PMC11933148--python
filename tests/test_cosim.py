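"""Follower contract: registry, do-step semantics, FMU packaging/checking."""

import zipfile
from xml.etree import ElementTree as ET

import numpy as np
import pytest

from cardiocosim.config import BOUNDARIES, default_config
from cardiocosim.cosim import (
    CosimSlave,
    StepStatus,
    check_fmu,
    load_fmu,
    package_fmu,
)
from cardiocosim.errors import CausalityError, InterfaceError
from cardiocosim.solver import SubdivisionPolicy, integrate_macro_step


@pytest.fixture()
def slave():
    return CosimSlave(default_config().lpm)


class TestRegistry:
    def test_unique_references_and_starts(self, slave):
        refs = [v.value_reference for v in slave.variables]
        assert len(refs) == len(set(refs))
        for v in slave.variables:
            if v.causality in ("input", "parameter"):
                assert v.start is not None

    def test_unknown_reference_rejected(self, slave):
        with pytest.raises(InterfaceError):
            slave.set_input(999, 1.0)
        with pytest.raises(InterfaceError):
            slave.get_output(999)

    def test_setting_an_output_rejected(self, slave):
        ref = slave.ref_of("P_aortic_root")
        with pytest.raises(CausalityError):
            slave.set_input(ref, 1.0)


class TestDoStep:
    def test_null_input_static_model(self):
        from conftest import equilibrium_config
        s = CosimSlave(equilibrium_config().lpm)
        before = [s.get(f"P_{b}") for b in BOUNDARIES]
        for b in BOUNDARIES:
            s.set(f"Q_{b}", 0.0)
        assert s.do_step(0.0, 1e-3) is StepStatus.OK
        after = [s.get(f"P_{b}") for b in BOUNDARIES]
        assert after == pytest.approx(before, abs=1e-12)

    def test_fixed_point_outputs_constant(self):
        from conftest import equilibrium_config
        s = CosimSlave(equilibrium_config().lpm)
        p0 = s.get("P_ventricle")
        for i in range(5):
            assert s.do_step(i * 1e-3, 1e-3) is StepStatus.OK
        assert s.get("P_ventricle") == pytest.approx(p0, abs=1e-10)

    def test_matches_direct_solver_call(self, slave):
        """Driving through the interface equals integrating directly."""
        q = [12.0, 2.0, 1.0, 1.0, 4.0, 4.5, 4.5]
        for b, v in zip(BOUNDARIES, q):
            slave.set(f"Q_{b}", v)
        y0 = slave.state.copy()
        model, pol = slave.model, slave.solver
        assert slave.do_step(0.0, 1e-3) is StepStatus.OK
        direct = integrate_macro_step(
            lambda y, t, qq: model.rhs(y, t, qq), y0, 0.0, 1e-3, pol, inputs=q)
        assert slave.state == pytest.approx(direct, rel=1e-12)
        p_direct = model.boundary_pressures(direct, 1e-3, q)
        assert [slave.get(f"P_{b}") for b in BOUNDARIES] == pytest.approx(p_direct, rel=1e-12)

    def test_chaining_two_half_steps(self, slave):
        q = [10.0, 2.0, 1.0, 1.0, 4.0, 4.0, 4.0]
        twin = CosimSlave(default_config().lpm)
        for b, v in zip(BOUNDARIES, q):
            slave.set(f"Q_{b}", v)
            twin.set(f"Q_{b}", v)
        assert slave.do_step(0.0, 1e-3) is StepStatus.OK
        assert twin.do_step(0.0, 5e-4) is StepStatus.OK
        assert twin.do_step(5e-4, 5e-4) is StepStatus.OK
        p1 = [slave.get(f"P_{b}") for b in BOUNDARIES]
        p2 = [twin.get(f"P_{b}") for b in BOUNDARIES]
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_out_of_order_step_rejected(self, slave):
        assert slave.do_step(0.5, 1e-3) is StepStatus.ERROR
        assert "out-of-order" in slave.last_error

    def test_clock_accumulates_step_sizes(self, slave):
        steps = [1e-3, 2.5e-4, 7.5e-4, 5e-4]
        t = 0.0
        for dt in steps:
            assert slave.do_step(t, dt) is StepStatus.OK
            t += dt
        assert slave.clock == pytest.approx(sum(steps), abs=1e-15)

    def test_parameter_change_takes_effect(self, slave):
        slave.set("E_max", 20.0)
        assert slave.do_step(0.0, 1e-3) is StepStatus.OK
        assert slave.model.chambers[0].elastance.E_max == 20.0


class TestFMUArchive:
    def test_round_trip_preserves_registry(self, slave, tmp_path):
        p = tmp_path / "norwood.fmu"
        package_fmu(slave, p)
        clone = load_fmu(p)
        assert [(v.name, v.value_reference, v.causality, v.start)
                for v in clone.variables] == \
               [(v.name, v.value_reference, v.causality, v.start)
                for v in slave.variables]

    def test_archive_declares_fmi_2_0(self, slave, tmp_path):
        p = tmp_path / "norwood.fmu"
        package_fmu(slave, p)
        with zipfile.ZipFile(p) as zf:
            assert "modelDescription.xml" in zf.namelist()
            root = ET.fromstring(zf.read("modelDescription.xml"))
        assert root.get("fmiVersion") == "2.0"
        assert root.find("CoSimulation") is not None

    def test_packaged_fmu_passes_checker(self, slave, tmp_path):
        p = tmp_path / "norwood.fmu"
        package_fmu(slave, p)
        report = check_fmu(p)
        assert report.passed, str(report)

    def test_packaging_is_deterministic(self, slave, tmp_path):
        g1 = package_fmu(slave, tmp_path / "a.fmu")
        g2 = package_fmu(CosimSlave(default_config().lpm), tmp_path / "b.fmu")
        assert g1 == g2


class TestChecker:
    def _write(self, path, xml: bytes, with_md=True):
        with zipfile.ZipFile(path, "w") as zf:
            if with_md:
                zf.writestr("modelDescription.xml", xml)
            zf.writestr("resources/model.yaml", "{}")

    def test_missing_model_description(self, tmp_path):
        p = tmp_path / "bad.fmu"
        self._write(p, b"", with_md=False)
        rep = check_fmu(p)
        assert any(f.code == "missing-model-description" for f in rep.findings)

    def test_malformed_xml(self, tmp_path):
        p = tmp_path / "bad.fmu"
        self._write(p, b"<not-closed")
        rep = check_fmu(p)
        assert any(f.code == "malformed-xml" for f in rep.findings)

    def test_duplicate_value_reference_named(self, tmp_path):
        xml = (
            b'<fmiModelDescription fmiVersion="2.0" modelName="m" guid="g">'
            b'<CoSimulation modelIdentifier="m"/>'
            b'<ModelVariables>'
            b'<ScalarVariable name="a" valueReference="3" causality="output"><Real/></ScalarVariable>'
            b'<ScalarVariable name="b" valueReference="3" causality="output"><Real/></ScalarVariable>'
            b'</ModelVariables></fmiModelDescription>'
        )
        p = tmp_path / "dup.fmu"
        self._write(p, xml)
        rep = check_fmu(p)
        assert any(f.code == "duplicate-value-reference" and "3" in f.message
                   for f in rep.findings)

    def test_input_without_start_flagged(self, tmp_path):
        xml = (
            b'<fmiModelDescription fmiVersion="2.0" modelName="m" guid="g">'
            b'<CoSimulation modelIdentifier="m"/>'
            b'<ModelVariables>'
            b'<ScalarVariable name="u" valueReference="0" causality="input"><Real/></ScalarVariable>'
            b'</ModelVariables></fmiModelDescription>'
        )
        p = tmp_path / "nostart.fmu"
        self._write(p, xml)
        rep = check_fmu(p)
        assert any(f.code == "missing-start" for f in rep.findings)

    def test_unreadable_archive_raises(self, tmp_path):
        p = tmp_path / "not_a_zip.fmu"
        p.write_text("hello")
        with pytest.raises(OSError):
            check_fmu(p)
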