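"""FMI-style co-simulation follower: variable registry, do-step semantics,
FMU archive packaging, and a structural compliance checker.

The follower owns its solver (fixed-step RK4 with ≤ h_max subdivision) and
is driven purely through set-input / do-step / read-output calls, mirroring
an FMI 2.0 co-simulation unit.  Packaging is source-based: the archive
carries modelDescription.xml plus the model configuration in resources,
and is reloadable by this framework; no compiled C binary is produced.
"""

from __future__ import annotations

import enum
import hashlib
import math
import zipfile
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple
from xml.etree import ElementTree as ET

import numpy as np
import yaml

from .config import BOUNDARIES, LPMConfig
from .errors import (
    CausalityError,
    InterfaceError,
    PackagingError,
    ProtocolError,
)
from .lpm import CirculationModel, build_norwood_lpm, elastance as _elastance, initial_state
from .solver import SubdivisionPolicy, integrate_macro_step_fast

__all__ = [
    "VariableDescriptor",
    "CosimSlave",
    "StepStatus",
    "package_fmu",
    "load_fmu",
    "check_fmu",
    "ComplianceFinding",
    "ComplianceReport",
]

CLOCK_TOL = 1e-12  # s, allowed drift between commanded and internal time


@dataclass(frozen=True)
class VariableDescriptor:
    name: str
    value_reference: int
    causality: str  # "input" | "output" | "parameter"
    unit: str = ""
    start: Optional[float] = None


class StepStatus(enum.Enum):
    OK = "ok"
    ERROR = "error"


_PARAMETER_NAMES = ("T", "E_max", "E_min", "t_peak", "V0", "h_max_us")


def _build_registry(cfg: LPMConfig) -> List[VariableDescriptor]:
    """Variable registry: boundary-flow inputs, pressure/monitor outputs,
    and the tunable heart/solver parameters."""
    out: List[VariableDescriptor] = []
    ref = 0
    for b in BOUNDARIES:
        out.append(VariableDescriptor(f"Q_{b}", ref, "input", "mL/s", start=0.0))
        ref += 1
    for b in BOUNDARIES:
        out.append(VariableDescriptor(f"P_{b}", ref, "output", "mmHg"))
        ref += 1
    for b in BOUNDARIES:
        out.append(VariableDescriptor(f"Q_{b}_out", ref, "output", "mL/s"))
        ref += 1
    for name, unit in (("P_ventricle", "mmHg"), ("V_ventricle", "mL"),
                       ("P_atrium", "mmHg"), ("V_atrium", "mL")):
        out.append(VariableDescriptor(name, ref, "output", unit))
        ref += 1
    heart = cfg.heart
    starts = {
        "T": heart.T, "E_max": heart.E_max, "E_min": heart.E_min,
        "t_peak": heart.t_peak, "V0": heart.V0, "h_max_us": cfg.h_max_us,
    }
    units = {"T": "s", "E_max": "mmHg/mL", "E_min": "mmHg/mL",
             "t_peak": "s", "V0": "mL", "h_max_us": "us"}
    for name in _PARAMETER_NAMES:
        out.append(VariableDescriptor(name, ref, "parameter", units[name], start=starts[name]))
        ref += 1
    return out


class CosimSlave:
    """The packaged follower: circulation model + RK4 solver + registry."""

    model_identifier = "norwood_lpm"

    def __init__(self, cfg: LPMConfig, state: Optional[np.ndarray] = None):
        self.cfg = cfg
        self.variables: List[VariableDescriptor] = _build_registry(cfg)
        self._by_ref: Dict[int, VariableDescriptor] = {}
        for v in self.variables:
            if v.value_reference in self._by_ref:
                raise PackagingError(f"duplicate value reference {v.value_reference}")
            self._by_ref[v.value_reference] = v
        self._by_name = {v.name: v for v in self.variables}
        self._values: Dict[int, float] = {
            v.value_reference: (v.start if v.start is not None else 0.0)
            for v in self.variables
        }
        self._params_dirty = False
        self._q_refs = [self._by_name[f"Q_{b}"].value_reference for b in BOUNDARIES]
        self._p_refs = [self._by_name[f"P_{b}"].value_reference for b in BOUNDARIES]
        self._qout_refs = [self._by_name[f"Q_{b}_out"].value_reference for b in BOUNDARIES]
        self._rebuild_model()
        self.state = (np.asarray(state, dtype=float) if state is not None
                      else initial_state(self.model, cfg))
        self.clock = 0.0
        self.last_error: Optional[str] = None
        self.last_substeps: Tuple[int, float] = (0, 0.0)
        self._refresh_outputs()

    # -- construction ------------------------------------------------
    def _rebuild_model(self) -> None:
        heart = self.cfg.heart.model_copy(
            update={k: self._values[self._by_name[k].value_reference]
                    for k in ("T", "E_max", "E_min", "t_peak", "V0")}
        )
        cfg = self.cfg.model_copy(update={
            "heart": heart,
            "h_max_us": self._values[self._by_name["h_max_us"].value_reference],
        })
        self.cfg = cfg
        self.model: CirculationModel = build_norwood_lpm(cfg)
        self.solver = SubdivisionPolicy(h_max=cfg.h_max_us * 1e-6)
        idx = self.model.variable_names()
        self._i_vsv = idx["V_sv"]
        self._i_va = idx["V_atrium"]
        self._params_dirty = False

    # -- registry access ---------------------------------------------
    def ref_of(self, name: str) -> int:
        try:
            return self._by_name[name].value_reference
        except KeyError:
            raise InterfaceError(f"unknown variable {name!r}") from None

    def set_input(self, ref: int, value: float) -> None:
        """Store an input or parameter value; takes effect at the next step."""
        var = self._by_ref.get(ref)
        if var is None:
            raise InterfaceError(f"unknown value reference {ref}")
        if var.causality == "output":
            raise CausalityError(f"variable {var.name!r} is an output and cannot be set")
        if not math.isfinite(value):
            raise InterfaceError(f"non-finite value for {var.name!r}")
        self._values[ref] = float(value)
        if var.causality == "parameter":
            self._params_dirty = True

    def get_output(self, ref: int) -> float:
        var = self._by_ref.get(ref)
        if var is None:
            raise InterfaceError(f"unknown value reference {ref}")
        return self._values[ref]

    def get(self, name: str) -> float:
        return self.get_output(self.ref_of(name))

    def set(self, name: str, value: float) -> None:
        self.set_input(self.ref_of(name), value)

    # -- stepping ----------------------------------------------------
    def _input_flows(self) -> List[float]:
        v = self._values
        return [v[r] for r in self._q_refs]

    def set_boundary_flows(self, q: Sequence[float]) -> None:
        """Bulk set of all boundary-flow inputs, in boundary order."""
        v = self._values
        for r, qq in zip(self._q_refs, q):
            v[r] = qq

    def do_step(self, t_comm: float, dt: float,
                inputs_end: Optional[Sequence[float]] = None) -> StepStatus:
        """Advance the follower from ``t_comm`` to ``t_comm + dt``.

        ``inputs_end`` optionally supplies end-of-step boundary flows for a
        first-order input hold; by default the stored inputs are held
        constant (zero-order).
        """
        if dt <= 0:
            self.last_error = "macro step must be positive"
            return StepStatus.ERROR
        if abs(t_comm - self.clock) > CLOCK_TOL:
            self.last_error = (
                f"out-of-order do_step: commanded t={t_comm!r}, slave clock={self.clock!r}"
            )
            return StepStatus.ERROR
        if self._params_dirty:
            self._rebuild_model()
        q = self._input_flows()
        try:
            y = integrate_macro_step_fast(
                self.model, self.state, self.clock, dt, self.solver, q,
                q_end=inputs_end,
            )
        except Exception as exc:  # numerical failure inside the solver
            self.last_error = str(exc)
            return StepStatus.ERROR
        self.state = np.asarray(y)
        self.clock = t_comm + dt
        self.last_substeps = self.solver.substeps(dt)
        if inputs_end is not None:
            self.set_boundary_flows([float(v) for v in inputs_end])
        self._refresh_outputs()
        return StepStatus.OK

    def _refresh_outputs(self) -> None:
        q = self._input_flows()
        pb = self.model.boundary_pressures(self.state, self.clock, q)
        v = self._values
        for r, p in zip(self._p_refs, pb):
            v[r] = p
        for r, qq in zip(self._qout_refs, q):
            v[r] = qq
        y = self.state
        ep = self.model.chambers[0].elastance
        v[self._by_name["V_ventricle"].value_reference] = float(y[self._i_vsv])
        v[self._by_name["P_ventricle"].value_reference] = (
            _elastance(self.clock, ep) * (float(y[self._i_vsv]) - ep.V0)
        )
        at = self.model.chambers[1]
        v[self._by_name["V_atrium"].value_reference] = float(y[self._i_va])
        v[self._by_name["P_atrium"].value_reference] = (
            (float(y[self._i_va]) - at.V0) / at.C
        )

    def boundary_pressure_vector(self) -> List[float]:
        v = self._values
        return [v[r] for r in self._p_refs]


# ---------------------------------------------------------------------------
# FMU archive
# ---------------------------------------------------------------------------

def _model_description_xml(slave: CosimSlave, guid: str) -> bytes:
    root = ET.Element("fmiModelDescription", {
        "fmiVersion": "2.0",
        "modelName": slave.model_identifier,
        "guid": guid,
        "generationTool": "cardiocosim",
        "numberOfEventIndicators": "0",
    })
    ET.SubElement(root, "CoSimulation", {
        "modelIdentifier": slave.model_identifier,
        "canHandleVariableCommunicationStepSize": "true",
    })
    ET.SubElement(root, "DefaultExperiment", {
        "startTime": "0.0",
        "stopTime": repr(8 * slave.cfg.heart.T),
        "stepSize": "0.001",
    })
    mv = ET.SubElement(root, "ModelVariables")
    for v in slave.variables:
        attrs = {
            "name": v.name,
            "valueReference": str(v.value_reference),
            "causality": v.causality,
            "variability": "tunable" if v.causality == "parameter" else "continuous",
        }
        sv = ET.SubElement(mv, "ScalarVariable", attrs)
        rattrs = {}
        if v.unit:
            rattrs["unit"] = v.unit
        if v.start is not None:
            rattrs["start"] = repr(v.start)
        ET.SubElement(sv, "Real", rattrs)
    ms = ET.SubElement(root, "ModelStructure")
    outs = ET.SubElement(ms, "Outputs")
    for i, v in enumerate(slave.variables, start=1):
        if v.causality == "output":
            ET.SubElement(outs, "Unknown", {"index": str(i)})
    return ET.tostring(root, encoding="utf-8", xml_declaration=True)


def package_fmu(slave: CosimSlave, path) -> str:
    """Write the follower as an FMI-2.0-style co-simulation archive.

    Returns the archive's guid.  Raises :class:`PackagingError` on a
    registry with duplicate value references.
    """
    refs = [v.value_reference for v in slave.variables]
    dupes = sorted({r for r in refs if refs.count(r) > 1})
    if dupes:
        raise PackagingError(f"duplicate value references: {dupes}")
    for v in slave.variables:
        if v.causality in ("input", "parameter") and v.start is None:
            raise PackagingError(f"variable {v.name!r} ({v.causality}) lacks a start value")
    cfg_yaml = yaml.safe_dump(slave.cfg.model_dump(mode="json"), sort_keys=True)
    guid = hashlib.sha1(
        (cfg_yaml + "".join(f"{v.name}:{v.value_reference}:{v.causality}"
                            for v in slave.variables)).encode()
    ).hexdigest()
    xml = _model_description_xml(slave, guid)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("modelDescription.xml", xml)
        zf.writestr("resources/model.yaml", cfg_yaml)
        zf.writestr(
            "resources/loader.txt",
            "Source-based co-simulation unit produced by cardiocosim.\n"
            "Reconstruct with cardiocosim.cosim.load_fmu(path).\n",
        )
    return guid


def load_fmu(path) -> CosimSlave:
    """Rebuild a follower from an archive produced by :func:`package_fmu`."""
    with zipfile.ZipFile(path) as zf:
        cfg_raw = yaml.safe_load(zf.read("resources/model.yaml"))
    cfg = LPMConfig.model_validate(cfg_raw)
    return CosimSlave(cfg)


# ---------------------------------------------------------------------------
# structural compliance checker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplianceFinding:
    code: str
    message: str


@dataclass
class ComplianceReport:
    findings: List[ComplianceFinding] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.findings

    def add(self, code: str, message: str) -> None:
        self.findings.append(ComplianceFinding(code, message))

    def __str__(self) -> str:
        if self.passed:
            return "PASS: no findings"
        return "\n".join(f"[{f.code}] {f.message}" for f in self.findings)


def check_fmu(path) -> ComplianceReport:
    """Structural check of an FMU archive against the FMI 2.0 layout.

    Findings cover: missing/malformed model description, wrong FMI version,
    missing co-simulation element, duplicate value references, inputs or
    parameters without start values, and unknown causalities.
    """
    report = ComplianceReport()
    try:
        zf = zipfile.ZipFile(path)
    except (OSError, zipfile.BadZipFile) as exc:
        raise OSError(f"cannot read FMU archive {path}: {exc}") from exc
    with zf:
        names = zf.namelist()
        if "modelDescription.xml" not in names:
            report.add("missing-model-description",
                       "archive root lacks modelDescription.xml")
            return report
        try:
            root = ET.fromstring(zf.read("modelDescription.xml"))
        except ET.ParseError as exc:
            report.add("malformed-xml", f"modelDescription.xml does not parse: {exc}")
            return report
    if root.get("fmiVersion") != "2.0":
        report.add("fmi-version", f"fmiVersion is {root.get('fmiVersion')!r}, expected '2.0'")
    if root.find("CoSimulation") is None:
        report.add("missing-cosimulation", "no CoSimulation element declared")
    if not root.get("guid"):
        report.add("missing-guid", "model description lacks a guid")
    seen: Dict[int, str] = {}
    for sv in root.iter("ScalarVariable"):
        name = sv.get("name", "?")
        try:
            ref = int(sv.get("valueReference", ""))
        except ValueError:
            report.add("bad-value-reference", f"variable {name!r} has no integer valueReference")
            continue
        if ref in seen:
            report.add("duplicate-value-reference",
                       f"value reference {ref} shared by {seen[ref]!r} and {name!r}")
        else:
            seen[ref] = name
        causality = sv.get("causality", "local")
        if causality not in ("input", "output", "parameter", "local", "independent"):
            report.add("unknown-causality", f"variable {name!r} has causality {causality!r}")
        real = sv.find("Real")
        if causality in ("input", "parameter"):
            if real is None or real.get("start") is None:
                report.add("missing-start", f"{causality} {name!r} lacks a start value")
    return report
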