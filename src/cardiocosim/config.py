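"""Run configuration schema.

The whole simulation — circulation topology parameters, leader surrogate
network, coupling protocol and monitors — is driven by one structured
config (YAML on disk, pydantic-validated in memory).  Units are fixed
internally: pressure mmHg, volume mL, time s; hence resistance mmHg·s/mL,
compliance mL/mmHg, inertance mmHg·s²/mL.
"""

from __future__ import annotations

import math
from typing import Dict, List, Literal, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError

#: Canonical boundary labels shared by follower and leader (order matters:
#: it fixes the layout of exchange vectors).
BOUNDARIES: Tuple[str, ...] = (
    "aortic_root",
    "innominate",
    "l_carotid",
    "l_subclavian",
    "dao",
    "lpa",
    "rpa",
)

#: Orientation convention: +1 if positive exchanged flow enters the LPM at
#: that boundary.  The aortic root feeds the leader (arch inlet), so positive
#: flow there leaves the LPM.
ORIENTATION: Dict[str, int] = {b: (-1 if b == "aortic_root" else +1) for b in BOUNDARIES}

#: Required branch labels of the leader surrogate network.
LEADER_BRANCHES: Tuple[str, ...] = (
    "aortic_root",      # aortic_root boundary -> arch node
    "brachiocephalic",  # arch -> innominate junction
    "innominate",       # innominate junction -> innominate boundary
    "l_carotid",        # arch -> l_carotid boundary
    "l_subclavian",     # arch -> l_subclavian boundary
    "dao",              # arch -> dao boundary
    "shunt",            # innominate junction -> pulmonary junction (MBTS)
    "lpa",              # pulmonary junction -> lpa boundary
    "rpa",              # pulmonary junction -> rpa boundary
)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class HeartConfig(_Model):
    """Time-varying elastance single ventricle."""

    T: float = Field(0.4, gt=0, description="cardiac period (s)")
    E_max: float = Field(14.0, gt=0, description="peak elastance (mmHg/mL)")
    E_min: float = Field(0.22, gt=0, description="diastolic elastance (mmHg/mL)")
    t_peak: float = Field(0.12, gt=0, description="time of peak activation (s)")
    V0: float = Field(3.0, ge=0, description="unstressed volume (mL)")

    @model_validator(mode="after")
    def _check(self) -> "HeartConfig":
        if self.E_max < self.E_min:
            raise ValueError("E_max must be >= E_min")
        if not self.t_peak < self.T:
            raise ValueError("t_peak must lie inside the cardiac period")
        return self


class AtriumConfig(_Model):
    """Passive common atrium."""

    C: float = Field(2.0, gt=0, description="compliance (mL/mmHg)")
    V0: float = Field(2.0, ge=0, description="unstressed volume (mL)")


class ValveConfig(_Model):
    R_open: float = Field(..., gt=0, description="forward resistance (mmHg·s/mL)")
    eps: float = Field(0.0, ge=0, description="smoothing width (mmHg); 0 = ideal diode")


class BedConfig(_Model):
    """Three-element Windkessel vascular bed behind a coupling boundary."""

    R_prox: float = Field(0.05, ge=0, description="proximal (characteristic) resistance")
    C: float = Field(..., gt=0, description="bed compliance (mL/mmHg)")
    R_dist: float = Field(..., gt=0, description="distal resistance to the venous node")


class VenousConfig(_Model):
    C: float = Field(..., gt=0)
    R_return: float = Field(..., gt=0, description="resistance into the atrium")


class InitialState(_Model):
    """Initial conditions; pressures in mmHg, volumes in mL."""

    V_sv: float = Field(16.0, gt=0)
    V_a: float = Field(8.5, gt=0)
    P_aortic_root: float = 52.0
    P_innominate: float = 50.0
    P_l_carotid: float = 50.0
    P_l_subclavian: float = 50.0
    P_dao: float = 50.0
    P_lpa: float = 12.0
    P_rpa: float = 12.0
    P_venous_systemic: float = 4.0
    P_venous_pulmonary: float = 4.5


class LPMConfig(_Model):
    heart: HeartConfig = HeartConfig()
    atrium: AtriumConfig = AtriumConfig()
    av_valve: ValveConfig = ValveConfig(R_open=0.012)
    aortic_valve: ValveConfig = ValveConfig(R_open=0.03)
    aortic_root_C: float = Field(0.08, gt=0, description="aortic root node compliance")
    beds: Dict[str, BedConfig]
    venous_systemic: VenousConfig = VenousConfig(C=3.5, R_return=0.09)
    venous_pulmonary: VenousConfig = VenousConfig(C=1.8, R_return=0.10)
    h_max_us: float = Field(100.0, gt=0, description="max internal RK4 substep (µs)")
    initial: InitialState = InitialState()

    @model_validator(mode="after")
    def _check_beds(self) -> "LPMConfig":
        required = [b for b in BOUNDARIES if b != "aortic_root"]
        missing = [b for b in required if b not in self.beds]
        if missing:
            raise ValueError(f"missing vascular bed parameters for: {missing}")
        extra = [b for b in self.beds if b not in required]
        if extra:
            raise ValueError(f"unknown vascular bed names: {extra}")
        return self


class BranchConfig(_Model):
    R: float = Field(..., ge=0, description="linear resistance (mmHg·s/mL)")
    L: float = Field(..., gt=0, description="inertance (mmHg·s²/mL)")
    k: float = Field(0.0, ge=0, description="quadratic loss coefficient (mmHg·s²/mL²)")


class LeaderConfig(_Model):
    branches: Dict[str, BranchConfig]
    dt_min_us: float = Field(10.0, gt=0)
    dt_max_us: float = Field(2000.0, gt=0)
    residual_tol: float = Field(1e-5, gt=0, description="junction residual tolerance, relative")
    max_iterations: int = Field(50, ge=1)
    error_tol: float = Field(2e-3, gt=0, description="step-controller local error tolerance")

    @model_validator(mode="after")
    def _check(self) -> "LeaderConfig":
        missing = [b for b in LEADER_BRANCHES if b not in self.branches]
        if missing:
            raise ValueError(f"missing leader branches: {missing}")
        extra = [b for b in self.branches if b not in LEADER_BRANCHES]
        if extra:
            raise ValueError(f"unknown leader branches: {extra}")
        if self.dt_min_us > self.dt_max_us:
            raise ValueError("dt_min_us must not exceed dt_max_us")
        return self


class CouplingConfig(_Model):
    n_cycles: int = Field(8, ge=1, description="number of cardiac cycles to simulate")
    exchange_iterations: int = Field(
        1, ge=1, description="inner leader/follower exchange repetitions per macro step"
    )
    input_hold: Literal["zero", "first"] = Field(
        "zero", description="hold order for boundary-flow inputs across a macro step"
    )


DEFAULT_MONITORS: Tuple[str, ...] = (
    "P_ventricle",
    "V_ventricle",
    "P_atrium",
    "Q_shunt",
    "P_pulmonary",
    "P_arch",
)


class RunConfig(_Model):
    lpm: LPMConfig
    leader: LeaderConfig
    coupling: CouplingConfig = CouplingConfig()
    monitors: List[str] = Field(default_factory=lambda: list(DEFAULT_MONITORS))
    seed: int = 0

    @model_validator(mode="after")
    def _check_monitors(self) -> "RunConfig":
        allowed = set(DEFAULT_MONITORS)
        bad = [m for m in self.monitors if m not in allowed]
        if bad:
            raise ValueError(f"unknown monitors: {bad}; allowed: {sorted(allowed)}")
        return self

    # -- convenience -------------------------------------------------
    @property
    def period(self) -> float:
        return self.lpm.heart.T

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")


def default_config() -> RunConfig:
    """Shipped default Norwood + MBTS configuration.

    Parameter values represent a ~3.5 kg neonate after stage-1 palliation
    (heart rate 150 bpm, mean aortic pressure ≈ 50 mmHg, Qp/Qs ≈ 0.9); the
    fine balance against a particular patient's measurements is the job of
    the tuner, not of these defaults.
    """
    beds = {
        "innominate": BedConfig(R_prox=0.05, C=0.030, R_dist=19.0),
        "l_carotid": BedConfig(R_prox=0.08, C=0.020, R_dist=31.0),
        "l_subclavian": BedConfig(R_prox=0.08, C=0.020, R_dist=31.0),
        "dao": BedConfig(R_prox=0.04, C=0.10, R_dist=8.4),
        "lpa": BedConfig(R_prox=0.03, C=0.05, R_dist=1.65),
        "rpa": BedConfig(R_prox=0.03, C=0.05, R_dist=1.65),
    }
    branches = {
        "aortic_root": BranchConfig(R=0.08, L=3e-4),
        "brachiocephalic": BranchConfig(R=0.05, L=2e-4),
        "innominate": BranchConfig(R=0.05, L=2e-4),
        "l_carotid": BranchConfig(R=0.15, L=3e-4),
        "l_subclavian": BranchConfig(R=0.15, L=3e-4),
        "dao": BranchConfig(R=0.05, L=2e-4),
        "shunt": BranchConfig(R=1.0, L=5e-4, k=0.31),
        "lpa": BranchConfig(R=0.05, L=2e-4),
        "rpa": BranchConfig(R=0.05, L=2e-4),
    }
    return RunConfig(lpm=LPMConfig(beds=beds), leader=LeaderConfig(branches=branches))


def load_shipped_config() -> RunConfig:
    """Load the default Norwood configuration shipped as package data.

    Content-identical to :func:`default_config`; exists so the on-disk
    schema itself is exercised.
    """
    from importlib.resources import files

    text = files("cardiocosim").joinpath("data/norwood.yaml").read_text(encoding="utf-8")
    return config_from_dict(yaml.safe_load(text))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected; violations raise :class:`ConfigurationError`
    naming the offending key and constraint.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            key = ".".join(str(p) for p in err["loc"])
            lines.append(f"{key}: {err['msg']}")
        raise ConfigurationError("invalid configuration: " + "; ".join(lines)) from exc


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def _finite(x: float) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)
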