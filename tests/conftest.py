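import pytest
from hypothesis import HealthCheck, settings

from cardiocosim.config import RunConfig, default_config
from cardiocosim.driver import run_coupled
from cardiocosim.io import shipped_targets

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def default_cfg() -> RunConfig:
    return default_config()


@pytest.fixture(scope="session")
def coupled_default(default_cfg):
    """One shared 8-cycle coupled run of the shipped configuration."""
    return run_coupled(default_cfg)


@pytest.fixture(scope="session")
def clinical_targets():
    return shipped_targets()


def equilibrium_config(P_eq: float = 10.0) -> RunConfig:
    """A zero-amplitude-elastance config at a uniform-pressure equilibrium.

    With E_max = E_min = E and every node at pressure P_eq, chamber volumes
    V0 + P_eq/E (ventricle) and V0 + C·P_eq (atrium) make every pressure
    gradient vanish, so the closed loop should sit still.
    """
    cfg = default_config()
    E = 0.5
    cfg.lpm.heart.E_max = E
    cfg.lpm.heart.E_min = E
    ini = cfg.lpm.initial
    ini.V_sv = cfg.lpm.heart.V0 + P_eq / E
    ini.V_a = cfg.lpm.atrium.V0 + cfg.lpm.atrium.C * P_eq
    for f in ("P_aortic_root", "P_innominate", "P_l_carotid", "P_l_subclavian",
              "P_dao", "P_lpa", "P_rpa", "P_venous_systemic", "P_venous_pulmonary"):
        setattr(ini, f, P_eq)
    return cfg
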