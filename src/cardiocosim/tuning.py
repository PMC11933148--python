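"""Deterministic parameter tuning toward cycle-averaged clinical targets.

The paper-style workflow tunes the circulation so that the coupled model's
final-cycle averages land within a percent-difference envelope of measured
values.  Tuning here is a derivative-free coordinate descent on the
logarithm of a documented subset of parameters; it is fully deterministic:
the same config, targets and budget always yield the same tuned config.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

from .config import RunConfig
from .driver import run_coupled
from .errors import ConfigurationError
from .metrics import ClinicalTargets, percent_difference

log = logging.getLogger(__name__)

__all__ = ["TuningResult", "tune_parameters", "TUNABLE_PARAMETERS", "apply_multipliers"]

#: Names of the tunable degrees of freedom, each a multiplicative factor
#: applied to the shipped config.  Documented subset: vascular-bed
#: resistances, shunt loss, peak elastance, and circulating volume.
TUNABLE_PARAMETERS: Tuple[str, ...] = (
    "r_systemic",   # total systemic resistance (upper + lower beds together)
    "r_upper",      # distal resistance of innominate/carotid/subclavian beds
    "r_lower",      # distal resistance of the descending-aorta bed
    "r_pulmonary",  # distal resistance of the lpa/rpa beds
    "shunt_loss",   # shunt branch R and quadratic k together
    "e_max",        # ventricular peak elastance
    "volume",       # circulating volume (initial chamber volumes + pressures)
)


def apply_multipliers(cfg: RunConfig, m: Dict[str, float]) -> RunConfig:
    """Return a new config with the tuning multipliers applied."""
    c = cfg.model_copy(deep=True)
    mu = {k: m.get(k, 1.0) for k in TUNABLE_PARAMETERS}
    for bed in ("innominate", "l_carotid", "l_subclavian"):
        c.lpm.beds[bed].R_dist *= mu["r_upper"] * mu["r_systemic"]
    c.lpm.beds["dao"].R_dist *= mu["r_lower"] * mu["r_systemic"]
    for bed in ("lpa", "rpa"):
        c.lpm.beds[bed].R_dist *= mu["r_pulmonary"]
    sh = c.leader.branches["shunt"]
    sh.R *= mu["shunt_loss"]
    sh.k *= mu["shunt_loss"]
    c.lpm.heart.E_max *= mu["e_max"]
    ini = c.lpm.initial
    s = mu["volume"]
    ini.V_sv *= s
    ini.V_a *= s
    for f in ("P_aortic_root", "P_innominate", "P_l_carotid", "P_l_subclavian",
              "P_dao", "P_lpa", "P_rpa", "P_venous_systemic", "P_venous_pulmonary"):
        setattr(ini, f, getattr(ini, f) * s)
    return c


@dataclass
class TuningResult:
    config: RunConfig
    multipliers: Dict[str, float]
    differences: Dict[str, float]  # percent, unrounded
    achieved: Dict[str, float]     # final-cycle averages of the tuned model
    max_difference: float
    evaluations: int
    converged: bool


def _objective(averages: Dict[str, float], targets: ClinicalTargets) -> Dict[str, float]:
    tgt = targets.as_dict()
    return {k: percent_difference(averages[k], tgt[k], ndigits=None) for k in tgt}


def tune_parameters(
    cfg: RunConfig,
    targets: ClinicalTargets,
    budget: int = 200,
    threshold: float = 10.0,
    stop_tol: float = 3.0,
    evaluate: Optional[Callable[[RunConfig], Dict[str, float]]] = None,
) -> TuningResult:
    """Coordinate descent on log-multipliers minimizing the worst percent
    difference across the seven targets.

    ``budget`` bounds the number of coupled-model evaluations; ``threshold``
    defines success (max difference below it); descent stops early once the
    objective drops under ``stop_tol``.  ``evaluate`` defaults to running
    the coupled model and reading its final-cycle averages.
    """
    if budget < 1:
        raise ConfigurationError("tuning budget must be at least 1 evaluation")
    if evaluate is None:
        evaluate = lambda c: run_coupled(c).final_cycle_averages()

    cache: Dict[Tuple[float, ...], Tuple[float, float, Dict[str, float], Dict[str, float]]] = {}
    evals = 0

    def key(m: Dict[str, float]) -> Tuple[float, ...]:
        return tuple(m[k] for k in TUNABLE_PARAMETERS)

    def measure(m: Dict[str, float]):
        nonlocal evals
        k = key(m)
        if k in cache:
            return cache[k]
        if evals >= budget:
            return None
        evals += 1
        averages = evaluate(apply_multipliers(cfg, m))
        diffs = _objective(averages, targets)
        worst = max(diffs.values())
        # descent score: the max-norm objective plus a small mean term that
        # breaks the plateaus a pure max-norm creates for coordinate moves
        score = worst + 0.05 * sum(diffs.values()) / len(diffs)
        out = (score, worst, diffs, averages)
        cache[k] = out
        return out

    best_m = {k: 1.0 for k in TUNABLE_PARAMETERS}
    best = measure(best_m)
    assert best is not None
    step = 1.3
    while evals < budget and best[1] > stop_tol and step > 1.02:
        improved = False
        for name in TUNABLE_PARAMETERS:
            if best[1] <= stop_tol or evals >= budget:
                break
            for factor in (step, 1.0 / step):
                cand_m = dict(best_m)
                cand_m[name] = best_m[name] * factor
                cand = measure(cand_m)
                if cand is None:
                    break
                if cand[0] < best[0] - 1e-12:
                    best, best_m = cand, cand_m
                    improved = True
                    # keep moving along the improving direction
                    while evals < budget and best[1] > stop_tol:
                        cand_m = dict(best_m)
                        cand_m[name] = best_m[name] * factor
                        cand = measure(cand_m)
                        if cand is None or not cand[0] < best[0] - 1e-12:
                            break
                        best, best_m = cand, cand_m
                    break
        if not improved:
            step = math.sqrt(step)
    _, max_diff, diffs, achieved = best
    converged = max_diff < threshold
    if not converged:
        log.warning("tuning exhausted budget at max difference %.2f%% (threshold %.1f%%)",
                    max_diff, threshold)
    return TuningResult(
        config=apply_multipliers(cfg, best_m),
        multipliers=best_m,
        differences=diffs,
        achieved=achieved,
        max_difference=max_diff,
        evaluations=evals,
        converged=converged,
    )
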