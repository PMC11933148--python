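"""Result serialization: per-signal CSVs, exchange log, JSON summary."""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List

import numpy as np
import yaml

from .config import BOUNDARIES
from .driver import SimulationResult
from .errors import ConfigurationError
from .metrics import ClinicalTargets, WaveformSeries

__all__ = ["write_results", "read_signal_csv", "load_targets", "save_targets"]

_FMT = "%.17g"  # text round-trips IEEE doubles exactly


def write_results(res: SimulationResult, out_dir) -> Dict[str, List[str]]:
    """Write one CSV per monitored signal, the exchange log, and a JSON
    summary.  Returns a manifest of the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, List[str]] = {"signals": [], "exchange": [], "summary": []}

    for name, w in res.waveforms.items():
        p = out / f"{name}.csv"
        with open(p, "w", newline="", encoding="utf-8") as fh:
            wr = csv.writer(fh)
            wr.writerow(["t_s", "value", "cycle"])
            cyc = w.cycle_index if w.cycle_index is not None else np.zeros(len(w), dtype=int)
            for t, y, c in zip(w.t, w.y, cyc):
                wr.writerow([_FMT % t, _FMT % y, int(c)])
        manifest["signals"].append(str(p))

    p = out / "exchange_log.csv"
    with open(p, "w", newline="", encoding="utf-8") as fh:
        wr = csv.writer(fh)
        header = ["t_s", "dt_s", "n_substeps", "h_substep_s", "residual", "iterations"]
        header += [f"Q_{b}" for b in BOUNDARIES] + [f"P_{b}" for b in BOUNDARIES]
        wr.writerow(header)
        for e in res.exchanges:
            row = [_FMT % e.t, _FMT % e.dt, e.n_substeps, _FMT % e.h_substep,
                   _FMT % e.residual, e.iterations]
            row += [_FMT % q for q in e.Q] + [_FMT % pp for pp in e.P]
            wr.writerow(row)
    manifest["exchange"].append(str(p))

    summary = {
        "cycles_completed": res.cycles_completed,
        "final_cycle_window": list(res.final_cycle_window),
        "final_cycle_averages": res.final_cycle_averages(),
        "volume_drift_percent": res.volume_drift_percent,
        "dt_statistics": res.dt_statistics(),
        "seed": res.config.seed,
    }
    p = out / "summary.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    manifest["summary"].append(str(p))
    return manifest


def read_signal_csv(path) -> WaveformSeries:
    """Reload a signal CSV written by :func:`write_results`."""
    t: List[float] = []
    y: List[float] = []
    cyc: List[int] = []
    with open(path, newline="", encoding="utf-8") as fh:
        rd = csv.reader(fh)
        header = next(rd)
        if header[:2] != ["t_s", "value"]:
            raise ConfigurationError(f"{path} is not a cardiocosim signal CSV")
        for row in rd:
            t.append(float(row[0]))
            y.append(float(row[1]))
            cyc.append(int(row[2]))
    return WaveformSeries(np.array(t), np.array(y), cycle_index=np.array(cyc))


def load_targets(path) -> ClinicalTargets:
    """Load a clinical-targets YAML (keys CO, Q_UB, Q_DAO, Q_SH, Qp_Qs,
    P_AO, P_PUL)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"targets file {path} must be a mapping")
    try:
        return ClinicalTargets(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad targets file {path}: {exc}") from exc


def shipped_targets() -> ClinicalTargets:
    """Example clinical targets for a Norwood neonate, shipped as data."""
    from importlib.resources import files

    raw = yaml.safe_load(
        files("cardiocosim").joinpath("data/clinical_targets.yaml").read_text(encoding="utf-8")
    )
    return ClinicalTargets(**raw)


def save_targets(t: ClinicalTargets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(t.as_dict(), fh, sort_keys=False)
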