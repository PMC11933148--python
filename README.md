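# cardiocosim

Co-simulation of a univentricular (Norwood, modified Blalock–Taussig
shunt) circulation: a closed-loop lumped-parameter model (LPM) of the
heart and vascular beds is packaged as an FMI-2.0-style co-simulation
*follower* and driven, one macro timestep at a time, by a *leader*
subsystem — a 0D surrogate of the aortic arch / shunt region standing
where a 3D CFD model would sit — with boundary pressures and flows
exchanged at every step.

The package is for researchers in computational hemodynamics who want a
desk-scale, fully testable implementation of the leader/follower coupling
pattern used in multiscale cardiovascular modeling: the follower owns its
own solver (classical RK4 with the macro step subdivided into equal
substeps of at most 100 µs), the leader owns the macro clock (adaptive,
10 µs–2 ms), and the two communicate only through a typed variable
registry (set-input / do-step / read-output), exactly as an FMU does.

## Model

- **Follower** (`lpm`, `cosim`): time-varying-elastance single ventricle
  P = E(t)·(V − V0) with a double-cosine activation; passive common
  atrium; AV and aortic diode valves; three-element Windkessel beds behind
  six return boundaries (innominate, left carotid, left subclavian,
  descending aorta, left/right pulmonary arteries); systemic and pulmonary
  venous compliances returning to the atrium. 11 states, volume-conserving
  by construction. Packageable as a zip archive with
  `modelDescription.xml` (FMI 2.0 layout) plus its configuration in
  `resources/`, with an in-repo structural compliance checker.
- **Leader** (`leader`): nine inertial branches
  dQ/dt = (ΔP − R·Q − k·Q·|Q|)/L joined at rigid junctions (arch,
  innominate take-off, pulmonary bifurcation; the shunt carries the
  quadratic loss), advanced by backward Euler with Newton relinearization
  and an exact junction-balance solve each sweep.
- **Coupling** (`driver`): explicit staggered exchange, leader first;
  default 8 cardiac cycles; final-cycle averages reported for CO, Q_UB,
  Q_DAO, Q_SH, Qp/Qs = Q_SH/(Q_UB + Q_DAO), P_AO, P_PUL. A monolithic
  merged-ODE oracle (`run_monolithic_oracle`) verifies the splitting.
- **Analytics & tuning** (`metrics`, `tuning`): trapezoidal cycle
  averages, percent differences (table convention, 1 d.p.),
  range-normalized RMSE, PV-loop stroke volume / stroke work, and a
  deterministic coordinate-descent tuner that drives the model toward
  measured cycle-averaged targets.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```sh
cardio-cosim fixtures --out example          # writes config + targets
cardio-cosim run --config example/norwood_default.yaml --out example/run
```

The run writes one CSV per signal, the exchange log, and `summary.json`,
and prints (abridged):

```json
{
  "final_cycle_averages": {
    "CO": 22.192, "Q_UB": 5.981, "Q_DAO": 6.088, "Q_SH": 10.124,
    "Qp_Qs": 0.839, "P_AO": 57.813, "P_PUL": 13.115
  },
  "volume_drift_percent": 5.8e-13
}
```

i.e. the untuned default circulation ejects ≈22 mL/s, splits it roughly
evenly between the shunt (10.1 mL/s) and the systemic beds
(6.0 + 6.1 mL/s), holds a mean aortic pressure of ≈58 mmHg and a mean
pulmonary pressure of ≈13 mmHg, and conserves blood volume to roundoff
over the 8 cycles. Tuning against the shipped example targets
(a Norwood neonate: CO 21 mL/s, Q_UB 5.6, Q_DAO 5.7, Q_SH 9.7 mL/s,
Qp/Qs 0.9, P_AO 52 mmHg, P_PUL 12 mmHg):

```sh
cardio-cosim tune --targets example/clinical_targets.yaml --out example/tuned.yaml
cardio-cosim run --config example/tuned.yaml --out example/tuned_run
cardio-cosim report --results example/tuned_run --targets example/clinical_targets.yaml
```

brings every percent difference below 3%:

```
Parameter Units    Clinical     Model  Diff %
CO        mL/s        21.00     20.78     1.1
Q_UB      mL/s         5.60      5.48     2.1
Q_DAO     mL/s         5.70      5.58     2.1
Q_SH      mL/s         9.70      9.71     0.1
Qp_Qs     -            0.90      0.88     2.5
P_AO      mmHg        52.00     53.42     2.7
P_PUL     mmHg        12.00     11.83     1.4
```

`cardio-cosim package-fmu norwood.fmu` exports the follower archive and
`cardio-cosim check-fmu norwood.fmu` validates its structure.

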