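# Methods

`cardiocosim` simulates the stage-1 palliated (Norwood, modified
Blalock–Taussig shunt) single-ventricle circulation as two coupled
subsystems exchanging boundary data once per macro timestep, the way a 3D
CFD solver and a lumped-parameter model (LPM) are coupled in multiscale
hemodynamics. This note documents the models, the numerical choices, and
what the shipped defaults do and do not represent.

## The follower: closed-loop lumped-parameter circulation

The LPM is a 0D circuit in mmHg / mL / s (resistance mmHg·s/mL, compliance
mL/mmHg, inertance mmHg·s²/mL):

- **Single ventricle** — time-varying elastance, P = E(t)·(V − V0). The
  normalized activation is a double cosine: it rises over [0, t_peak],
  falls over [t_peak, 1.5·t_peak], and is zero through diastole, giving a
  C¹ drive that is friendly to explicit integration. Defaults: T = 0.4 s
  (150 bpm, a typical neonatal rate), E_max = 14 mmHg/mL, E_min =
  0.22 mmHg/mL, t_peak = 0.12 s, V0 = 3 mL.
- **Atrium** — a single passive compliance chamber (C = 2 mL/mmHg)
  receiving both systemic and pulmonary venous return, as in the common
  mixing atrium of the univentricular circulation. No atrial elastance:
  atrial kick is a second-order effect at these heart rates and would add
  two unconstrained parameters.
- **Valves** — ideal diodes with forward resistance; an optional smooth
  regularization `eps` replaces the corner by
  Q = (ΔP + √(ΔP² + eps²))/(2R). The default is eps = 0: with ≤ 100 µs
  substeps the discontinuity in the derivative caused no observable
  artifacts, and the ideal diode keeps regurgitant flow exactly zero.
- **Vascular beds** — three-element Windkessels (R_prox, C, R_dist) behind
  each of the six return boundaries: innominate, left carotid, left
  subclavian (upper body), descending aorta (lower body), and left/right
  pulmonary arteries. Systemic beds drain into a systemic venous
  compliance, pulmonary beds into a pulmonary venous compliance; both
  return to the atrium. R_prox is algebraic (it shifts the exported
  interface pressure by R_prox·Q without adding a state).
- **Aortic root node** — a small compliance (0.08 mL/mmHg) between the
  aortic valve and the aortic-root boundary, from which the leader draws
  the arch inflow.

State vector: 2 chamber volumes + 9 node pressures = 11 states. Total
blood volume (chambers + C·P stored volume) is conserved by construction
up to the oriented sum of boundary flows; this is the main structural
invariant the tests exercise.

The topology is compiled once into flat index lists and then into a
generated straight-line derivative function (all parameters baked in as
literals). The generated function is bitwise-identical to the readable
loop implementation (`rhs_reference`), which the test suite asserts on
random states; the generation exists purely to keep a ~130k-evaluation
run cheap in pure Python.

## The leader: 0D surrogate of the arch/shunt domain

The region a CFD model would occupy — aortic arch, arch branches,
descending-aorta take-off, the 3.5 mm MBTS shunt and the proximal
pulmonary arteries — is a network of nine inertial branches
(dQ/dt = (ΔP − R·Q − k·Q·|Q|)/L) joined at three rigid internal junctions
(arch, innominate take-off, pulmonary bifurcation). The quadratic
coefficient k concentrates the shunt's nonlinear pressure loss; all
coefficients are tunable parameters, not derived from geometry. The
surrogate honors exactly the interface a CFD code would: pressures in,
flows out, its own internal solver, its own adaptive macro step — so a 3D
solver could replace this module behind the same contract.

Each macro step is advanced by backward Euler with Newton relinearization
of the quadratic loss; junction pressures are re-solved every sweep (3×3
Gaussian elimination) so net junction flow vanishes. "Sufficient
stability" per step is defined as a relative junction residual below 1e−5
(scale: mean branch-flow magnitude with a 1e−6 mL/s floor), iteration cap
50; in practice Newton converges in 1–2 sweeps. The step controller
shrinks dt (factor ≥ 0.5) when a forward-Euler/backward-Euler local error
estimate exceeds `error_tol` (default 2e−3, relative to max flow) and
grows it (factor ≤ 2) below `error_tol`/4, clamped to [10 µs, 2 ms].

## Coupling protocol

Explicit staggered (Gauss–Seidel) exchange, leader first: the leader
advances under the last exported follower pressures, its boundary flows
are written to the follower's inputs, the follower's do-step subdivides
the macro step into equal RK4 substeps of at most h_max = 100 µs
(n = ceil(Δt/h_max), zero-order input hold by default; a first-order hold
is available via `coupling.input_hold: first`), and the refreshed follower
pressures are held for the next leader step. An optional inner repetition
of the exchange (`coupling.exchange_iterations`) tightens the coupling;
the default (1) matches the serial exchange-once-per-step scheme.
Initialization solves the leader's steady network under the follower's
initial pressures so the first exchange is consistent and cycle 1 is not
polluted by an impulsive start.

The follower is also packageable as an FMI-2.0-style co-simulation
archive: `modelDescription.xml` (FMI version, guid, CoSimulation element,
full variable registry with causalities, units and starts) plus the model
configuration under `resources/`. Packaging is source-based — the model
and its RK4 solver are reconstructed from the archive by this framework —
not a compiled C binary; the structural checker (`check_fmu`) validates
the layout an external FMI tool would inspect.

## Verification

- **Windkessel fixture** — a three-element Windkessel under a half-sine
  inflow has a closed-form periodic response; RK4 at the shipped substep
  matches it to < 0.1%.
- **Monolithic oracle** — follower and leader merged into one 20-state ODE
  (junction pressures eliminated algebraically) and integrated by a single
  RK4 at h ≤ 100 µs. The co-simulated run agrees with it to < 2%
  range-normalized RMSE on every boundary waveform at a 100 µs macro cap,
  with the mismatch non-increasing as the cap halves — the splitting error
  of the staggered exchange is first order in the macro step.
- **Conservation** — total blood volume drifts < 0.5% over 8 cycles in the
  coupled run (in practice ~1e−13: the leader's junction solve returns
  flows whose oriented sum is zero, so the follower integrates a
  conservative input).
- **Periodicity** — cycle 7 vs cycle 8 waveforms differ by < 1%
  range-normalized RMSE for all boundary signals (≈ 0.02% in practice), so
  the 8th cycle used for reporting is at periodic steady state.

## Tuning and reported quantities

A run reports final-cycle averages: CO (aortic-root flow), Q_UB (sum of
the three upper-body boundary flows), Q_DAO, Q_SH (shunt branch flow),
Qp/Qs = Q_SH/(Q_UB + Q_DAO), P_AO (mean aortic-root boundary pressure) and
P_PUL (mean pulmonary-junction pressure). The Qp/Qs denominator and the
measurement sites are documented conventions chosen for internal
consistency (CO ≈ Q_UB + Q_DAO + Q_SH holds by junction balance).

`tune_parameters` is a deterministic coordinate descent on the logarithm
of seven multipliers — total systemic resistance, upper-body distal
resistance, descending-aorta distal resistance, pulmonary distal
resistance, shunt loss (R and k together), E_max, and circulating volume
(initial volumes/pressures scaled together). The joint systemic knob
exists alongside the two distribution knobs because the worst-case
objective has valleys along the "raise/lower total SVR" diagonal that
axis-aligned moves cannot descend. The objective is the worst absolute
percent difference across the seven targets; internally candidates are
ranked by that maximum plus 0.05× the mean difference, a small smoothing
term that breaks the plateaus a pure max-norm creates for coordinate
moves (the reported quantity remains the plain maximum). The step factor
starts at 1.3 and shrinks when a sweep yields no improvement; descent
stops at a documented tolerance (default 3%), on convergence of the step
factor, or when the evaluation budget (default 200 runs) is exhausted.
Starting from the shipped defaults it reaches ≈ 2.7% maximum difference
against the example clinical targets in a few dozen evaluations.

## What the defaults represent — and what they do not

The shipped parameters describe a generic ~3.5 kg Norwood/MBTS neonate
(mean aortic pressure ≈ 50 mmHg, Qp/Qs ≈ 0.9, CO ≈ 21 mL/s). They are a
plausible operating point for exercising the coupling method, not a
patient: there is no baroreflex or autoregulation, no respiratory
modulation, no oxygen transport, no vessel-wall mechanics, and the leader
is a lumped surrogate rather than a flow-resolving model — so passing
tests validate the coupling protocol, solvers and analytics, not
patient-specific hemodynamic prediction. Problem sizes used throughout
(8 cycles of a 0.4 s period, ≤ 200 tuning evaluations) keep a full
verification run in the minutes range on one core.

## Degenerate inputs and tie-breaks

Zero-amplitude elastance with uniform pressures is an exact fixed point
(flows identically zero; the relative junction residual is defined with a
1e−6 mL/s floor precisely so that this state is recognized as converged).
A branch with R = k = 0 has no steady solution and is rejected.
`steady_flow_solve` uses the rationalized quadratic root, stable as
k → 0. Macro steps that are exact multiples of h_max are protected by a
relative guard in the ceiling rule so roundoff cannot add a spurious
substep. The do-step clock tolerance is 1e−12 s; accumulated leader time
and follower clock advance by identical additions, so the comparison is
exact in practice.
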