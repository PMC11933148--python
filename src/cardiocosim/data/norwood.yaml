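lpm:
  heart:
    T: 0.4
    E_max: 14.0
    E_min: 0.22
    t_peak: 0.12
    V0: 3.0
  atrium:
    C: 2.0
    V0: 2.0
  av_valve:
    R_open: 0.012
    eps: 0.0
  aortic_valve:
    R_open: 0.03
    eps: 0.0
  aortic_root_C: 0.08
  beds:
    innominate:
      R_prox: 0.05
      C: 0.03
      R_dist: 19.0
    l_carotid:
      R_prox: 0.08
      C: 0.02
      R_dist: 31.0
    l_subclavian:
      R_prox: 0.08
      C: 0.02
      R_dist: 31.0
    dao:
      R_prox: 0.04
      C: 0.1
      R_dist: 8.4
    lpa:
      R_prox: 0.03
      C: 0.05
      R_dist: 1.65
    rpa:
      R_prox: 0.03
      C: 0.05
      R_dist: 1.65
  venous_systemic:
    C: 3.5
    R_return: 0.09
  venous_pulmonary:
    C: 1.8
    R_return: 0.1
  h_max_us: 100.0
  initial:
    V_sv: 16.0
    V_a: 8.5
    P_aortic_root: 52.0
    P_innominate: 50.0
    P_l_carotid: 50.0
    P_l_subclavian: 50.0
    P_dao: 50.0
    P_lpa: 12.0
    P_rpa: 12.0
    P_venous_systemic: 4.0
    P_venous_pulmonary: 4.5
leader:
  branches:
    aortic_root:
      R: 0.08
      L: 0.0003
      k: 0.0
    brachiocephalic:
      R: 0.05
      L: 0.0002
      k: 0.0
    innominate:
      R: 0.05
      L: 0.0002
      k: 0.0
    l_carotid:
      R: 0.15
      L: 0.0003
      k: 0.0
    l_subclavian:
      R: 0.15
      L: 0.0003
      k: 0.0
    dao:
      R: 0.05
      L: 0.0002
      k: 0.0
    shunt:
      R: 1.0
      L: 0.0005
      k: 0.31
    lpa:
      R: 0.05
      L: 0.0002
      k: 0.0
    rpa:
      R: 0.05
      L: 0.0002
      k: 0.0
  dt_min_us: 10.0
  dt_max_us: 2000.0
  residual_tol: 1.0e-05
  max_iterations: 50
  error_tol: 0.002
coupling:
  n_cycles: 8
  exchange_iterations: 1
  input_hold: zero
monitors:
- P_ventricle
- V_ventricle
- P_atrium
- Q_shunt
- P_pulmonary
- P_arch
seed: 0
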