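geometry:
  vessels:
  - name: CFA
    radius: 0.004
    length: 0.02
    angle_deg: 0.0
  - name: SFA
    radius: 0.003
    length: 0.028
    angle_deg: 12.0
  - name: DFA
    radius: 0.0025
    length: 0.016
    angle_deg: -40.0
  wall_segments:
    CFA:
    - CFA
    - 0.0
    - 0.02
    proximal SFA:
    - SFA
    - 0.003
    - 0.02
    distal SFA:
    - SFA
    - 0.02
    - 0.028
    DFA:
    - DFA
    - 0.0
    - 0.016
waveforms:
  T: 1.0
  n_samples: 200
  CFA:
    psv: 0.9
    reverse_fraction: 0.3
    phase: triphasic
  SFA:
    psv: 0.7
    reverse_fraction: 0.3
    phase: triphasic
  DFA:
    psv: 0.8
    reverse_fraction: 0.25
    phase: triphasic
fluid:
  rho: 1060.0
  mu: 0.0035
windkessel:
  mode: tune
  mean_pressure_mmhg: 100.0
  tolerance: 0.05
solver:
  resolution: 0.0005
  dt: 0.001
  cycles_max: 8
  periodicity_tol: 0.04
  backflow_beta: 0.2
  cfl_target: 0.45
  n_store: 200
thresholds:
- 0.4
- 0.15
- 0.05
seed: 1
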