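profiles:
- sex: male
  diet: ethanol
  n_animals: 8
  plateau_mean: 0.6593
  plateau_sd: 0.0591
  tau_hours: 72.0
  anchors:
    pv_flow:
    - - -24.0
      - 0.9
      - 0.25
    - - 0.0
      - 1.41
      - 0.3
    - - 10.0
      - 1.92
      - 0.44
    - - 96.0
      - 1.41
      - 0.3
    - - 168.0
      - 0.9
      - 0.25
    - - 336.0
      - 0.9
      - 0.25
    ha_flow:
    - - -24.0
      - 0.12
      - 0.04
    - - 10.0
      - 0.2
      - 0.06
    - - 96.0
      - 0.15
      - 0.05
    - - 168.0
      - 0.12
      - 0.04
    - - 336.0
      - 0.12
      - 0.04
    stiffness:
    - - -24.0
      - 1.75
      - 0.06
    - - 10.0
      - 2.07
      - 0.15
    - - 96.0
      - 1.9449999999999998
      - 0.15
    - - 168.0
      - 1.82
      - 0.1
    - - 336.0
      - 1.82
      - 0.1
    spo2:
    - - -24.0
      - 57.0
      - 3.0
    - - 0.0
      - 54.0
      - 3.0
    - - 48.0
      - 53.53
      - 3.26
    - - 72.0
      - 55.08
      - 2.65
    - - 168.0
      - 55.42
      - 1.78
    - - 336.0
      - 55.42
      - 1.78
    body_mass_g:
    - - -24.0
      - 420.0
      - 25.0
    - - 24.0
      - 399.0
      - 25.0
    - - 336.0
      - 441.0
      - 25.0
- sex: male
  diet: control
  n_animals: 8
  plateau_mean: 0.9004
  plateau_sd: 0.0868
  tau_hours: 48.0
  anchors:
    pv_flow:
    - - -24.0
      - 0.9
      - 0.25
    - - 0.0
      - 1.105
      - 0.3
    - - 10.0
      - 1.31
      - 0.22
    - - 96.0
      - 1.105
      - 0.3
    - - 168.0
      - 0.9
      - 0.25
    - - 336.0
      - 0.9
      - 0.25
    ha_flow:
    - - -24.0
      - 0.12
      - 0.04
    - - 10.0
      - 0.2
      - 0.06
    - - 96.0
      - 0.15
      - 0.05
    - - 168.0
      - 0.12
      - 0.04
    - - 336.0
      - 0.12
      - 0.04
    stiffness:
    - - -24.0
      - 1.75
      - 0.08
    - - 10.0
      - 2.07
      - 0.15
    - - 96.0
      - 1.9449999999999998
      - 0.15
    - - 168.0
      - 1.82
      - 0.1
    - - 336.0
      - 1.82
      - 0.1
    spo2:
    - - -24.0
      - 57.0
      - 3.0
    - - 0.0
      - 54.0
      - 3.0
    - - 48.0
      - 55.91
      - 1.57
    - - 72.0
      - 57.0
      - 2.5
    - - 168.0
      - 57.0
      - 2.5
    - - 336.0
      - 57.0
      - 2.5
    body_mass_g:
    - - -24.0
      - 420.0
      - 25.0
    - - 24.0
      - 399.0
      - 25.0
    - - 336.0
      - 441.0
      - 25.0
- sex: female
  diet: ethanol
  n_animals: 7
  plateau_mean: 0.9713
  plateau_sd: 0.0837
  tau_hours: 48.0
  anchors:
    pv_flow:
    - - -24.0
      - 0.9
      - 0.25
    - - 0.0
      - 1.4949999999999999
      - 0.3
    - - 10.0
      - 2.09
      - 0.48
    - - 96.0
      - 1.4949999999999999
      - 0.3
    - - 168.0
      - 0.9
      - 0.25
    - - 336.0
      - 0.9
      - 0.25
    ha_flow:
    - - -24.0
      - 0.12
      - 0.04
    - - 10.0
      - 0.2
      - 0.06
    - - 96.0
      - 0.15
      - 0.05
    - - 168.0
      - 0.12
      - 0.04
    - - 336.0
      - 0.12
      - 0.04
    stiffness:
    - - -24.0
      - 1.93
      - 0.09
    - - 10.0
      - 2.35
      - 0.04
    - - 96.0
      - 2.215
      - 0.04
    - - 168.0
      - 2.08
      - 0.18
    - - 336.0
      - 2.08
      - 0.18
    spo2:
    - - -24.0
      - 57.0
      - 3.0
    - - 0.0
      - 54.0
      - 3.0
    - - 48.0
      - 56.0
      - 2.5
    - - 72.0
      - 58.34
      - 2.06
    - - 168.0
      - 59.74
      - 1.7
    - - 336.0
      - 59.74
      - 1.7
    body_mass_g:
    - - -24.0
      - 270.0
      - 20.0
    - - 24.0
      - 256.5
      - 20.0
    - - 336.0
      - 283.5
      - 20.0
- sex: female
  diet: control
  n_animals: 7
  plateau_mean: 0.9154
  plateau_sd: 0.1039
  tau_hours: 48.0
  anchors:
    pv_flow:
    - - -24.0
      - 0.9
      - 0.25
    - - 0.0
      - 1.585
      - 0.3
    - - 10.0
      - 2.27
      - 0.16
    - - 96.0
      - 1.585
      - 0.3
    - - 168.0
      - 0.9
      - 0.25
    - - 336.0
      - 0.9
      - 0.25
    ha_flow:
    - - -24.0
      - 0.12
      - 0.04
    - - 10.0
      - 0.2
      - 0.06
    - - 96.0
      - 0.15
      - 0.05
    - - 168.0
      - 0.12
      - 0.04
    - - 336.0
      - 0.12
      - 0.04
    stiffness:
    - - -24.0
      - 1.93
      - 0.09
    - - 10.0
      - 2.35
      - 0.08
    - - 96.0
      - 2.215
      - 0.08
    - - 168.0
      - 2.08
      - 0.18
    - - 336.0
      - 2.08
      - 0.18
    spo2:
    - - -24.0
      - 57.0
      - 3.0
    - - 0.0
      - 54.0
      - 3.0
    - - 48.0
      - 56.0
      - 2.5
    - - 72.0
      - 57.0
      - 2.5
    - - 168.0
      - 57.0
      - 2.5
    - - 336.0
      - 57.0
      - 2.5
    body_mass_g:
    - - -24.0
      - 270.0
      - 20.0
    - - 24.0
      - 256.5
      - 20.0
    - - 336.0
      - 283.5
      - 20.0
- sex: male
  diet: chow
  n_animals: 7
  plateau_mean: 0.95
  plateau_sd: 0.09
  tau_hours: 48.0
  anchors:
    pv_flow:
    - - -24.0
      - 0.9
      - 0.25
    - - 0.0
      - 1.105
      - 0.3
    - - 10.0
      - 1.31
      - 0.22
    - - 96.0
      - 1.105
      - 0.3
    - - 168.0
      - 0.9
      - 0.25
    - - 336.0
      - 0.9
      - 0.25
    ha_flow:
    - - -24.0
      - 0.12
      - 0.04
    - - 10.0
      - 0.2
      - 0.06
    - - 96.0
      - 0.15
      - 0.05
    - - 168.0
      - 0.12
      - 0.04
    - - 336.0
      - 0.12
      - 0.04
    stiffness:
    - - -24.0
      - 1.75
      - 0.08
    - - 10.0
      - 2.07
      - 0.15
    - - 96.0
      - 1.9449999999999998
      - 0.15
    - - 168.0
      - 1.82
      - 0.1
    - - 336.0
      - 1.82
      - 0.1
    spo2:
    - - -24.0
      - 57.0
      - 3.0
    - - 0.0
      - 54.0
      - 3.0
    - - 48.0
      - 55.91
      - 1.57
    - - 72.0
      - 57.0
      - 2.5
    - - 168.0
      - 57.0
      - 2.5
    - - 336.0
      - 57.0
      - 2.5
    body_mass_g:
    - - -24.0
      - 420.0
      - 25.0
    - - 24.0
      - 399.0
      - 25.0
    - - 336.0
      - 441.0
      - 25.0
- sex: female
  diet: chow
  n_animals: 6
  plateau_mean: 0.95
  plateau_sd: 0.09
  tau_hours: 48.0
  anchors:
    pv_flow:
    - - -24.0
      - 0.9
      - 0.25
    - - 0.0
      - 1.585
      - 0.3
    - - 10.0
      - 2.27
      - 0.16
    - - 96.0
      - 1.585
      - 0.3
    - - 168.0
      - 0.9
      - 0.25
    - - 336.0
      - 0.9
      - 0.25
    ha_flow:
    - - -24.0
      - 0.12
      - 0.04
    - - 10.0
      - 0.2
      - 0.06
    - - 96.0
      - 0.15
      - 0.05
    - - 168.0
      - 0.12
      - 0.04
    - - 336.0
      - 0.12
      - 0.04
    stiffness:
    - - -24.0
      - 1.93
      - 0.09
    - - 10.0
      - 2.35
      - 0.08
    - - 96.0
      - 2.215
      - 0.08
    - - 168.0
      - 2.08
      - 0.18
    - - 336.0
      - 2.08
      - 0.18
    spo2:
    - - -24.0
      - 57.0
      - 3.0
    - - 0.0
      - 54.0
      - 3.0
    - - 48.0
      - 56.0
      - 2.5
    - - 72.0
      - 57.0
      - 2.5
    - - 168.0
      - 57.0
      - 2.5
    - - 336.0
      - 57.0
      - 2.5
    body_mass_g:
    - - -24.0
      - 270.0
      - 20.0
    - - 24.0
      - 256.5
      - 20.0
    - - 336.0
      - 283.5
      - 20.0
times:
- -24.0
- 0.0
- 10.0
- 24.0
- 48.0
- 72.0
- 96.0
- 168.0
- 336.0
noise_sd: 0.03
missingness:
  rel_volume: 0.08
  body_mass_g: 0.05
  pv_flow: 0.15
  ha_flow: 0.3
  stiffness: 0.15
  spo2: 0.15
min_measurements: 5
enforce_eligibility: true
seed: 0
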