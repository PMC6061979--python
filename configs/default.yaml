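geometry:
  length: 200.0
  diameter: 6.0
  cm: 1.0
  rm: 138.0
  ri: 183.0
channels:
- name: CaT
  gmax: 0.0002
  erev: 51.0
  activation:
    half_potential: 31.796527
    slope: -1.150307
    tau:
      tau0: 0.506036
      amp: 0.0
      vmid: 0.0
      sigma: 10.0
    exponent: 1
  inactivation:
    half_potential: 38.0
    slope: 8.0
    tau:
      tau0: 5.136704
      amp: 12.17166
      vmid: 45.0
      sigma: 10.0
    exponent: 1
  ca_dependence: null
  ligand_dependence: null
  is_calcium_carrier: true
- name: CaL
  gmax: 0.0004
  erev: 51.0
  activation:
    half_potential: 19.44
    slope: -2.0
    tau:
      tau0: 2.080114
      amp: 0.0
      vmid: 0.0
      sigma: 10.0
    exponent: 1
  inactivation:
    half_potential: 23.392257
    slope: 5.897555
    tau:
      tau0: 70.0
      amp: 0.0
      vmid: 0.0
      sigma: 10.0
    exponent: 1
  ca_dependence: null
  ligand_dependence: null
  is_calcium_carrier: true
- name: Kv1
  gmax: 0.006
  erev: -75.0
  activation:
    half_potential: -31.771468
    slope: -4.361049
    tau:
      tau0: 5.099912
      amp: 4.801678
      vmid: 30.0
      sigma: 15.648
    exponent: 1
  inactivation:
    half_potential: 20.0
    slope: 6.0
    tau:
      tau0: 3000.0
      amp: 0.0
      vmid: 0.0
      sigma: 10.0
    exponent: 1
  ca_dependence: null
  ligand_dependence: null
  is_calcium_carrier: false
- name: KCNQ
  gmax: 0.009
  erev: -75.0
  activation:
    half_potential: -250.379864
    slope: -57.002795
    tau:
      tau0: 6.814508
      amp: 0.0
      vmid: 0.0
      sigma: 10.0
    exponent: 1
  inactivation: null
  ca_dependence: null
  ligand_dependence: null
  is_calcium_carrier: false
- name: IK
  gmax: 0.007
  erev: -75.0
  activation:
    half_potential: 200.0
    slope: -20.0
    tau:
      tau0: 30.0
      amp: 0.0
      vmid: 0.0
      sigma: 10.0
    exponent: 1
  inactivation: null
  ca_dependence:
    kd: 0.427514
    n: 2.0
  ligand_dependence: null
  is_calcium_carrier: false
- name: SK
  gmax: 0.01
  erev: -15.0
  activation:
    half_potential: 200.0
    slope: -20.0
    tau:
      tau0: 14.059271
      amp: 0.0
      vmid: 0.0
      sigma: 10.0
    exponent: 1
  inactivation: null
  ca_dependence:
    kd: 0.239021
    n: 2.0
  ligand_dependence:
    kind: apamin_block
    half: 1.0e-07
    n: 1.0
    concentration: 0.0
  is_calcium_carrier: false
- name: KATP
  gmax: 0.001
  erev: -21.0
  activation:
    half_potential: 0.0
    slope: -1.0
    tau:
      tau0: 1.0
      amp: 0.0
      vmid: 0.0
      sigma: 10.0
    exponent: 0
  inactivation: null
  ca_dependence: null
  ligand_dependence:
    kind: atp_inhibition
    half: 0.01995
    n: 1.0
    concentration: 0.0
  is_calcium_carrier: false
- name: Ih
  gmax: 0.0001
  erev: -40.0
  activation:
    half_potential: 57.164262
    slope: 4.160753
    tau:
      tau0: 30.856667
      amp: 0.0
      vmid: 0.0
      sigma: 10.0
    exponent: 1
  inactivation: null
  ca_dependence: null
  ligand_dependence: null
  is_calcium_carrier: false
bk:
  gmax: 0.024
  erev: -75.0
  kon: 134.52811
  kd_closed: 0.021357
  kd_open: 0.00928
  a0: 0.004022
  l0: 0.004202
  forward_frac: 0.7
  za: 0.323292
  zb: 0.228021
  vslope: 25.0
  kc4: 0.023203
  include_o0: false
leak_gmax: 7.25e-06
leak_erev: 17.135717
calcium:
  depth: 0.1
  baseline: 0.00015
  tau_removal: 2.38606
  floor: 1.0e-06
  ca_out: 2.0
  dynamic_eca: false
  e_ca_fixed: 51.0
temperature: 37.0
atp: 1.0
apamin: 0.0
v_init: -50.0
solver:
  dt: 0.02
  method: euler
provenance:
  CaT.gmax: source-cited
  CaL.gmax: source-cited
  Kv1.gmax: source-cited
  KCNQ.gmax: source-cited
  IK.gmax: source-cited
  SK.gmax: source-cited
  KATP.gmax: source-cited
  Ih.gmax: source-cited
  CaT.erev: source-cited
  CaL.erev: source-cited
  Kv1.erev: source-cited
  KCNQ.erev: source-cited
  IK.erev: source-cited
  SK.erev: source-cited
  KATP.erev: source-cited
  Ih.erev: source-cited
  BK.gmax: source-cited
  BK.erev: source-cited
  BK.rates: calibrated
  geometry: source-cited
  calcium.baseline: source-cited
  calcium.depth: source-cited
  calcium.tau_removal: calibrated
  leak: calibrated
  Kv1.inactivation.tau: calibrated
  KATP.atp_half: calibrated
  CaT.kinetics: calibrated
  CaL.kinetics: calibrated
  Kv1.kinetics: calibrated
  KCNQ.kinetics: calibrated
  IK.kinetics: calibrated
  SK.kinetics: calibrated
  KATP.kinetics: calibrated
  Ih.kinetics: calibrated
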