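# Channel parameter set for the reduced MSN model.
#
# Boltzmann half-activations (vh, mV), slopes (k, mV; negative k =
# inactivation), time constants (ms; scalar = fixed, {v:..., tau:...} =
# piecewise-linear V->tau lookup), maximal conductances (gbar, S/cm^2) per
# region, and the modified-inactivation coefficient a (1 = plain HH).
# Values are reconstructions grounded in the published MSN modeling
# literature; channels with distinct somatic and dendritic kinetics appear
# as separate table rows sharing a base channel name.

erev:
  na: 50.0
  k: -90.0
  ca: 130.0

channels:
  NaF_soma:
    channel: NaF
    erev: na
    x: 3
    y: 1
    a: 1.0
    gates:
      m: {vh: -23.9, k: 11.8, tau: 0.1}
      h:
        vh: -62.9
        k: -10.7
        tau:
          v: [-100.0, -80.0, -60.0, -50.0, -40.0, -30.0, -20.0, 0.0, 40.0]
          tau: [12.0, 10.0, 6.0, 3.0, 1.5, 1.0, 0.8, 0.6, 0.5]
    gbar: {soma: 1.5}
  NaF_dend:
    channel: NaF
    erev: na
    x: 3
    y: 1
    a: 1.0
    gates:
      m: {vh: -23.9, k: 11.8, tau: 0.1}
      h:
        vh: -62.9
        k: -10.7
        tau:
          v: [-100.0, -80.0, -60.0, -50.0, -40.0, -30.0, -20.0, 0.0, 40.0]
          tau: [12.0, 10.0, 6.0, 3.0, 1.5, 1.0, 0.8, 0.6, 0.5]
    gbar: {proximal: 0.0195, medial: 0.0195, distal: 0.0195}
  NaP_soma:
    channel: NaP
    erev: na
    x: 1
    y: 1
    a: 1.0
    gates:
      m: {vh: -52.6, k: 4.6, tau: 0.5}
      h: {vh: -48.8, k: -10.0, tau: 2000.0}
    gbar: {soma: 4.0e-5}
  NaP_dend:
    channel: NaP
    erev: na
    x: 1
    y: 1
    a: 1.0
    gates:
      m: {vh: -52.6, k: 4.6, tau: 0.5}
      h: {vh: -48.8, k: -10.0, tau: 2000.0}
    gbar: {proximal: 1.38e-7, medial: 1.38e-7, distal: 1.38e-7}
  KAf_prox:
    channel: KAf
    erev: k
    x: 2
    y: 1
    a: 1.0
    gates:
      m:
        vh: -10.0
        k: 17.7
        tau:
          v: [-100.0, -60.0, -40.0, -20.0, 0.0, 40.0]
          tau: [1.5, 1.2, 1.0, 0.8, 0.7, 0.6]
      h:
        vh: -75.6
        k: -10.0
        tau:
          v: [-100.0, -60.0, -40.0, -20.0, 0.0, 40.0]
          tau: [30.0, 25.0, 20.0, 15.0, 12.0, 10.0]
    gbar: {soma: 0.225, proximal: 0.225}
  KAf_dist:
    channel: KAf
    erev: k
    x: 2
    y: 1
    a: 1.0
    gates:
      m:
        vh: -10.0
        k: 17.7
        tau:
          v: [-100.0, -60.0, -40.0, -20.0, 0.0, 40.0]
          tau: [1.5, 1.2, 1.0, 0.8, 0.7, 0.6]
      h:
        vh: -75.6
        k: -10.0
        tau:
          v: [-100.0, -60.0, -40.0, -20.0, 0.0, 40.0]
          tau: [30.0, 25.0, 20.0, 15.0, 12.0, 10.0]
    gbar: {medial: 0.021, distal: 0.021}
  KAs_prox:
    channel: KAs
    erev: k
    x: 2
    y: 1
    a: 0.996
    gates:
      m: {vh: -27.0, k: 16.0, tau: 10.0}
      h: {vh: -33.5, k: -21.5, tau: 1000.0}
    gbar: {soma: 0.0104, proximal: 0.0104}
  KAs_dist:
    channel: KAs
    erev: k
    x: 2
    y: 1
    a: 0.996
    gates:
      m: {vh: -27.0, k: 16.0, tau: 10.0}
      h: {vh: -33.5, k: -21.5, tau: 1000.0}
    gbar: {medial: 0.00951, distal: 0.00951}
  KIR:
    channel: KIR
    erev: k
    x: 1
    y: 0
    a: 1.0
    gates:
      m:
        vh: -82.0
        k: -13.0
        tau:
          v: [-140.0, -100.0, -80.0, -60.0, -40.0, 0.0]
          tau: [5.0, 8.0, 10.0, 13.0, 17.0, 25.0]
    # conductance retuned to hold the resting membrane voltage with all
    # spines instantiated
    gbar: {soma: 1.4e-4, proximal: 1.4e-4, medial: 1.4e-4, distal: 1.4e-4,
           head: 1.4e-4, neck: 1.4e-4}
  KRP:
    channel: KRP
    erev: k
    x: 1
    y: 1
    a: 1.0
    gates:
      m:
        vh: -13.5
        k: 11.8
        tau:
          v: [-100.0, -60.0, -40.0, -20.0, 0.0, 40.0]
          tau: [15.0, 12.0, 10.0, 8.0, 7.0, 6.0]
      h: {vh: -54.7, k: -18.6, tau: 3000.0}
    gbar: {soma: 1.0e-3, proximal: 8.7e-4, medial: 8.7e-4, distal: 8.7e-4}
  BK:
    channel: BK
    erev: k
    x: 1
    y: 0
    a: 1.0
    gates:
      m: {ca_gated: true, ca_ec50: 3.0e-3, ca_hill: 2.0, tau: 1.0}
    gbar: {soma: 1.0e-4}
  SK:
    channel: SK
    erev: k
    x: 1
    y: 0
    a: 1.0
    gates:
      m: {ca_gated: true, ca_ec50: 5.7e-4, ca_hill: 4.0, tau: 10.0}
    gbar: {soma: 1.0e-4, proximal: 1.0e-4, medial: 1.0e-4, distal: 1.0e-4,
           head: 2.0e-4}
  CaL1.2:
    channel: CaL1.2
    erev: ca
    is_calcium: true
    x: 1
    y: 1
    a: 0.17
    gates:
      m: {vh: -8.9, k: 6.7, tau: 0.2}
      h: {vh: -13.4, k: -11.9, tau: 44.3}
    gbar: {soma: 1.0e-5, proximal: 1.0e-5, medial: 1.0e-5, distal: 1.0e-5,
           psd: 1.5e-3}
  CaL1.3:
    channel: CaL1.3
    erev: ca
    is_calcium: true
    x: 1
    y: 1
    a: 1.0
    gates:
      m: {vh: -33.0, k: 6.7, tau: 0.2}
      h: {vh: -13.4, k: -11.9, tau: 44.3}
    gbar: {soma: 1.0e-5, proximal: 1.0e-5, medial: 1.0e-5, distal: 1.0e-5,
           psd: 1.5e-3}
  CaN:
    channel: CaN
    erev: ca
    is_calcium: true
    x: 2
    y: 1
    a: 0.21
    gates:
      m: {vh: -8.7, k: 7.4, tau: 0.15}
      h: {vh: -74.8, k: -6.5, tau: 70.0}
    gbar: {soma: 1.0e-5, head: 5.0e-4}
  CaQ:
    channel: CaQ
    erev: ca
    is_calcium: true
    x: 2
    y: 0
    a: 1.0
    gates:
      m: {vh: -9.0, k: 6.6, tau: 0.377}
    gbar: {soma: 1.0e-5, head: 5.0e-4}
  CaR:
    channel: CaR
    erev: ca
    is_calcium: true
    x: 3
    y: 1
    a: 1.0
    gates:
      m: {vh: -10.3, k: 6.6, tau: 1.7}
      h:
        vh: -33.3
        k: -17.0
        tau:
          v: [-100.0, -60.0, -40.0, -20.0, 0.0, 40.0]
          tau: [80.0, 70.0, 65.0, 60.0, 55.0, 50.0]
    gbar: {soma: 1.0e-5, head: 5.0e-4}
  CaT:
    channel: CaT
    erev: ca
    is_calcium: true
    x: 3
    y: 1
    a: 1.0
    gates:
      m:
        vh: -51.73
        k: 6.53
        tau:
          v: [-100.0, -70.0, -50.0, -30.0, 0.0]
          tau: [4.0, 3.0, 2.0, 1.5, 1.2]
      h:
        vh: -80.0
        k: -6.7
        tau:
          v: [-100.0, -80.0, -60.0, -40.0, 0.0]
          tau: [40.0, 30.0, 20.0, 15.0, 12.0]
    gbar: {medial: 1.0e-5, distal: 1.0e-5}
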