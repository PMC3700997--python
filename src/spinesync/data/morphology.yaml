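# Reduced MSN morphology: soma plus n_dendrites primary dendrites, each a
# proximal -> medial -> two-distal branch chain.  Spines attach to the
# first distal branch.  Dimensions in µm; passive properties per section.

passive:
  ra: 100.0        # Ω·cm axial resistivity
  cm: 1.0          # µF/cm²
  g_pas: 2.4e-5    # S/cm²
  e_pas: -70.0     # mV

soma: {diameter: 16.0, length: 16.0}
proximal: {diameter: 2.25, length: 20.0}
medial: {diameter: 1.10, length: 24.0}
distal: {diameter: 0.72, length: 190.0}
n_dendrites: 1

spine:
  psd: {diameter: 0.5, length: 0.05}
  head: {diameter: 1.175, length: 1.0}
  neck: {diameter: 0.1, length: 1.5}

synapse:
  # ca_fraction: share of the synaptic current carried by calcium
  ampa: {tau_rise: 0.5, tau_decay: 3.0, gpeak: 1.0, ca_fraction: 0.05}
  nmda: {tau_rise: 2.0, tau_decay: 100.0, gpeak: 0.5, ca_fraction: 0.01}
  erev: 0.0                                             # mV

shell:
  depth_um: 0.1
  vmax: 1.0e-6       # mM/ms
  km: 5.0e-4         # mM
  tau_r: 43.0        # ms
  ca_inf: 1.0e-4     # mM
  buffer_ratio: 50.0 # implicit endogenous fast buffer

integration:
  dt: 0.025        # ms
  v_init: -80.0    # mV
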