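# Kinetic parameters and initial concentrations of the spine plasticity
# network, keyed by the table they belong to.  M and s units throughout.
#
# table6 — allosteric (two-conformation) calmodulin calcium binding:
#   one per-site on-rate, macroscopic per-step off-rates for the high
#   affinity (R) and low affinity (T) conformations, and per-occupancy
#   R<->T transition rates obeying detailed balance with an allosteric
#   constant L0 = 2e4 and affinity ratio c = KR/KT = 1/30.
# table7 — enzymatic constants of the CaMKII / calcineurin / DARPP-32 /
#   PP1 / AMPAR reactions, the calcium pump and leak.
# table8 — initial (total) concentrations.
#
# Values are reconstructions grounded in the published kinetics literature
# for these enzymes; see docs/methods.md.

table6:
  kon: 5.0e+7           # M^-1 s^-1, per free site
  koff_R: [25.0, 50.0, 75.0, 100.0]        # s^-1, unbinding from R1..R4
  koff_T: [750.0, 1500.0, 2250.0, 3000.0]  # s^-1, unbinding from T1..T4
  k_RT: [14142.1, 2581.99, 471.405, 86.0663, 15.7135]  # s^-1, R_i -> T_i
  k_TR: [0.707107, 3.87298, 21.2132, 116.190, 636.396] # s^-1, T_i -> R_i

table7:
  pump:
    vmax: 1.0e-4        # M/s
    km: 1.0e-6          # M
  leak:
    k: 9.0909e-6        # M/s; balances the pump at 100 nM resting calcium
  cam_can:
    kon: 8.0e+7         # M^-1 s^-1
    koff: 1.2           # s^-1
  cam_camkii:
    kon: 5.0e+7         # M^-1 s^-1
    koff: 1.0           # s^-1
  camkii_autop:
    kcat: 0.05          # s^-1, Thr286, first order on the CaM-bound complex
  pka_d32:
    kon: 5.6e+7         # M^-1 s^-1
    koff: 10.8          # s^-1
    kcat: 2.7           # s^-1, Thr34
  can_d32p:
    kon: 1.0e+8         # M^-1 s^-1
    koff: 2.0           # s^-1
    kcat: 2.0           # s^-1
  d32p_pp1:
    kon: 1.0e+7         # M^-1 s^-1
    koff: 0.3           # s^-1  (Kd 30 nM)
  pp1_camkiip:
    kon: 3.0e+6         # M^-1 s^-1
    koff: 0.5           # s^-1
    kcat: 0.5           # s^-1
  camkii_ampar:
    kcat: 2.0           # s^-1, Ser831
    km: 5.0e-7          # M
  pp1_amparp:
    kcat: 0.5           # s^-1
    km: 2.0e-6          # M

table8:
  Ca: 1.0e-7            # M, free resting calcium
  CaM: 1.0e-5           # M
  CaMKII: 2.0e-5        # M
  CaN: 3.0e-6           # M
  PKA: 3.0e-7           # M (fixed-activity input; upstream cAMP not modeled)
  DARPP32: 5.0e-6       # M
  PP1: 2.0e-6           # M
  AMPAR: 4.6e-7         # M (~300 receptors in a 1.08 fL head)

options:
  cam_transitions: all  # 'all' (MWC) or 'ends' (sequential alternative)
  can_binds: 2          # R-state calcium occupancy recognized by calcineurin
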