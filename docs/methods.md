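# Methods

## The synchronization kernel

`spinesync` treats a multiscale simulation as two independent simulators
driven by a meta-simulator. A simulator is anything exposing
`current_time`, `step(to_time)`, `get(name)` and `set(name, value)`; the
kernel owns the timeline and always passes absolute target times, so
floating-point drift between the two clocks cannot accumulate — after
every synchronization cycle the two `current_time` values are identical,
not merely close.

Events (timed synaptic stimuli) are sorted into a queue before the run.
For each event the kernel advances both simulators independently to the
exact event time, then executes four-phase synchronization cycles every
`delta_exchange` (default 1 ms) for `window_length` (default 10 ms): the
slow simulator is read first — the fast, externally stimulated side must
see up-to-date values before the stimulus lands — then the fast side
steps, is read back, and the slow side steps by the same interval. The
pending event is delivered between phase 1 and phase 2 of the first
cycle, so a stimulus always sees the freshly computed synaptic weight.
Events arriving while a window is still open extend the window rather
than nesting a new one; this preserves a single timeline and makes the
cycle count for n non-overlapping events exactly
`n × window_length / delta_exchange`, independent of the total simulated
time. Off-grid events inside a window shorten one cycle so delivery still
happens at the exact event time.

Two baselines exist for comparison. The fixed-step while loop
synchronizes at every multiple of `dt_sync` and can only deliver events
that coincide with a grid point (absolute tolerance 1e-9 ms, to avoid
spurious float misses); everything else is recorded as missed. The
on-demand variant advances the fast simulator first in fixed strides and
opens a synchronization window whenever the fast side reports events
emitted during its last step; a slow simulator emitting events is
rejected, since the hierarchy requires the fast side to own event
generation.

When a window closes, targets of derivative-style transforms (the calcium
influx constant) are explicitly zeroed. A zeroth-order influx left
running after decoupling would keep injecting calcium with no electrical
counterpart; the stateful flux transform likewise re-samples its baseline
at window opening so declines that happened while decoupled are never
differenced into a spurious flux.

## The coupling transforms

Two quantities cross the interface per spine. The biochemical-to-
electrical direction maps phospho-AMPAR concentration to a dimensionless
synaptic weight, `w = 1 + g·(P/P_eq − 1)` with `P_eq` the equilibrium
phospho-AMPAR level recorded at the end of equilibration; `g = 1`
recovers the plain ratio `P/P_eq` (weight 1 at rest, >1 potentiated). The
default experiment gain is `g = 0.2`, chosen so that the several-fold
phospho-AMPAR excursions of a stimulation train map to weights of order
1.2–2 — a physiological conductance modulation — rather than the raw
ratio. The weight multiplies the AMPA peak conductance of the next
delivered stimulus only; it is never applied retroactively.

The electrical-to-biochemical direction converts the shell calcium
concentration into a zeroth-order flux constant
`k = Δ[Ca]/Δt` (mM/ms, numerically equal to M/s), the discrete
derivative over the exchange interval, driving a constant-flux process in
the kinetic model. Copying the concentration directly would fight the
rapid calmodulin buffering on the biochemical side; transferring the
derivative lets the buffered biochemical calcium reproduce the rise and
fall of the electrical trace. Negative fluxes (declining electrical
calcium) pass through; the free-calcium floor at zero is enforced with a
smooth shutoff (`k·x/(x+1e-9 M)` for negative k) — a hard cutoff makes
the right-hand side discontinuous and stalls the stiff integrator at the
boundary. Endpoint sampling per interval is used; sub-interval sampling
would only matter if the electrical solver's internal step exceeded the
exchange interval, which it never does here.

Counts and concentrations interconvert through the spine-head cylinder
volume (1.084 fL for the default geometry; 1 µM ≈ 653 molecules).

## The electrical model

A reduced MSN: soma plus `n_dendrites` primary dendrites, each a
proximal → medial → two-distal chain, with three-section spines
(PSD 0.5×0.05 µm, head 1.175×1.0 µm, neck 0.1×1.5 µm cylinders) attached
to the first distal branch. Spine sections carry their full surface
(lateral plus end caps: 0.471, 5.86, 0.487 µm²) as membrane area; the
default tree is deliberately small (desk-scale runtime); the full
symmetric 28-branch tree is buildable from config.

Channels follow the Hodgkin–Huxley/Boltzmann form
`I = ḡ·m^x·h_eff^y·(V−E)` with
`m∞ = 1/(1+exp(−(V−Vh)/k))` (negative slope k for inactivation) and
first-order gate relaxation by the exact exponential update
`m ← m∞ + (m−m∞)·exp(−dt/τ(V))`. Time constants are fixed values or
piecewise-linear V→τ lookups. Four channels (slow A-type potassium,
N-type and Cav1.2 calcium; assignments in the shipped config) use a
modified inactivation `h_eff = a·h + (1−a)`, which scales inactivation
depth and reduces to plain HH at a = 1. SK (and somatic BK) channels use
a Hill function of shell calcium instead of a voltage-dependent
activation. Channel Boltzmann parameters, conductance densities and τ
tables in `data/channels.yaml` are reconstructions grounded in the
published MSN modeling literature; they are config, not code, and any
entry can be overridden.

Placement: the PSD carries Cav1.2/Cav1.3 plus the co-localized AMPA and
NMDA synapses; the head carries Q-, R-, N-type calcium and SK; the
inward rectifier sits in head and neck. A build-time audit verifies this.

Numerics: backward-Euler solve of the voltage tree (dense linear system
per internal step — the desk-scale trees are far too small for sparse
methods to pay off), channel conductances frozen over the step, gates
updated exponentially, internal step 0.025 ms by default. Halving the
step changes the spine-head peak depolarization by well under 1%.
Blow-up (|V| > 200 mV) aborts with a named diagnostic.

Spine calcium is a thin shell (0.1 µm) under the head+PSD membrane:

    d[Ca]/dt = −I_Ca/(2·F·depth·B) − Vmax·[Ca]/([Ca]+Km) − ([Ca]−[Ca]∞)/τ_r

with F = 96.489 C/mmol, τ_r = 43 ms, and calcium current summed over the
voltage-gated calcium channels of the PSD and head plus a configurable
calcium fraction of the synaptic currents (AMPA 0.05, NMDA 0.01 —
glutamate-receptor calcium is a real influx source the coupling must
see). B is an implicit fast-buffer ratio (default 50 in the
shipped config, 1 in the standalone shell dataclass): a bare 0.1 µm shell
with no buffering produces millimolar transients, two orders above
measured spine transients, so only 1/B of entering calcium appears free.
The shell is advanced by forward Euler inside the voltage step.

NMDA receptors use a double-exponential conductance without a magnesium
block by default (configurable off/on was considered; the block is
omitted as the baseline since the plasticity protocols here never
hyperpolarize below the range where it would qualitatively matter, and
it adds a nonlinearity the rest of the model is not calibrated against).
Each synaptic event adds a normalized double-exponential transient whose
per-event peak equals `weight × g_peak`.

## The biochemical model

Deterministic mass-action/Michaelis–Menten kinetics in M and s,
integrated with LSODA (rtol 1e-8, atol 1e-14). Species are tagged with a
moiety composition, and every reaction is audited at build time for
moiety balance; calmodulin, CaMKII, DARPP-32, PP1 and AMPAR totals are
conserved to better than 1e-6 relative over any protocol.

Calmodulin is a two-conformation allosteric sensor: four sequential
calcium-binding steps in each conformation (one per-site on-rate with
statistical factors; macroscopic per-step off-rates, high-affinity R
state KD 0.5 µM per site, low-affinity T state 15 µM) and R↔T
transitions at every occupancy with rates obeying detailed balance
(allosteric constant L0 = 2·10⁴, affinity ratio c = 1/30). A config flag
(`options.cam_transitions: ends`) switches to the fully sequential
alternative wiring where only the empty and fully loaded states
interconvert.

Calcineurin binds the R conformation at calcium occupancy 2
(`options.can_binds`), CaMKII only the fully loaded R4 — this occupancy
gap is what routes sustained low calcium to the phosphatase branch and
high calcium to the kinase branch, standing in for the holoenzyme
cooperativity that is deliberately not modeled (a single first-order
Thr286 autophosphorylation per the one published constant). The
DARPP-32 cycle (PKA phosphorylates Thr34; CaM–calcineurin
dephosphorylates it) runs with both enzymes near substrate saturation,
making it a zero-order-ultrasensitive switch: when the calcineurin
capacity crosses the fixed PKA capacity, phospho-DARPP-32 collapses and
PP1 is released from inhibition in a strongly nonlinear fashion. PKA is
a fixed-concentration input (no upstream cAMP/dopamine dynamics).

Kinetic constants and initial concentrations in `data/kinetics.yaml` are
reconstructions: each is grounded in the published enzymology of these
reactions and then balanced, as part of model construction, so that the
network reproduces the described physiology — a resting fixed point with
free calcium at 100 nM, phospho-AMPAR a strict interior equilibrium
(~10% of the receptor pool), PP1 mostly DARPP-32-inhibited at rest, and
the calcium-level switch below.

The switch. From a potentiated state (elevated phospho-AMPAR), sustained
modest calcium influx (free calcium ~0.2 µM) yields net
**de**phosphorylation — the released PP1 outweighs the mildly activated
kinase — while strong influx (micromolar calcium) yields net
phosphorylation, the CaM–CaMKII complex overwhelming the phosphatase.
The net-flux sign is evaluated at an elevated phospho-AMPAR reference
rather than at the resting fixed point: with a non-cooperative kinase
whose activation is quartic in calcium (R4) and a phosphatase arm at most
quadratic (R2), any calcium rise from rest transiently favors the
kinase; what the phosphatase branch governs is the fate of an already
potentiated synapse, which matches the observed decay of the synaptic
weight between stimulation trains.

`equilibrate` integrates with zero influx until every species' relative
time derivative falls below tolerance (per-species, not globally scaled —
small species such as phospho-AMPAR must individually settle), records
the equilibrium as the weight reference, and warns rather than raises on
non-convergence. Two differently perturbed starts relax to the same
fixed point at the default parameters (no bistability).

Counts are reported from concentrations via the head volume at reporting
time only; internally everything is a concentration.

## Morphology

The spine budget inverts the Segev fold `L' = L·F^{2/3}`,
`d' = d·F^{1/3}` (lateral area scales by exactly F): the surface deficit
between the corrected and original dendritic areas, divided by the
6.35 µm² one spine exposes, floored (a partial spine is no spine), then
reduced to the largest multiple of the primary-dendrite count, with an
optional per-branch removal of proximal digitization-noise spines. On
the default inputs (14973/5278 µm², 4 dendrites, 5 noise spines per
branch) this gives 9695 µm² → 1526 → 1524 → 381 per branch → 1504 final.

Spine placement integrates a fitted spine-surface density profile
(distance from soma → µm² of spine membrane per µm of dendrite) along a
branch path, divides by the per-dendrite share (4), discretizes by the
per-spine equivalent area with a running remainder, and removes spines
inside a proximal exclusion distance. Fits use a Chebyshev basis — a raw
power basis is numerically unusable at the default order 17 — with
evaluations clamped at zero. The shipped profile generator is synthetic:
it emulates the qualitative shape of measured MSN data (near-zero
proximal density, peak ≈50 µm from the soma, slow distal decay) because
the digitized microscopy data are not available; user CSV profiles are
accepted. Placement is deterministic (even spacing within each segment;
the optional noise in the synthetic generator takes an explicit seed).

## Experiments and what the tests do and do not show

The default experiment is one dendrite with one to a handful of spines
and ≤ 20 s of simulated time: a double 8 Hz train (20 inputs each) at
2000 ms and 15000 ms on one spine. Biochemical instances are created only
for stimulated spines, each equilibrated before the run. Recording
cadence is 1 ms electrical, 10 ms biochemical, both configurable. The
acceptance experiment runs at an internal electrical step of 0.05 ms;
the convergence check bounds the step-halving error well under the
effect sizes asserted.

The double-train comparison shows the mechanism the package exists to
demonstrate: the first train's calcium drives CaM–CaMKII phosphorylation
of AMPAR over ~10 s — continuing to rise after the train ends, because
the kinase outlives the stimulus — so the second train arrives at an
increased weight and elicits a larger depolarization; disabling the
biochemistry makes the two responses identical.

These are qualitative reproductions at desk scale. The synthetic density
profile, the reconstructed channel and kinetic constants, and the reduced
tree mean that passing tests demonstrate the algorithmic and structural
claims (event delivery, conservation, the switch logic, the feedback
loop), not quantitative agreement with any particular neuron's traces.
Wall-clock comparisons between strategies are reported but never
asserted: they are hardware-dependent.

## Numerical choices, in one place

* Time grid tolerance 1e-9 ms for event/grid coincidence.
* Electrical: backward Euler dt 0.025 ms (0.05 ms in the acceptance
  experiment), exponential gate updates, forward-Euler shells, dense
  tree solve.
* Biochemical: LSODA, rtol 1e-8 / atol 1e-14; halving rtol moves the
  phospho-AMPAR trajectory by < 0.5%.
* Equilibration: per-species relative-derivative tolerance 1e-6 /s,
  horizon 5000 s, geometric chunk growth.
* Degenerate inputs: zero-length cylinders are legal (zero area); a
  fitted density clamps at zero; shell calcium clamps at zero with a
  warning; negative weights rejected.

## Known limitations

* No action potentials are expected or validated; the channel parameter
  reconstruction is not calibrated for somatic excitability studies.
* The LTD regime requires a pre-potentiated synapse (see the switch
  discussion); rest-referenced LTD would need cooperative CaMKII
  activation, which is out of scope.
* No spatial diffusion, no stochastic kinetics, no rollback
  synchronization, no MPI transport.
* The implicit fast buffer and the synaptic calcium fractions are
  effective parameters standing in for unmodeled buffer species and
  receptor-level calcium permeabilities.
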