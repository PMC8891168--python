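# Methods

## The plasticity rule

Per synapse, eight state variables are integrated by explicit forward
Euler on the trace grid (default dt = 0.1 ms): the constrained energies
P, P_bas, P_sup and weight W; their unconstrained shadows; and the supply
pair S_damp, S_lin. The supply is integrated in split form
(dS_damp/dt = −S_damp/τ with S_damp(0)=1; dS_lin/dt = R with S_lin(0)=0;
S = S_damp·S_lin + S0), which reproduces S(t) = R·t·e^(−t/τ) + S0 up to
Euler error. Within one step the supply variables advance first; the sign
factor sign(S − |P|) then combines the updated supply with the
start-of-step P, and all energies and the weight advance together.
sign(0) = 0 freezes the constrained state for that step.

Initial values: P = P_bas = P_sup = 0, W = 0.5, likewise the shadows.
Threshold classification is strict/inclusive — subthreshold iff
V_m < V_th, suprathreshold iff V_m ≥ V_th — so a sample at the threshold
is counted exactly once. The decomposition P = P_bas/A_r + P_sup and the
unconstrained identity W_u − 0.5 = A·(P_bas_u − P_sup_u) hold to machine
precision at every step by construction, and the test suite asserts both.

The time-compression factor A_scale multiplies *every* derivative,
including the supply dynamics: five simulated pairings with A_scale = 12
traverse the same supply trajectory as sixty pairings in real time. The
supply clock starts at stimulation onset and runs continuously through a
protocol (the four HFS series share one clock); state is never carried
across protocol runs.

Although the supply variables are maintained per synapse, their dynamics
do not depend on synaptic state, so every synapse sees the same S(t); the
vectorized engine therefore carries them once and exposes per-synapse
values on the state object.

### Behavior at the supply boundary

The sign flip is a chattering controller: while the drive V·I pushes |P|
outward, the trajectory alternates around |P| = S and tracks the boundary
to within one Euler increment A_scale·|V·I|·dt. Two caveats follow from
taking the differential form literally. First, if the drive later drops to
zero (between stimuli), P stays where the last chatter left it while S
keeps decaying, so at end of stimulation |P| can exceed S by the supply
decay since the last active episode; the protocol tests therefore assert
exact boundary pinning only where the supply has already reached its floor
(0.1 Hz pairing, 1 Hz afferent) and plot-resolution overlap elsewhere.
Second, if the drive reverses sign while |P| > S, the flipped sign moves P
*away* from the boundary instead of back toward it; none of the modeled
protocols enter that regime persistently (their drive alternates quickly),
and the fixture battery used for boundary tests keeps V·I single-signed
where the tracking property is asserted.

### Oracles

Two independent checks cover the engine. On piecewise-constant traces
below the supply bound, the energies have closed forms (segment sums
Σ V·I·T split by threshold class) that the engine must match to machine
precision. In the constrained regime, a deliberately naive pure-Python
loop re-integrates the equations at dt/refine with the supply evaluated
from its closed form rather than the Euler pair; engine and oracle must
agree within the chattering bound on P and within 1% of the accumulated
plasticity flux A·(|P_bas|+|P_sup|) on W (ΔW itself can be a
near-cancelling difference of the two classes, so a relative tolerance on
ΔW would be ill-posed on balanced fixtures).

## The reduced neuron

The driver is a deliberately small compartmental model: a spherical soma
(20 μm) with four unbranched basal dendrites of twenty 10×1 μm
cylindrical compartments. It is not a stand-in for any particular
morphology; it exists to produce the qualitative V_m/I_m features the
plasticity rule consumes — a resting state, somatic spikes with
distance-attenuated backpropagation, and local synaptic depolarization —
under two quantitative calibration contracts (rest at −69 ± 0.5 mV;
strictly monotone bAP attenuation along each branch).

Channels: Traub/Pospischil-style Na and K spiking kinetics (V_T = −55 mV,
E_Na = 50, E_K = −90 mV) at 50 and 5 mS/cm² in the soma and 0.02× those
densities in dendrites; ohmic leak g_L = 0.05 mS/cm² with E_L = −60 mV;
Cm = 1 μF/cm²; Ra = 150 Ω·cm. Because E_L sits above the target rest, a
voltage-independent potassium leak is solved per compartment at build time
so that the full membrane equation (spiking channels at steady state
included) balances exactly at −69 mV — the resting contract then holds by
construction and I_m is exactly zero at rest. Each branch tip carries a
2 nS absorbing terminal conductance reversing at rest: it stands in for
the axial load of a continuing dendrite and suppresses the sealed-end
voltage reflection, which would otherwise make the bAP peak *grow* over
the last third of the branch. It carries no current at rest and, modeling
axial rather than transmembrane flux, is excluded from I_m.

Synapses are conductance-based with reversal 0 mV: a fast AMPA-like
component (0.5 nS peak × weight, τ = 2 ms) and a slow NMDA-like component
(8 nS × weight, τ = 50 ms) under the standard sigmoidal magnesium block
1/(1 + [Mg]/3.57·e^(−0.062V)), [Mg] = 1 mM. The NMDA dominance is what
gives the rule its coincidence detector: an isolated EPSP stays
subthreshold (local peak ≈ −64 mV) and accumulates negative P_sub (LTD
drive), while an EPSP paired with a bAP, or summating at high rates,
unblocks the NMDA conductance at suprathreshold voltages and accumulates
negative P_sup (LTP drive).

I_m sums ionic and synaptic transmembrane current densities with
depolarizing current positive; capacitive, axial and electrode currents
are excluded, so P measures the dissipative flux that pumps must restore.
Synaptic inclusion is a config switch (default on).

Integration is semi-implicit at dt = 0.1 ms: gates by exponential Euler at
the pre-step voltage, then a backward-Euler voltage solve with the
conductances frozen, performed by Hines elimination over the branch tree
(O(N) per step, compiled with numba). Identical configs give bitwise
identical traces.

### Calibration

The free strengths (dendritic channel scale, synaptic conductances,
terminal leak) were chosen once so that all qualitative contracts hold
simultaneously: monotone bAP attenuation; exactly one spike per 1 nA/3 ms
somatic pulse and five spikes for five pulses at 50 Hz; pairing at
Δt = +10 ms giving ≈ 0 constrained ΔW at 0.1 Hz and clear LTP at 50 Hz;
pairing at Δt = −10 ms giving LTD at 0.1 Hz crossing to LTP at 50 Hz;
Poisson afferent LTD at 1–5 Hz and LTP at ≥ 30 Hz; and HFS producing
homosynaptic LTP with distance-decaying heterosynaptic LTD. The corners of
this region are informative: dendritic Na above ~0.1× breaks the
Mexican-hat profile (its window current turns mid-branch P_sup negative
under sustained depolarization, i.e. spurious heterosynaptic LTP), and
NMDA beyond ~16 nS breaks low-rate afferent LTD (isolated EPSPs cross
threshold).

## Protocols and experiments

* Pairing: presynaptic events at the repetition frequency, each paired
  with a somatic pulse (1 nA, 3 ms) offset by Δt (positive = pre before
  post; negative Δt shifts the whole protocol so no event is negative).
  Five repeats, A_scale = 12. Protocol duration covers five full periods
  regardless of Δt, so a Δt sweep at fixed frequency shares one
  stimulation time and hence one supply trajectory (P_max is then
  identical across Δt by construction, which the tests assert).
* Afferent: exactly 20 events per synapse, count-conditioned Poisson
  (i.i.d. exponential inter-event intervals at the nominal rate); each
  synapse draws an independent stream from the root seed.
* HFS: 4 series × 10 trains × 10 shocks at 100 Hz (Poisson within train),
  trains 0.3 s apart; the separation between series defaults to 10 s
  (configurable) and the supply clock does not reset between series.

Sweeps record one synapse on each proximal- and distal-third site of every
branch (evenly spaced within the zone). Pairing sweeps stimulate one
synapse per simulation — concurrently active synapses on different
branches would sum at the soma and fire spikes the protocol does not
prescribe — while afferent sweeps batch one site per branch (independent
Poisson streams do not synchronize). The Mexican-hat experiment attaches
two synapses to every compartment of the stimulated branch, delivers HFS
to the stimulated compartment only, and bins the same-branch heterosynaptic
compartments into six equal-width path-distance sites (site 0 = stimulated
compartment; per-site values average over compartments and both synapses;
off-branch recording sites are tabulated but excluded from the 7-site
profile). All quantities are end-of-stimulation values, including a 50 ms
settle window; curves report mean ± SD over synapses.

Default sweep sizes in the test suite (two sites per zone for pairing and
afferent sweeps, one stimulated site per zone and branch for HFS) were
chosen as the smallest statistics that exercise both zones of every
branch; the CLI exposes the full grids.

## Known limitations

* The reduced neuron reproduces the qualitative shape, not the absolute
  energy magnitudes, of a detailed morphology; its per-pulse energy export
  is smaller, so in the afferent protocol the supply constraint is fully
  pinned at 1 Hz but only partially engaged at 3 Hz, and unconstrained
  pairing LTP at 50 Hz is larger than experimental weight changes (the
  supply is not binding there).
* Weights have no floor at zero by design — avoiding hard weight bounds
  is the model's point — so strong protocols can drive W above 1 or below
  0; interpret W − 0.5 as the plasticity readout.
* Heterosynaptic LTD here is carried by the suprathreshold energy of
  attenuated bAPs and spreading depolarization at non-activated synapses;
  models with different dendritic channel complements could shift the
  homo/hetero balance.
* The supply equation is a phenomenological stand-in for unknown supply
  dynamics; the engine accepts any supply implementation that exposes the
  same split-form interface, but only this one is provided.
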