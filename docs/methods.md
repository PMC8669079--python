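# Methods

`isthmus` simulates infarct-related ventricular tachycardia (VT) and
low-energy targeted electrotherapy on a synthetic two-dimensional tissue
preparation.  This note records the model, the calibrated study conditions,
the numerical choices, and what the synthetic preparation can and cannot
say about whole-heart behaviour.

## Tissue model

Cardiac tissue is the standard two-phase (bidomain) continuum:

    div(sigma_i grad phi_i) = beta * I_m
    -div(sigma_e grad phi_e) = beta * (I_m - I_e)
    I_m = C_m dV_m/dt + I_ion(V_m, eta),    V_m = phi_i - phi_e

with anisotropic intra/extracellular conductivity tensors rotated by the
local fibre angle, a surrounding conductive bath governed by a Laplace
equation with potential and flux continuity at the tissue surface, and
sealed (no-flux) outer boundaries.  Between therapies the simulator steps
the monodomain reduction, `div(sigma_m grad V_m) = beta (I_m - I_s)`, where
`sigma_m` is the per-eigendirection series (harmonic-mean) combination
`sigma_i sigma_e / (sigma_i + sigma_e)`; the full bidomain system runs only
while a shock is being delivered (Dirichlet electrode faces), which is the
usual economy for defibrillation studies.

Parameter defaults (all config-exposed):

| quantity | value | unit | note |
|---|---|---|---|
| sigma_il / sigma_el | 0.174 / 0.625 | S/m | along fibre, intra/extra |
| sigma_it / sigma_et | 0.019 / 0.236 | S/m | across fibre |
| border-zone factor | 0.5 | - | on all tissue conductivities |
| scar conductivity | 0.05 | S/m | isotropic, both phases, passive membrane |
| bath conductivity | 1.0 | S/m | isotropic |
| beta | 1400 | 1/cm | = 0.14 1/um |
| C_m | 1.0 | uF/cm^2 | standard value |

Units are cm / ms / mV / uA/cm^2; conductivities are stored in S/m and
converted to mS/cm (x10) at assembly (unit-tested).

## Membrane models

*Full model.*  The 2006 human ventricular (epicardial) ionic model,
implemented from the published kinetics with 18 state variables.  The
healthy "porcine" variant multiplies G_Kr and G_Ks by 1.5 to shorten the
action potential toward porcine durations (measured here: APD90 ~264 ms vs
~308 ms for the human baseline at 1 Hz).  Border-zone remodelling reduces
the potassium conductances by 30-65% and the sodium conductance by 10-90%,
applied multiplicatively on the porcine basis (the remodelled tissue is
"altered from healthy tissue", i.e. after the 1.5x scaling).

*Reduced model.*  A two-variable threshold-recovery membrane
(Mitchell-Schaeffer type): normalised excitation u with cubic ingoing
current (time scale `tau_in`), linear outgoing current (`tau_out`), and a
recovery gate h opening with `tau_open` below the gate voltage and closing
with `tau_close` above it.  V_m = -80 mV + 100 mV * u.  Defaults:
tau_in 0.3 ms, tau_out 6 ms, tau_open 120 ms, tau_close 70 ms, gate 0.13
(healthy porcine reference: APD90 ~190 ms, longitudinal CV ~0.47 m/s,
transverse ~0.15 m/s at 0.025 cm pitch).  The conductance multipliers map
onto its time constants -- `tau_in` and `tau_open` scale with 1/g_Na
(slower upstroke, post-repolarisation refractoriness), `tau_close` with the
inverse relative potassium scaling (longer action potential) -- so
border-zone physiology is preserved qualitatively.  One deliberate
extension: below rest the linear outgoing term acts on the raw (unclipped)
variable, so shock-hyperpolarised tissue relaxes back to rest instead of
being stuck at the clip boundary.  All reentry/therapy simulations and the
acceptance runs use the reduced model; the full ionic model is exercised at
single-cell level and in unit-scale tissue tests (a tissue-scale run with
it is ~50x more expensive and adds nothing to the mechanisms examined
here).

*Passive model.*  A linear leak membrane for cable-theory validation; the
steady-state space constant is lambda = sqrt(sigma_ml / (beta g_m)), about
0.031 cm for the default conductivities at g_m = 1 mS/cm^2.

## Synthetic infarct geometry (the study conditions)

The undeposited animal anatomies are replaced by a parameterised 2-D sheet:

* tissue 4.0 x 3.2 cm at 0.025 cm pitch, bath bands 1.2 cm on the cavity
  and exterior sides (desk-scale: large enough for ~0.6 cm flanks around
  the scar and for electrode clearances, small enough that induction plus a
  therapy sweep runs in minutes on one core);
* a non-conducting scar band 2.0 cm thick spanning the full width, pierced
  by a single 0.4 cm conducting channel ("CI"), with a 0.05 cm border-zone
  rim around the scar and lining the channel;
* inside the channel, a thin (0.075 cm) fibrotic strand ending 0.12 cm
  short of the band edges splits it into a fast (healthy) lane and a slow
  (border-zone) lane that rejoin at both mouths -- the heterogeneous
  channel composition that clinical isthmuses exhibit, and the anatomical
  circuit for figure-of-eight reentry;
* uniform fibre angle 0 (along the sheet), so channel conduction is
  transverse and slow; an optional linear transmural rotation is available.

Flood-fill invariants are enforced at construction: the excitable tissue is
one connected component, and removing the "CI" node-set disconnects the two
flanks (every reentrant path crosses the channel).

Electrode layouts: the transmural pair (two 0.5 cm squares facing each
other across the tissue at the channel, clearance 0.6 cm on this grid --
the ~1 cm used at whole-heart scale does not fit a 1.2 cm bath band), and
the bipolar array (five 0.4 cm squares with 0.4 cm gaps in the cavity-side
bath, the face of each square nearest the channel grounded and the opposite
face driven).  Electrode interiors are insulating and excluded from bath
conduction; only face node-sets carry Dirichlet values, and they are
released when the pulse ends.  Placement happens before operator assembly;
each layout lives on its own grid clone so checkpointed states transfer.

## VT induction and the episode library

Programmed stimulation follows the standard clinical protocol: three S1 at
a 500 ms basic cycle length from a cavity-side edge strip, then S2
decremented by 10 ms per attempt (S3 added if capture fails first; coupling
floor 200 ms, at most 31 attempts).  Unidirectional block arises at the
slow lane's entrance -- its long post-repolarisation refractoriness blocks
the premature wavefront antegradely while the fast lane conducts -- and the
wave re-enters the slow lane retrogradely from the exterior mouth, closing
the circuit.  With the calibrated border-zone reductions (65% IKr/IKs, 30%
INa) the default preparation induces at S2 couplings of ~250 ms and below
(measured VTCL ~555 ms with the remodelled border zone in the circuit);
the block is evidenced by retrograde slow-lane activation -- the lane's
exit end activating before its entrance end -- recorded in episode
provenance.

Stabilisation then resets the border-zone ionic properties to healthy
(longer border-zone action potentials are anti-arrhythmic and attenuate
sustenance) and optionally rescales conductivities subject to a measured
conduction-velocity change of at most 60%; the stabilised episode rotates
with VTCL ~450 ms and cycle-length variation under 1%.

The episode library re-conditions the stabilised circuit by scaling the
channel conductivity (slower channel -> longer cycle) and, optionally,
re-applying border-zone kinetics; conductivity variants must respect a 10%
CV bound, each variant is re-simulated for more than five cycles, and only
stable monomorphic rhythms are kept.  The default factor sweep
(0.6, 1.0, 1.5, 2.5) spans VTCL ~578 / 450 / 377 / 310 ms -- both the slow
(> 320 ms) and fast (<= 320 ms) classes.

## Therapies and endpoints

*Burst pacing*: two sequences of eight pulses at 88% of the VTCL (second
sequence 10 ms faster), started 88% of the VTCL after the last sensed
activation at the pacing site; 50 uA/cm^2, 2 ms pulses over a 0.5 cm tissue
block.  The stimulus is applied as a transmembrane current density over the
block (at the reduced model's scale a 50 uA/cm^2 x 2 ms pulse is ~4x
threshold, so no extra scaling constant is needed; the identity scale is
logged in provenance).  The gap between sequences re-senses the site by
default (a fixed one-interval gap is the config alternative).

*Single shocks*: 5 ms monophasic pulses, delivered a configurable fraction
(default 0.88) of the VTCL after the last sensed activation at the
reference site; the strength search walks the voltage grid bottom-up
(transmural step 10 V, bipolar step 20 V by convention) and memoises
outcomes, so the returned minimum is guaranteed terminating while one step
below is guaranteed failing.  Calibration strengths are the smallest grid
strengths terminating 5/6 and 6/6 of a six-episode calibration set.

On this 2-D preparation the transmural pair polarises the channel mouths
and the tissue surfaces (the space constant is ~0.03 cm, so lane interiors
are shielded); a shock also excites the flanks broadly, and the circuit
restarts whenever either lane entrance has recovered.  Termination
therefore happens in the phase window where both lane entrances are
refractory: the fast-class episode terminates at delivery fractions near
0.45 and 0.65 of the cycle (thresholds ~150 V and ~200 V, i.e. ~1.1-2 J),
while the slow base episode resets rather than terminates at every tested
phase and strength (<= 500 V), and the far-field bipolar array does not
terminate these episodes at up to 2000 V.  The optimal fraction is a
property of the preparation and of where in the channel the sensing
electrode sits; whole-heart geometry shifts it.  The search-correctness
checks therefore run at the preparation's measured vulnerable phase
(0.45), while the protocol default stays at the conventional 0.88.

*Sensing and verdicts*: activations are upward crossings of -20 mV with a
50 ms refractory gate and a 10 mV re-arm hysteresis (robust across both
membrane models and noisy fixtures).  The reference sensing site is the
cavity-side channel mouth: the mean potential over the whole channel
smears the two lanes' activations (~200 ms apart) and misses crossings.
Termination requires a reference-site-silent window of 3 x VTCL AND all
excitable tissue below -60 mV at the end of the run; the follow-up extends
automatically (up to 3 windows) when a shock leaves transient activity that
dies late, and a verdict is refused (never silently) when the simulated
follow-up is too short.  Scar nodes hold a frozen potential in monodomain
and are excluded from activity checks.

*Energy*: device energy is the capacitive-discharge estimate
E = C V^2 / 2 with effective capacitance C = 1.0e-4 F, recovered by a
tested least-squares helper from standard device operating points;
deposited field energy integrates sigma |grad phi|^2 over the domain
(quadratic form of the assembled extracellular operator) and splits it
into tissue versus bath, assuming 1 cm out-of-plane depth.

## Numerics

* Structured-grid finite differences; anisotropic tensors enter through
  harmonic face averages (axis terms) and a symmetric central scheme
  (cross terms); with axis-aligned fibres this is exactly the 5-point
  anisotropic stencil.  Zero conductivity outside a node-set acts as a
  sealed boundary, so each operator carries natural no-flux conditions.
  All operators are symmetric with zero row sums.
* Operator splitting: Rush-Larsen for gates, forward Euler for
  concentrations, Crank-Nicolson diffusion; dt = 0.1 ms between therapies,
  0.025 ms during shocks (both capped at 0.1 ms).  Sparse LU
  factorisations are cached per (dt, electrode configuration).
* The elliptic extracellular solve is gauge-fixed (zero mean) when no
  electrode is active; a net extracellular monopole current is balanced by
  removing the mean source (uniform return current).
* First-order splitting biases a passive membrane's effective conductance
  by ~dt g_m / 2; the cable-validation harness therefore steps at 0.02 ms.
* Planar conduction velocity is mesh-converged (halving the 0.025 cm
  pitch changes it by well under 3%) but, as in any coarse-dt reaction
  splitting of a stiff upstroke, depends on the reaction time step (the
  0.1 ms default overestimates the dt -> 0 velocity by a few tens of
  percent).  The study conditions -- cycle lengths, induction windows,
  vulnerable phases -- are defined and calibrated at the default dt, which
  is therefore part of the frozen conditions.
* Determinism: geometry, fixtures and episode generation are seed-exact;
  repeated runs are bit-identical.

## Problem sizes used by the test-suite and acceptance runs

The default preparation has ~8,900 excitable nodes (~29,000 including
bath).  The suite induces one episode (S1 drive plus S2 scan entering the
decremental search at 280 ms) and reuses it session-wide, derives the
fast-class variant from it, and runs shock searches on coarse voltage
grids (a 3-point transmural grid at the vulnerable phase; a 2-point
far-field grid for the logged timing trend); solver validation (cable,
bidomain equivalence, virtual electrodes) uses 1 x 1 cm or strip sheets.
The full suite runs in roughly 10-15 minutes on one core.  These sizes are
the package's desk-scale study conditions, chosen once with the geometry
calibration.

## What the synthetic preparation does and does not show

The preparation reproduces the mechanisms: anatomical isthmus-dependent
reentry with realistic cycle lengths, slow/fast classes driven by channel
conduction, virtual-electrode polarisation concentrated at the channel
mouths and tissue surfaces, targeted low-energy termination, and the
strength/timing structure of single-shock therapy.  It does not reproduce
whole-heart quantities: absolute termination voltages, efficacy
percentages over a 40-episode anatomical cohort, or transmural
(wall-thickness) effects -- those depend on 3-D anatomy, fibre rotation
and cluster-scale meshes.  Headline animal-cohort numbers are therefore
not targets of the desk-scale acceptance runs; the acceptance checks cover
the energy model, solver physics, protocol arithmetic, reentry induction
and search correctness.

On the same preparation burst pacing captures and entrains the circuit
but does not terminate it from any tested site (remote or near-channel,
either VT class): a paced wavefront that penetrates the excitable gap
resets the rotation exactly as a mistimed shock does, and the 2-D sheet
offers no transmural dispersion for the paced wavefronts to exploit.
Anti-tachycardia pacing efficacy on this preparation is therefore 0% --
consistent in ordering (targeted shocks outperform pacing) though not in
magnitude with whole-heart behaviour.

## Known limitations

* 2-D sheet: no transmural fibre rotation effects, no wall-thickness
  virtual electrodes; the "epicardial/endocardial" surfaces are the two
  long edges.
* The reduced membrane has no biphasic-shock electroporation or
  make/break excitation asymmetry; only monophasic pulses are modelled
  (by design).
* Scar is a passive conductor (config-selectable fully-insulating
  alternative via a very small conductivity).
* The monodomain phase freezes scar potential; exported fields reflect
  this (activity checks exclude scar).
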