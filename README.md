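# isthmus

Desk-scale simulation of infarct-related ventricular tachycardia (VT) and
low-energy targeted electrotherapy, for computational electrophysiologists
who want the mechanisms of isthmus-dependent reentry and its termination —
programmed-stimulation induction, anti-tachycardia pacing (ATP), and
virtual-electrode shocks — on a laptop instead of a cluster.

## The model

Tissue is the standard bidomain continuum,

```
∇·(σ_i ∇φ_i) = β I_m          I_m = C_m ∂V_m/∂t + I_ion(V_m, η)
−∇·(σ_e ∇φ_e) = β (I_m − I_e)  V_m = φ_i − φ_e
```

with anisotropic conductivity tensors rotated by the fibre angle, a
surrounding conductive bath (∇·(σ_b∇φ_b) = 0, flux- and
potential-continuous at the tissue surface), and no-flux outer boundaries.
Between therapies the monodomain reduction ∇·(σ_m∇V_m) = β(I_m − I_s) is
stepped with the harmonic-mean tensor σ_m = σ_iσ_e/(σ_i+σ_e); the full
bidomain system runs during shock delivery, with electrode faces held at
Dirichlet potentials.

Membrane kinetics are either the 2006 human ventricular ionic model (with
+50% I_Kr/I_Ks to approximate the shorter porcine action potential, and
30–65% potassium / 10–90% sodium conductance reductions for border-zone
remodelling) or a fast two-variable threshold-recovery surrogate that maps
the same conductance multipliers onto its time constants.

The undeposited animal anatomies are replaced by a synthetic infarct: a
2-D sheet whose non-conducting scar band is pierced by a single conducting
channel (the critical isthmus, "CI") containing a thin fibrotic strand, so
a fast healthy lane and a slow border-zone lane rejoin at both mouths.
Programmed stimulation (S1×3 at 500 ms, S2 decremented by 10 ms) blocks
antegradely in the slow lane and re-enters it retrogradely — a
figure-of-eight circuit whose cycle length is set by channel conduction.
See `docs/methods.md` for the full parameter table and calibration.

## Worked example

```python
from isthmus import analysis, geometry, protocols, synthetic

setup = synthetic.default_infarct_setup()          # grid + membrane models
raw = protocols.induce_vt(setup, s2_start=280.0)   # S1-S2 programmed stimulation
ep = protocols.stabilize_vt(raw)                   # border zone -> healthy kinetics
print(f"{ep.vtcl:.0f} ms {ep.vt_class}")

fast = protocols.generate_vt_library(ep, [{"ci_factor": 2.5}])[-1]
ep_t, pair = protocols.with_electrodes(
    fast, lambda g: geometry.place_transmural_pair(g, clearance=0.6))
v = protocols.find_min_strength(ep_t, pair, step=100.0, vmax=300.0,
                                fraction=0.45)
print(f"{v:.0f} V  {analysis.shock_energy(v):.1f} J")
```

prints (reduced membrane model; the geometry is deterministic):

```
450 ms SLOW
200 V  2.0 J
```

— programmed stimulation induces a sustained slow monomorphic VT (449.6 ms
cycle), the library variant with faster channel conduction is a fast VT
(310 ms), and the smallest transmural shock on the 100 V grid that
terminates it at the preparation's vulnerable phase is 200 V, with
capacitive-discharge energy E = ½CV² (C = 1.0×10⁻⁴ F; e.g. 120 V ↦
0.72 J).  `examples/` contains one narrative script per capability
(geometry, single-cell APs, induction, virtual electrodes, therapy
comparison, config-driven experiments).

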