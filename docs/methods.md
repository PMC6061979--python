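# Methods

## The model

`detrusor` simulates the electrical activity of a mouse detrusor (urinary
bladder) smooth muscle cell.  The membrane is a single isopotential
cylinder (200 µm × 6 µm, C_m = 1 µF/cm², R_m = 138 kΩ·cm²,
R_i = 183 Ω·cm) obeying

    C_m dV/dt = (I_inj + I_axial − Σ I_ion − I_syn) / C_m,

with injected depolarizing current defined positive.  Nine active
conductances plus an ohmic background leak carry Σ I_ion:

| channel | form | role in the calibrated cell |
|---|---|---|
| CaT  | HH m·h | steep low-threshold trigger near −30 mV; fast inactivation, slow subthreshold recovery |
| CaL  | HH m·h | carries the spike dome; slow inactivation (τ_h ≈ 70 ms) sets the dome's decay |
| Kv1  | HH m·h | high-threshold delayed rectifier capping the peak; inactivation is a calibrated 3 s constant (the published inactivation protocol lasts 15 s) |
| KCNQ | HH m | quasi-ohmic resting K⁺ conductance (see "exponential foot" below) |
| BK   | 10-state Markov | accumulates open probability through the dome, terminates it, and its closing residual is the AHP |
| IK   | HH m, Ca-gated | Hill-activated by the shell transient; late repolarization |
| SK   | HH m, Ca-gated | Hill-activated; E_rev = −15 mV per the published table, so it depolarizes below −15 mV and grooms the late phase |
| KATP | ohmic, ATP-gated | equilibrium Hill inhibition by ATP; resting background |
| Ih   | HH m | hyperpolarization-activated restorer that terminates the AHP |

Maximal conductances and reversal potentials are the published whole-cell
values (S/cm² and mV).  All gating parameters are calibrated (see below)
and tagged `calibrated` in the configuration's provenance map; the
published geometry, conductances, reversals, resting [Ca²⁺]ᵢ and shell
depth are tagged `source-cited`.

Units throughout: mV, ms, mM, S/cm², mA/cm²; absolute currents in nA,
inter-compartment conductances in µS.

## Gating kinetics

Steady states are single Boltzmann functions

    m∞(V) = 1 / (1 + exp((V + V½) / S)),

implemented literally, so activation gates carry negative S and
inactivation gates positive S (Ih, activated by hyperpolarization, uses
positive S).  Time constants are either constants or bell curves
τ(V) = τ₀ + a / cosh((V + V_mid)/σ); the bell form gives CaT its fast
inactivation at spike voltages with slow subthreshold recovery (which makes
the cell refractory enough to fire exactly twice during a 100 ms, 0.1 nA
injection) and gives Kv1 slow deactivation through the repolarization.

Temperature scales all rates by tadj = 2^((T−37)/10); steady states are
temperature independent.  Doubling tadj exactly halves every relaxation
time constant (verified by exponential fits in the suite).

**KCNQ on its exponential foot.**  A single-Boltzmann KCNQ cannot
simultaneously supply the standing outward current implied by the ~2 mV
resting depolarization under 20% BK+KCNQ block *and* avoid a slow
activation tail that stretches the AHP far beyond 15 ms.  The calibrated
KCNQ therefore operates on the exponential foot of its activation curve
(nominal midpoint far outside the physiological range; conductance grows
e-fold per ≈57 mV) with a fast time constant: within −70..+10 mV it acts
as a mildly voltage-sensitive background K⁺ conductance that responds
quickly and leaves no tail.  This is a deliberate phenomenological choice;
the channel's identity is carried by its published maximal conductance and
reversal and its functional role at rest.

## The BK Markov scheme

Ten states — closed C0–C4 and open O0–O4, the index counting bound Ca²⁺.
Horizontal transitions are sequential mass-action Ca²⁺ binding with site
multiplicity (4, 3, 2, 1 forward; 1, 2, 3, 4 backward); the open tier
binds with higher affinity (Kd_open < Kd_closed), which is what makes the
channel Ca²⁺-activated.  Vertical C_i↔O_i transitions carry the voltage
dependence, with the allosteric factor D = Kd_closed/Kd_open multiplying
the opening equilibrium once per bound Ca²⁺ — detailed balance around each
square of the scheme forces exactly this D.  The C4↔O4 pair additionally
carries a Ca²⁺-saturating factor applied symmetrically to both directions,
so that the transition depends on both voltage and Ca²⁺ without disturbing
the equilibrium.  The conducting open probability sums O1–O4; a
configuration switch (`include_o0`) restores the convention in which every
open state conducts.

The calibrated rates make BK deliberately slow (base vertical rate
a0 ≈ 4·10⁻³ ms⁻¹): its open probability accumulates over tens of
milliseconds during the dome, terminates the plateau, drives the final
repolarization, and its residual at the resting potential decays within a
few milliseconds of the Ca²⁺ tail — producing the ~5 mV, ~15 ms AHP.
Occupancies are integrated with automatic sub-stepping such that no
state's exit probability per substep exceeds 0.1, which keeps occupancies
in [0, 1] and conserves their sum to machine precision.

## Calcium shell

Ca²⁺ entering through CaT and CaL distributes instantly in a 0.1 µm
submembrane shell and relaxes mono-exponentially to a 150 nM baseline:

    d[Ca]ᵢ/dt = −i_Ca / (2 F d) − ([Ca]ᵢ − [Ca]ᵢ∞) / τ_r.

Two transcription points are resolved deliberately: the removal term is
written in its stabilizing orientation (a literal reading of the source
expression destabilizes the baseline), and the printed unit-conversion
factor of 1000 corresponds to reading the expression with depth in cm and
time in seconds; the implementation works in mM/ms with the depth
converted internally, which is numerically identical.  With no buffering
or SR handling, the shell transient is large (tens of µM); the Ca²⁺-gated
channels' half-saturations are calibrated on that scale.  τ_r ≈ 2.4 ms is
calibrated jointly with the AHP.  The Ca²⁺ reversal is fixed at +51 mV by
default; a Nernst-updating variant is switchable (`dynamic_eca`) since the
source is ambiguous about whether E_Ca was updated during spikes.

## Synaptic input

Three conductance time courses (single exponential, alpha, biexponential)
with the biexponential as standard; its normalization factor is computed
analytically from the peak time t_peak = t₀ + (τ_d τ_r/(τ_d−τ_r)) ln(τ_d/τ_r)
so the maximum equals g_max exactly (the printed normalization expression
is time-dependent and cannot serve as a constant amplitude factor).

The synaptic reversal potential is calibrated at −16.1 mV rather than the
0 mV typical of a purinergic cation conductance.  This is a lumped
effective value: with the printed conductance amplitudes and this cell's
input resistance, a 0 mV reversal would drive even a Ca²⁺-channel-blocked
cell past the L-type activation range, contradicting the reported result
that full CaT block abolishes the synaptic AP.  The lowered reversal makes
subthreshold purinergic depolarizations saturate below the CaL range, so
the CaT trigger is genuinely required — at the cost of representing
receptor desensitization and driving-force saturation only implicitly.

The published SD figures imply a much lower input resistance than the
published current-injection figures; both cannot hold at once in a single
cell.  The package keeps the current-injection behavior quantitative
(it is an acceptance-level readout) and demonstrates SD amplitude ordering
at proportionally scaled subthreshold conductances.

## Solver

Fixed-step forward Euler at 0.02 ms, matching the solver the model was
designed around; an identical-arithmetic compiled kernel (numba) executes
protocol runs, and a pure-numpy reference step is kept and held to exact
agreement by a consistency test.  Halving (indeed, tenfold-reducing) the
step changes the standard spike trajectory by less than 1 mV.  A step that
would move any compartment by more than 5 mV raises an instability error.
Voltage clamp is ideal: the command is followed exactly and no capacitive
current flows.

## Feature extraction

* RMP: mean over the pre-stimulus baseline.
* Threshold: voltage at the maximum of d²V/dt² on the upstroke, searched
  from where V has left the baseline by 3 mV (stimulus-onset artifacts are
  excluded); a 10 mV/ms dV/dt crossing is reported alongside.
* APD50: width at RMP + APA/2; width is also reported at an absolute level
  (−25 mV by default).
* AHP: depth of the post-spike minimum below RMP.  Because the return to
  rest is asymptotic, the duration is read with a resolution band: time
  from the first crossing below RMP until recovery to within 10% of the
  AHP depth of RMP.
* ADP: interior local maximum on the late repolarization, RMP-referenced
  (the source leaves the reference implicit).
* Foot curvature (cable work): mean second difference of V between 10%
  and 50% of the upstroke amplitude; negative = convex-upward (synaptic
  foot), positive = concave-upward (propagated foot).

## Calibration

The source's kinetic parameter tables live in an unavailable supplement,
so all gating parameters were calibrated against the printed whole-cell
readouts: the emergent −50 mV rest with 150 nM shell Ca²⁺; the 0.1 nA /
10 ms spike (peak +9.6 mV, 35 ms width at −25 mV, 5 mV / 15 ms AHP,
threshold ≈ −30 mV); exactly two spikes under 0.1 nA / 100 ms; the 20%
BK+KCNQ block response (+2 mV rest, +2.5 mV peak, broader spike); the
abolition of the synaptic AP by full CaT block; and the reference spike
configuration at −43 mV rest (amplitude 54 mV, APD50 37.4 ms).
Calibration used staged greedy pattern search on a weighted least-squares
objective, with the background-leak reversal solved at each step so the
rest sits exactly at −50 mV.  The achieved defaults: peak 9.59 mV, width
34.4 ms, AHP 4.98 mV / 15.1 ms, threshold −30.0 mV, block deltas
+2.01 / +2.50 mV.

The −43 mV-resting configuration reuses the same cell with three maximal
conductances shifted inside the ±20% physiological envelope (CaL +20%,
Kv1 −15%, BK −20%), a lower ambient ATP (more KATP availability) to set
the depolarized rest, and its own brief synaptic drive.

## Cable and strand

Long cells are chains of isopotential compartments coupled by
g = (π d²/4)/(R_i Δx) with sealed ends; the standard cable is 22.2 mm in
111 compartments (0.2 mm each).  Multicellular strands join abutting cell
ends through ohmic gap junctions (default 30 MΩ, 51 compartments per cell
for the three-cell topology; the figure-specific 111-compartment variant is
available through the same builder).  The reference space constant
(1.8 mm) and the one implied by the passive parameters (3.36 mm) are not
mutually consistent; both are reported by `cable_diagnostics` and the
geometry-derived value is used wherever a closed form is checked.  The
cable stimulus default (0.07 µS) is larger than the single-cell value
because a cable's input conductance is dominated by axial charge spread.

## Synthetic fixtures

Experimental overlays are not redistributable, so the fit machinery is
exercised against fixtures generated by simulating the model under the
relevant protocol and adding seeded Gaussian noise; zero noise reproduces
the clean simulation bit-for-bit, and the ground truth is returned with
the noisy points.  Passing fixture-based tests demonstrates the scoring
pipeline, not agreement with laboratory data.

## Problem sizes

Single-compartment protocol runs integrate 300–800 ms at dt = 0.02 ms
(1.5–4·10⁴ steps); convergence checks use dt = 0.002 ms; cable runs are
111–120 compartments for 120–600 ms; sweeps cover 5-point ±20% grids per
channel.  These sizes reproduce every reported readout and keep the full
suite fast.

## Known limitations

* No SR Ca²⁺ release/uptake, buffers, exchangers or pumps — the shell is a
  forcing function, and its unbuffered transient amplitude is accordingly
  large.
* SK's published reversal (−15 mV) makes apamin-like block *deepen* rather
  than reduce the AHP in this model; the published block figure is matched
  only in that SK touches the late phase exclusively.
* The KCNQ exponential-foot parameterization and the −16 mV effective
  synaptic reversal are phenomenological reconciliations of mutually
  inconsistent published readouts (see above).
* Kinetic parameters are calibrated, not measured; they are first-pass
  estimates exactly in the spirit of the original tuning, not channel-level
  measurements.
* Pacemaker-type APs, contractile coupling and 2-D/3-D syncytium topology
  are out of scope.
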