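# detrusor

A biophysically detailed simulator of the detrusor smooth muscle (urinary
bladder) action potential, for electrophysiologists and modelers studying
how bladder excitability — and its disorders, such as overactive bladder —
emerges from the interplay of ionic conductances.

The model is a single cylindrical smooth muscle cell whose membrane
potential obeys

    C_m dV/dt = −(I_CaL + I_CaT + I_Kv1 + I_KCNQ + I_BK + I_IK + I_SK
                  + I_KATP + I_h + I_leak) + I_inj + I_syn,

with eight Hodgkin–Huxley conductances

    I = ḡ · m(V,t)^x · h(V,t)^y · (V − E_rev),     dm/dt = (m∞(V) − m)/τ_m(V),
    m∞(V) = 1 / (1 + exp((V + V½)/S)),

a 10-state Markov BK channel (two tiers C0–C4 / O0–O4 of sequential Ca²⁺
binding with voltage-dependent opening; I_BK = ḡ_BK·(O1+O2+O3+O4)·(V−E_K)),
a submembrane Ca²⁺ shell

    d[Ca]ᵢ/dt = −i_Ca/(2Fd) − ([Ca]ᵢ − [Ca]ᵢ∞)/τ_r,

biexponential purinergic synaptic drive, and 1-D extensions: a
111-compartment cable (22.2 mm) and gap-junction-coupled cell strands.
The resting potential (≈ −50 mV) is emergent — no holding current is
injected.  Spikes are triggered either by current pulses or by synaptic
conductances; an analysis layer extracts spike morphology (peak, APA,
APD50, width at −25 mV, AHP, ADP, threshold), builds normalized I–V curves
from ideal voltage-clamp families, and scores fits against reference data
with the standard error of regression (good fit: S below 5% of the
reference range).

## A worked example

```bash
python examples/single_spike.py
```

prints, for the calibrated default cell,

```
standard 0.1 nA / 10 ms current-clamp spike
  resting potential      -50.00 mV   (emergent, no bias current)
  spike peak               9.59 mV
  amplitude (APA)         59.59 mV
  width at -25 mV         34.44 ms
  APD50                   32.07 ms
  AHP depth                4.98 mV
  AHP duration            15.06 ms
  threshold              -30.00 mV  (max d2V/dt2 on the upstroke)
  time to peak            17.66 ms
```

i.e. a brief 0.1 nA pulse depolarizes the cell from its −50 mV rest across
the ≈ −30 mV threshold; CaT triggers, CaL carries a ~35 ms spike dome
peaking near +9.6 mV, BK terminates the dome and leaves a ~5 mV
after-hyperpolarization that recovers within ~15 ms.  Other examples
reproduce the subthreshold spontaneous depolarizations and ADP/AHP-type
spike shapes (`synaptic_shapes.py`), voltage-clamp I–V validation
(`voltage_clamp_iv.py`), conductance-block pharmacology
(`channel_block.py`), ±20% robustness sweeps (`robustness_sweep.py`), and
regenerative propagation along cables and across gap junctions
(`cable_propagation.py`).

A thin CLI wraps the same machinery:

```bash
detrusor run-cc --out spike.csv && detrusor analyze spike.csv
detrusor run-vc --channel CaL --out iv.csv
detrusor run-cable --sites 11.1,15.5,19.9 --out cable.csv
```

Model configurations (channel kinetics, conductances, geometry, solver)
round-trip through YAML (`detrusor.load_config` / `save_config`); every
parameter carries a provenance tag distinguishing published values from
calibrated ones.  See `docs/methods.md` for the model's assumptions,
calibration procedure and known limitations.

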