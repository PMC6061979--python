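"""Spike-shape variety from the synaptic conductance time course.

Subthreshold purinergic inputs appear as spontaneous depolarizations (SDs)
whose amplitude follows the peak conductance; suprathreshold inputs trigger
spike-type APs whose late phase — after-depolarization (ADP) versus
after-hyperpolarization (AHP) — is set by the synaptic time course, one of
the proposed explanations for the striking AP shape variability of detrusor
smooth muscle.
"""

import detrusor as d
from detrusor.analysis import extract_ap_features
from detrusor.cell import StimulusProtocol, run_protocol, standard_synaptic_protocol
from detrusor.synapse import SynapseSpec

cfg = d.default_config()

print("subthreshold SDs (biexp, rise 5 ms / decay 50 ms):")
for gmax in (1e-3, 0.6e-3, 0.4e-3):
    syn = SynapseSpec(model="biexp", gmax=gmax, tau_rise=5.0, tau_decay=50.0,
                      onset=20.0)
    proto = StimulusProtocol(mode="synaptic", synapses=(syn,), duration=300.0,
                             settle=300.0)
    tr = run_protocol(proto, cfg)
    print(f"  gmax {gmax*1e3:5.2f} nS   SD amplitude {tr.v.max() - tr.v[0]:5.2f} mV")

print("\nsuprathreshold drives:")
drives = {
    "ADP-type (0.0095 uS, 15/25 ms)": standard_synaptic_protocol(),
    "AHP-type (0.006 uS, 5/12 ms)": standard_synaptic_protocol(
        gmax_uS=0.006, tau_rise=5.0, tau_decay=12.0
    ),
}
for label, proto in drives.items():
    f = extract_ap_features(run_protocol(proto, cfg))
    print(f"  {label}")
    print(f"    peak {f.v_max:6.2f} mV  APD50 {f.apd50:6.2f} ms  "
          f"ADP {f.adp_amplitude if f.adp_amplitude else 0:5.2f} mV  "
          f"AHP {f.ahp_amplitude if f.ahp_amplitude else 0:5.2f} mV")
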