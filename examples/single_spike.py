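"""Fire the standard current-clamp spike and read off its morphology.

A 0.1 nA, 10 ms rectangular pulse is injected into the resting detrusor
smooth muscle cell; the resulting spike-type action potential is reduced to
its standard features.  The peak (~+9.6 mV), width at -25 mV (~35 ms),
after-hyperpolarization (~5 mV for ~15 ms) and threshold (~-30 mV) are the
whole-cell readouts the default model was calibrated to reproduce.
"""

import detrusor as d
from detrusor.analysis import extract_ap_features
from detrusor.cell import run_protocol, standard_pulse_protocol

cfg = d.default_config()
trace = run_protocol(standard_pulse_protocol(), cfg)
f = extract_ap_features(trace)

print("standard 0.1 nA / 10 ms current-clamp spike")
print(f"  resting potential    {f.rmp:8.2f} mV   (emergent, no bias current)")
print(f"  spike peak           {f.v_max:8.2f} mV")
print(f"  amplitude (APA)      {f.apa:8.2f} mV")
print(f"  width at -25 mV      {f.width_at_level:8.2f} ms")
print(f"  APD50                {f.apd50:8.2f} ms")
print(f"  AHP depth            {f.ahp_amplitude:8.2f} mV")
print(f"  AHP duration         {f.ahp_duration:8.2f} ms")
print(f"  threshold            {f.threshold:8.2f} mV  (max d2V/dt2 on the upstroke)")
print(f"  time to peak         {f.time_to_peak:8.2f} ms")
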