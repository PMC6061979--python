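"""Voltage-clamp validation: I-V curves and the 5% goodness-of-fit rule.

An ideal clamp steps the cell from -90 mV through -70..+50 mV and the
L-type Ca2+ current's peak per step forms the normalized I-V relation; its
zero crossing sits at the configured Ca2+ reversal (+51 mV).  A noisy
synthetic reference (standing in for digitized experimental points) is then
scored with the standard error of regression: a fit is accepted when S is
below 5% of the reference's range.
"""

import numpy as np

import detrusor as d
from detrusor.analysis import build_iv_curve, fit_score
from detrusor.cell import run_voltage_clamp
from detrusor.fixtures import generate_fixture

cfg = d.default_config()
fam = run_voltage_clamp(np.arange(-70.0, 51.0, 10.0), cfg)
curve = build_iv_curve(fam, "CaL")

print("L-type Ca2+ normalized I-V (peak current per step):")
for v, i in zip(curve.voltages, curve.normalized):
    bar = "#" * int(round(30 * abs(i)))
    print(f"  {v:6.0f} mV  {i:+6.3f}  {bar}")
print(f"zero crossing: {curve.zero_crossing():.1f} mV (configured E_Ca = 51 mV)")

fx = generate_fixture("iv_points", cfg, noise_sd=0.02, seed=11, channel="CaL")
score = fit_score(fx.values, curve.normalized)
print(f"\nfit against noisy synthetic reference: S = {score.s:.4f} "
      f"(threshold {score.threshold:.4f}) -> {'good' if score.is_good else 'poor'}")
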