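"""Simulate one tea sample and extract its sensor features.

Builds a single synthetic observation (E-nose record + NIR reflectance
cube) for a mid-range polyphenol content, then prints a few of the 62
gas-sensor features and all 24 image features.
"""

import numpy as np

from teafuse import extract_enose_features, extract_hsi_features
from teafuse.simulate import simulate_cube, simulate_enose

rng = np.random.default_rng(0)
tp = 18.5  # polyphenol content, % dry mass

record = simulate_enose(tp, "Demo variety", rng, sample_id="demo")
cube = simulate_cube(tp, "Demo variety", rng)

enose = extract_enose_features(record)
print(f"E-nose features ({len(enose)} total) for TP = {tp}%")
for name in ("RSAV_f6", "RSAV_f1", "VAR_f6", "ADV_f6", "WM", "WA"):
    print(f"  {name:10s} = {enose[name]:.4f}")
print("RSAV_f6 is the steady-state plateau of the sulfur-organics sensor")
print("(W1W), the strongest responder; WM/WA summarize wavelet energy.\n")

hsi = extract_hsi_features(cube, (1106.0, 1375.0))
print(f"HSI wavelet features ({len(hsi)} total) at 1106 and 1375 nm:")
for name, val in hsi.items():
    print(f"  {name:12s} = {val:.3e}")
print("WE = detail sub-band energy (texture strength at that band),")
print("WEN = normalized entropy (how evenly that energy is spread).")
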