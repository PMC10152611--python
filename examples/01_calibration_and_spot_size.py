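"""Fit the laser calibration and determine the spectrometer spot size.

Builds a staircase-style calibration dataset (6 reference heights, 119
readouts, caliper noise), fits the raw-to-mm line, and then simulates
the square-scan procedure that measures the spectrometer's detection
spot diameter.
"""

import numpy as np

from vitroscan import determine_spot_size, fit_laser_calibration, raw_to_height, simulate_spot_scan

rng = np.random.default_rng(0)
heights = np.repeat(np.array([0.0, 5.0, 10.0, 20.0, 40.0, 60.0]), [20, 20, 20, 20, 20, 19])
raws = 19430 + heights / 0.01 + rng.normal(0, 5, heights.size)  # ~0.05 mm sensor noise
cal = fit_laser_calibration(list(zip(raws, heights)))
print(f"laser calibration: slope={cal.slope:.6f} mm/raw, zero plane raw={cal.zero_raw:.0f}")
print(f"fit quality: adj R2={cal.adj_r2:.6f}, MAE={cal.mae:.4f} mm")

h, valid = raw_to_height(cal, 21430.0)
print(f"a readout of 21430 maps to {float(h):.2f} mm above the surface (valid={bool(valid)})")

side = determine_spot_size(simulate_spot_scan(23.5))
print(f"detection spot size from the square scan: {side} mm")
# The spot diameter limits how point-specific a fluorescence reading is:
# anything within ~23 mm of the target contributes signal.
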