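"""Process a night-time chlorophyll fluorescence readout.

Renders a spectrometer readout with the 375 nm excitation leak and the
chlorophyll doublet, subtracts the mean dark current, masks 400-660 nm
and prints the F690/F730/F740 summary.
"""

from vitroscan import (
    default_scene,
    fluorescence_summary,
    mask_band,
    mean_dark,
    render_spectrum,
    subtract_dark,
)

scene = default_scene(seed=2)
darks = [render_spectrum(scene, False, excitation_amplitude=0.0) for _ in range(3)]
spec = render_spectrum(scene, has_plant_in_spot=True)

processed = mask_band(subtract_dark(spec, mean_dark(darks)))
res = fluorescence_summary(processed)

print(f"F690={res.F690:.0f}  F730={res.F730:.0f}  F740={res.F740:.0f} counts")
print(f"F690/F740 = {res.ratio_F690_F740:.3f}")
print(f"local-maximum quality flags: 690:{res.f690_is_local_max} "
      f"730:{res.f730_is_local_max} 740:{res.f740_is_local_max}")
# F690/F740 falls as chlorophyll content rises (reabsorption of the 690 nm
# band), making the ratio a per-explant stress/chlorophyll indicator.
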