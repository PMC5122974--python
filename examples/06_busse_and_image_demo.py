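"""Mask/test contrast combinations (winner-take-all) and image processing
through iso- versus pinwheel-pooling extra-striate cells.
"""
from encortex.experiments import ExperimentConfig, run_busse, run_image_demo

busse = run_busse(ExperimentConfig(seed=0))
curve = busse["curves"]["iso_narrow_en"]
print("EN iso unit, preferred mask fixed at 25% contrast, orthogonal test")
print(f"{'test c':>8}{'plaid':>8}{'test alone':>12}   (relative to the 25% output)")
for tc, pl, te in zip(curve["test_contrast"], curve["plaid"],
                      curve["test_alone"]):
    print(f"{tc:8.4f}{pl:8.3f}{te:12.3f}")
d = busse["diagnostics"]
print(f"\nwinner-take-all gap at 100% test: EN "
      f"{d['iso_narrow_en']['wta_gap_at_100']:.3f} vs FF "
      f"{d['iso_narrow_ff']['wta_gap_at_100']:.3f} -- the cortical "
      "suppression completes the winner-take-all")

demo = run_image_demo(ExperimentConfig(seed=0))
print(f"\nimage demo: bar-peak iso/pinwheel ratio "
      f"{demo['bar_peak_ratio_iso_over_pin']:.2f} (contours favour the "
      "iso pool)")
pp = demo["pattern_preference"]
print(f"rosette/bar preference: iso {pp['iso']:.2f} vs pinwheel "
      f"{pp['pinwheel']:.2f} (multi-orientation patterns favour the "
      "pinwheel pool)")
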