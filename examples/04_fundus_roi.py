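"""Fundus arm: frame registration, stacking and ROI intensity time course.

A fundus-like scene (bright optic disc, radiating particle-decorated axons)
is imaged as a jittered frame stack on three "days" with decaying signal.
Each day's stack is registered and averaged; four fixed quadrant ROIs two
disc diameters from the disc head give a per-day intensity ratio to day 0.
"""

from mitospread import PipelineConfig, run_invivo

cfg = PipelineConfig(seed=2, days=[0, 1, 7], decay_factors=[1.0, 0.9, 0.6],
                     n_frames=6, jitter_px_sd=2.0)
result = run_invivo(cfg)

print("day  intensity ratio to day 0")
for day, ratio in zip(result.roi_series.days,
                      result.roi_series.ratio_to_baseline):
    print(f"{day:3d}  {ratio:.3f}")

print("\nper-axon dispersion on the day-0 stacked image (pixel units):")
for axon, call in result.calls.items():
    print(f"  {axon}: {call.label}")

print("\nThe ratio series tracks the simulated signal decay (1.0, 0.9, "
      "0.6), and the\naxons analyzable at this resolution keep the uniform "
      "spacing signature.")
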