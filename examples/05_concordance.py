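"""Imaging-quality concordance: high resolution versus blurred + downsampled.

One synthetic axon scene is analyzed twice — at full resolution and after
Gaussian blur plus 4x downsampling (emulating a low-resolution fundus
modality). Particle positions recovered by the two routes are matched
against the ground truth within two low-res pixels.
"""

from mitospread import PipelineConfig, run_concordance

cfg = PipelineConfig(
    seed=1,
    scene=dict(pattern="uniform", density_per_um=0.2, area_mean_um2=1.0,
               area_sd_um2=0.2, psf_sigma_px=0.8, noise_sd=60.0),
    downsample=4, blur_sigma_px=2.0)
result = run_concordance(cfg)

print(f"particles (truth)        : {len(result.truth_positions_um)}")
print(f"recovered high / low res : {len(result.positions_hi_um)} / "
      f"{len(result.positions_lo_um)}")
print(f"match rate (±{result.tolerance_um:.1f} μm)    : "
      f"{result.match_rate:.2f}")
print(f"pattern call hi / lo     : {result.call_hi.label} / "
      f"{result.call_lo.label}")
print("\nA match rate near 1 with identical pattern calls shows the "
      "dispersion\nanalysis is robust to the resolution gap between the two "
      "imaging modalities.")
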