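"""Control versus fission: the morphometric signature of axonal injury.

Two groups of synthetic axons are analyzed end to end. In the injured
group, 21% of mitochondria split into two half-area daughters (dispersed
enough to be resolved). Fission raises linear density, lowers mean particle
area, conserves total area — and leaves the uniform spacing pattern intact.
"""

from collections import Counter

from mitospread import GroupSpec, PipelineConfig, run_invitro

cfg = PipelineConfig(
    seed=3,
    scene=dict(pattern="uniform", density_per_um=0.3, area_mean_um2=1.0,
               area_sd_um2=0.2, psf_sigma_px=0.8, noise_sd=60.0),
    groups={"control": GroupSpec(n_axons=6),
            "day7": GroupSpec(n_axons=6, split_prob=0.21,
                              fission_offset_um=1.1)},
)
result = run_invitro(cfg)

print(result.report.round(4).to_string(index=False))
calls = Counter(c.label for c in result.calls.values())
print(f"\npattern calls: {dict(calls)}")
dens = result.report[result.report.metric == "density_per_um"].iloc[0]
print(f"density ratio day7/control: "
      f"{dens['mean_day7'] / dens['mean_control']:.2f}")
print("\nDensity is higher and mean area lower in the fission group "
      "(rank-sum test),\nyet every axon in both groups is still called "
      "'uniform' — fission does not\ndisturb the spacing pattern.")
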