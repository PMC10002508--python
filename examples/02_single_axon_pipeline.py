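"""Full single-axon analysis: render, segment, project, measure, classify.

One synthetic axon scene is rendered with known ground truth, then pushed
through the imaging pipeline: Otsu binarization, connected-component
particle analysis, arc-length projection onto the axon trace, dispersion
sweep and morphometry. Recovered values are compared with the truth.
"""

import numpy as np

from mitospread import (
    SceneSpec, area_stats, binarize, classify_pattern, density,
    find_particles, id_curve, render_axon_scene, straighten_and_project,
)

spec = SceneSpec(pattern="uniform", density_per_um=0.4, area_mean_um2=1.0,
                 area_sd_um2=0.2, psf_sigma_px=0.8, noise_sd=60.0, seed=11)
scene = render_axon_scene(spec)
trace = spec.trace()

particles = find_particles(binarize(scene.image), spec.pixel_size_um)
projected = straighten_and_project(particles, trace)

curve = id_curve(projected.positions_um, trace.arc_length_um)
call = classify_pattern(curve)
stats = area_stats(projected.areas_um2)

print(f"axon length           : {trace.arc_length_um:.0f} μm")
print(f"particles (truth)     : {len(projected)} ({scene.truth.n})")
print(f"density (truth)       : {density(projected, trace):.3f} "
      f"({scene.truth.density_per_um:.3f}) per μm")
print(f"mean area (truth)     : {stats.mean_um2:.2f} "
      f"({scene.truth.areas_um2.mean():.2f}) μm²")
err = np.abs(projected.positions_um[:, None]
             - scene.truth.positions_um[None, :]).min(axis=1)
print(f"mean position error   : {err.mean() / spec.pixel_size_um:.2f} px")
print(f"distribution pattern  : {call.label} "
      f"(small-width Iδ = {call.small_width_mean_id:.2f})")
print("\nDensity, area and every particle position are recovered from the "
      "image;\nthe low small-width Iδ with a sigmoidal rise toward 1 is the "
      "signature of\nevenly spaced mitochondria.")
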