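# mitospread

Quantification of mitochondrial spatial organization along single
unmyelinated axons of retinal ganglion cells (RGCs), from fluorescence
microscopy images. Healthy RGC axons carry mitochondria at remarkably even
spacing; axonal injury (e.g. optic nerve crush, a model of traumatic or
glaucomatous optic neuropathy) triggers mitochondrial fission — more,
smaller mitochondria — and the question this toolkit answers is whether the
*spacing pattern* survives that remodelling. It is written for researchers
who image labelled mitochondria in axons (confocal flat mounts or scanning
laser ophthalmoscope fundus stacks) and need reproducible, scriptable
replacements for interactive particle analysis.

## What it computes

**The Morisita dispersion index.** An axon's arc length is tiled into
`q = ⌊L/w⌋` equal compartments of width `w`; with `xᵢ` mitochondria in
compartment `i` and `N = Σxᵢ`,

```
Iδ(w) = q · Σᵢ xᵢ(xᵢ − 1) / [ N(N − 1) ]
```

`Iδ = 0` when no compartment holds two particles, stays ≈1 for complete
spatial randomness at every scale, and rises toward `q` for clustering.
Sweeping `w` yields a curve whose shape identifies the pattern: evenly
spaced mitochondria give a low-`Iδ` start rising sigmoidally toward 1,
Poisson placement a flat curve at 1, clusters a peak above 1. A calibrated
numeric rule reduces each curve to a `uniform / random / clustered /
indeterminate` call.

**Around the statistic**, the package provides the full pipeline:

- `synthetic` — seeded scene generator with exact ground truth: axon scenes
  with lattice/Poisson/Neyman–Scott particle placement, a fission transform
  (count up, area down, total area conserved), fundus-like jittered frame
  stacks with signal decay, and nucleus-like counting fields;
- `imaging` — Otsu/fixed thresholding, 8-connected particle analysis with
  calibrated areas, arc-length projection onto a traced axon polyline,
  translation registration of frame stacks, fixed-ROI intensity series;
- `dispersion` — compartment counts, `Iδ`, width sweeps, cross-axon
  aggregation (mean ± SEM), pattern classification;
- `morphometry` — linear density, area histograms with skewness and excess
  kurtosis, two-group rank-sum comparisons;
- `pipeline` — configured end-to-end runs (`run_invitro`, `run_invivo`,
  `run_concordance`) writing tidy CSV/JSON plus the resolved config.

## Worked example

`examples/02_single_axon_pipeline.py` renders one synthetic axon and runs
the complete analysis:

```
axon length           : 204 μm
particles (truth)     : 80 (81)
density (truth)       : 0.392 (0.397) per μm
mean area (truth)     : 0.99 (0.98) μm²
mean position error   : 0.15 px
distribution pattern  : uniform (small-width Iδ = 0.36)
```

The pipeline recovered 80 of 81 rendered mitochondria, their linear density
and mean area to within ~1%, each position to ~0.15 pixel, and called the
spacing pattern uniform. The other examples cover the dispersion statistic
on canonical patterns (`01`), a control-versus-fission group study (`03`:
density up ×1.17, area down, pattern still uniform in 12/12 axons), the
fundus registration/ROI arm (`04`: intensity ratios 1.000/0.899/0.600
tracking a simulated decay of 1/0.9/0.6), and high-versus-degraded imaging
concordance (`05`: match rate 1.00).

A thin CLI mirrors the library:
`mitospread simulate|particles|project|dispersion|morpho|roi|invitro|invivo|concordance`.

## A note on the measured regime

At the measured control regime (≈1.2 mitochondria/μm, ≈4.3 μm² mean area)
the numbers are mutually incompatible with resolvable rendering: any
4.3 μm² particle spans ≥ 2.34 μm along the axon while the mean gap is
0.83 μm, so rendered neighbours physically coalesce and no segmentation can
separate them. Image-based demonstrations therefore use a sparser regime;
all position-level statistics (dispersion, fission arithmetic,
classification) are computed at the measured densities. See
`docs/methods.md` for the full discussion.
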