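"""Seeded synthetic scenes with known ground truth.

Emulates the imaging regimes the analysis pipeline is built for, so every
downstream stage can be tested against a known answer:

* single-axon fluorescence scenes — a smooth axon path decorated with
  elliptical mitochondria placed by a regular (jittered-lattice), Poisson, or
  Neyman–Scott clustered 1-D process at densities around 1.2 per μm and mean
  particle areas around 4.3 μm², then blurred, offset and noised;
* a fission transform that splits particles in two, conserving total area —
  the morphometric signature of axonal injury (count up, size down, spacing
  pattern preserved);
* fundus-like frame stacks with integer inter-frame jitter and a global
  intensity decay factor, for registration and ROI-photometry testing;
* nucleus-like fields of non-overlapping disks for particle counting.

All randomness flows from one seed through named substreams, so each stage
can be re-run independently and identical specs give bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
from scipy import ndimage, stats

from .errors import GeometryError, ParameterError, PlacementError
from .trace import AxonTrace

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "RenderedScene",
    "FundusSpec",
    "FundusScene",
    "substream",
    "sample_positions",
    "sample_areas",
    "render_axon_scene",
    "apply_fission",
    "render_fundus_stack",
    "render_nucleus_field",
]

INTENSITY_MAX = 65535  # writer dynamic range: 16-bit unsigned


def substream(seed: int, *keys: str) -> np.random.Generator:
    """A named, reproducible child stream of the master seed.

    Stage names are hashed (CRC-32) into the SeedSequence spawn key, so the
    stream for ("positions",) is independent of ("areas",) and stable across
    runs and platforms.
    """
    spawn = tuple(zlib.crc32(k.encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn))


@dataclass
class SceneSpec:
    """Full generative description of one synthetic axon scene.

    Defaults emulate the measured control regime of healthy RGC axons:
    density ~1.2 mitochondria per μm of arc length and mean particle area
    ~4.3 μm², imaged at 0.2 μm/pixel with mild Gaussian blur and noise.
    """

    image_shape: tuple[int, int] = (160, 1100)
    pixel_size_um: float = 0.2
    axon_control_points: tuple = ((80.0, 40.0), (80.0, 1060.0))
    pattern: str = "uniform"
    density_per_um: float = 1.2
    jitter_sd_um: float = 0.15
    cluster_rate_per_um: float = 0.05
    cluster_size_mean: float = 8.0
    cluster_sd_um: float = 1.0
    area_mean_um2: float = 4.3
    area_sd_um2: float = 1.5
    elongation: float = 2.0
    psf_sigma_px: float = 1.0
    foreground_level: float = 1200.0
    background_level: float = 100.0
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_per_um <= 0:
            raise ParameterError("density_per_um must be > 0")
        if self.area_mean_um2 <= 0:
            raise ParameterError("area_mean_um2 must be > 0")
        if self.elongation < 1:
            raise ParameterError("elongation (major/minor) must be >= 1")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if len(self.axon_control_points) < 2:
            raise GeometryError("axon path needs >= 2 control points")

    def trace(self) -> AxonTrace:
        return AxonTrace(np.asarray(self.axon_control_points, dtype=float),
                         self.pixel_size_um)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["axon_control_points"] = [list(p) for p in self.axon_control_points]
        return d


@dataclass
class GroundTruth:
    """Known particle truth for one rendered scene.

    All per-particle arrays are index-aligned and sorted by arc-length
    position; positions lie within [0, axon_length_um].
    """

    positions_um: np.ndarray
    centroids_px: np.ndarray
    areas_um2: np.ndarray
    axon_length_um: float

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.centroids_px = np.asarray(self.centroids_px,
                                       dtype=float).reshape(-1, 2)
        self.areas_um2 = np.asarray(self.areas_um2, dtype=float)
        n = len(self.positions_um)
        if not (len(self.centroids_px) == n == len(self.areas_um2)):
            raise ParameterError("per-particle arrays must be index-aligned")

    @property
    def n(self) -> int:
        return len(self.positions_um)

    @property
    def density_per_um(self) -> float:
        return self.n / self.axon_length_um


class RenderedScene(NamedTuple):
    image: np.ndarray           # uint16
    truth: GroundTruth
    clamp_fraction: float       # fraction of pixels clipped to the 16-bit range


def sample_positions(pattern: str, axon_length_um: float, *,
                     density_per_um: float | None = None,
                     jitter_sd_um: float = 0.0,
                     cluster_rate_per_um: float | None = None,
                     cluster_size_mean: float | None = None,
                     cluster_sd_um: float = 1.0,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> np.ndarray:
    """Sample sorted 1-D particle positions on [0, L] by a named process.

    ``uniform``
        Lattice at spacing 1/density with i.i.d. Gaussian jitter of sd
        ``jitter_sd_um``, reflected at the boundaries 0 and L so no point is
        lost and the density stays exact.
    ``random``
        Homogeneous Poisson process with rate ``density_per_um``.
    ``clustered``
        Neyman–Scott: Poisson parents at ``cluster_rate_per_um``, a
        Poisson(``cluster_size_mean``) offspring count per parent, Gaussian
        offspring offsets of sd ``cluster_sd_um``; offspring falling outside
        [0, L] are discarded.
    """
    if axon_length_um <= 0:
        raise ParameterError("axon_length_um must be > 0")
    if rng is None:
        rng = substream(0 if seed is None else seed, "positions")
    L = float(axon_length_um)

    if pattern == "uniform":
        if density_per_um is None or density_per_um <= 0:
            raise ParameterError("uniform pattern needs density_per_um > 0")
        spacing = 1.0 / density_per_um
        n = int(np.floor(L / spacing + 1e-9))
        pos = (np.arange(n) + 0.5) * spacing
        if jitter_sd_um > 0:
            pos = pos + rng.normal(0.0, jitter_sd_um, size=n)
            pos = _reflect(pos, L)
    elif pattern == "random":
        if density_per_um is None or density_per_um <= 0:
            raise ParameterError("random pattern needs density_per_um > 0")
        n = rng.poisson(density_per_um * L)
        pos = rng.uniform(0.0, L, size=n)
    elif pattern == "clustered":
        if not cluster_rate_per_um or cluster_rate_per_um <= 0:
            raise ParameterError("clustered pattern needs cluster_rate_per_um > 0")
        if not cluster_size_mean or cluster_size_mean <= 0:
            raise ParameterError("clustered pattern needs cluster_size_mean > 0")
        n_parents = rng.poisson(cluster_rate_per_um * L)
        parents = rng.uniform(0.0, L, size=n_parents)
        offspring = []
        for p in parents:
            k = rng.poisson(cluster_size_mean)
            offspring.append(p + rng.normal(0.0, cluster_sd_um, size=k))
        pos = np.concatenate(offspring) if offspring else np.empty(0)
        pos = pos[(pos >= 0.0) & (pos <= L)]
    else:
        raise ParameterError(f"unknown pattern {pattern!r}")
    return np.sort(pos)


def _reflect(x: np.ndarray, L: float) -> np.ndarray:
    """Fold positions into [0, L] by reflection at both boundaries."""
    x = np.mod(x, 2.0 * L)
    return np.where(x > L, 2.0 * L - x, x)


def sample_areas(n: int, mean_um2: float, sd_um2: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Truncated-normal (> 0) particle areas.

    Truncation at zero shifts the realized mean slightly above ``mean_um2``
    when sd is large relative to the mean; with the default scene parameters
    (mean 4.3, sd 1.5) the shift is negligible.
    """
    if sd_um2 <= 0:
        return np.full(n, float(mean_um2))
    a = (0.0 - mean_um2) / sd_um2
    return stats.truncnorm.rvs(a, np.inf, loc=mean_um2, scale=sd_um2,
                               size=n, random_state=rng)


def _ellipse_mask(shape, center, a_px, b_px, theta, subsample: int = 3):
    """Rasterize one filled ellipse by subpixel coverage.

    Coverage is estimated on a ``subsample`` × ``subsample`` grid within each
    pixel and thresholded at 50%, so the rasterized area tracks the analytic
    ellipse area to within roughly one perimeter's worth of pixels.
    """
    r0, c0 = center
    half_r = a_px + 1.5
    rmin = max(int(np.floor(r0 - half_r)), 0)
    rmax = min(int(np.ceil(r0 + half_r)) + 1, shape[0])
    cmin = max(int(np.floor(c0 - half_r)), 0)
    cmax = min(int(np.ceil(c0 + half_r)) + 1, shape[1])
    if rmin >= rmax or cmin >= cmax:
        return None, None
    offs = (np.arange(subsample) + 0.5) / subsample - 0.5
    rr = np.arange(rmin, rmax)[:, None] + offs[None, :]       # (R, s)
    cc = np.arange(cmin, cmax)[:, None] + offs[None, :]       # (C, s)
    dr = rr - r0
    dc = cc - c0
    ct, st = np.cos(theta), np.sin(theta)
    # rotate into ellipse frame; broadcast (R, s, 1, 1) x (1, 1, C, s)
    u = dr[:, :, None, None] * ct + dc[None, None, :, :] * st
    v = -dr[:, :, None, None] * st + dc[None, None, :, :] * ct
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    coverage = inside.mean(axis=(1, 3))
    return (slice(rmin, rmax), slice(cmin, cmax)), coverage >= 0.5


def render_axon_scene(spec: SceneSpec,
                      truth: GroundTruth | None = None) -> RenderedScene:
    """Render a synthetic axon scene and return it with its ground truth.

    Particles are drawn as filled ellipses centred on the path point at each
    sampled arc-length position, oriented along the local path tangent, with
    axes derived from the sampled area and the spec's elongation. A Gaussian
    PSF blur, constant background and additive Gaussian noise follow. The
    image is clamped to the 16-bit range and the clamped fraction reported.

    Passing a pre-built ``truth`` (e.g. after :func:`apply_fission`) renders
    exactly those particles instead of sampling new ones.
    """
    trace = spec.trace()
    L = trace.arc_length_um
    if truth is None:
        pos = sample_positions(
            spec.pattern, L,
            density_per_um=spec.density_per_um,
            jitter_sd_um=spec.jitter_sd_um,
            cluster_rate_per_um=spec.cluster_rate_per_um,
            cluster_size_mean=spec.cluster_size_mean,
            cluster_sd_um=spec.cluster_sd_um,
            rng=substream(spec.seed, "positions"))
        areas = sample_areas(len(pos), spec.area_mean_um2, spec.area_sd_um2,
                             substream(spec.seed, "areas"))
        truth = GroundTruth(positions_um=pos,
                            centroids_px=trace.point_at(pos),
                            areas_um2=areas, axon_length_um=L)

    img = np.full(spec.image_shape, float(spec.background_level))
    for s_um, (r0, c0), area in zip(truth.positions_um, truth.centroids_px,
                                    truth.areas_um2):
        # area = pi * a * b with a/b = elongation
        a_um = np.sqrt(area * spec.elongation / np.pi)
        b_um = a_um / spec.elongation
        tan = trace.tangent_at(float(s_um))
        theta = float(np.arctan2(tan[1], tan[0]))
        box, mask = _ellipse_mask(spec.image_shape, (r0, c0),
                                  a_um / spec.pixel_size_um,
                                  b_um / spec.pixel_size_um, theta)
        if box is not None:
            img[box][mask] = spec.background_level + spec.foreground_level
    if spec.psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma_px)
    if spec.noise_sd > 0:
        img = img + substream(spec.seed, "noise").normal(
            0.0, spec.noise_sd, size=img.shape)
    clamped = (img < 0) | (img > INTENSITY_MAX)
    clamp_fraction = float(clamped.mean())
    img = np.clip(img, 0, INTENSITY_MAX)
    return RenderedScene(image=img.astype(np.uint16), truth=truth,
                         clamp_fraction=clamp_fraction)


def apply_fission(truth: GroundTruth, split_prob: float,
                  seed: int = 0, *, elongation: float = 2.0,
                  offset_um: float | None = None,
                  trace: AxonTrace | None = None) -> GroundTruth:
    """Split particles in two to emulate injury-induced mitochondrial fission.

    Each particle independently splits with probability ``split_prob`` into
    two daughters of exactly half the parent area, placed symmetrically at
    ± ``offset_um`` about the parent position. The default offset is one
    quarter of the parent's major-axis length — daughters stay inside the
    parent's footprint, preserving local spacing statistics. A larger
    explicit offset emulates post-fission dispersal of the daughters (in-
    place daughters physically abut, so only a dispersed pair is resolvable
    as two objects in a rendered image). Total area is conserved exactly;
    the expected count scales by (1 + split_prob).

    Daughter centroids are recomputed from ``trace`` when given, otherwise by
    monotone interpolation along the parent centroid track.
    """
    if not 0.0 <= split_prob <= 1.0:
        raise ParameterError("split_prob must lie in [0, 1]")
    rng = substream(seed, "fission")
    split = rng.random(truth.n) < split_prob
    L = truth.axon_length_um

    pos_out, area_out = [], []
    for p, area, s in zip(truth.positions_um, truth.areas_um2, split):
        if s:
            major_um = 2.0 * np.sqrt(area * elongation / np.pi)
            off = major_um / 4.0 if offset_um is None else offset_um
            pos_out.extend((np.clip(p - off, 0, L), np.clip(p + off, 0, L)))
            area_out.extend((area / 2.0, area / 2.0))
        else:
            pos_out.append(p)
            area_out.append(area)
    pos_out = np.asarray(pos_out)
    area_out = np.asarray(area_out)
    order = np.argsort(pos_out, kind="stable")
    pos_out, area_out = pos_out[order], area_out[order]

    if trace is not None:
        cent = trace.point_at(pos_out)
    elif truth.n >= 2:
        cent = np.stack([
            np.interp(pos_out, truth.positions_um, truth.centroids_px[:, 0]),
            np.interp(pos_out, truth.positions_um, truth.centroids_px[:, 1]),
        ], axis=-1)
    else:
        cent = np.repeat(truth.centroids_px, 2 if split.any() else 1, axis=0)
    return GroundTruth(positions_um=pos_out, centroids_px=cent,
                       areas_um2=area_out, axon_length_um=L)


@dataclass
class FundusSpec:
    """Generative description of a fundus-like scene, in pixel units only.

    The ophthalmoscope modality reports pixel sizes, not physical lengths, so
    everything here is pixel-calibrated: a bright optic-disc region with
    axon paths radiating from it, each decorated with particle dots.
    """

    image_shape: tuple[int, int] = (600, 800)
    disc_center_px: tuple[float, float] = (300.0, 400.0)
    disc_radius_px: float = 40.0
    n_axons: int = 8
    axon_length_px: float = 250.0
    pattern: str = "uniform"
    density_per_px: float = 0.08
    jitter_sd_px: float = 1.2
    dot_area_px2: float = 12.0
    dot_area_sd_px2: float = 3.0
    elongation: float = 1.5
    psf_sigma_px: float = 1.2
    disc_level: float = 3000.0
    foreground_level: float = 1500.0
    background_level: float = 150.0
    noise_sd: float = 40.0
    seed: int = 0


@dataclass
class FundusScene:
    """A rendered fundus frame stack plus everything needed to verify it."""

    frames: np.ndarray                 # (n_frames, rows, cols) uint16
    true_shifts_px: list[tuple[int, int]]
    base_image: np.ndarray             # noiseless, unshifted float image
    axon_traces: list[AxonTrace]       # pixel-calibrated (pixel_size 1)
    axon_positions_px: list[np.ndarray]


def _render_fundus_base(spec: FundusSpec):
    """Noiseless fundus scene: optic disc plus radiating decorated axons."""
    shape = spec.image_shape
    img = np.full(shape, float(spec.background_level))
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    disc = ((rr - spec.disc_center_px[0]) ** 2
            + (cc - spec.disc_center_px[1]) ** 2) <= spec.disc_radius_px ** 2
    img[disc] = spec.disc_level

    traces, positions = [], []
    rng_geom = substream(spec.seed, "fundus-geometry")
    angles = (np.arange(spec.n_axons) / spec.n_axons * 2 * np.pi
              + rng_geom.uniform(0, 2 * np.pi / spec.n_axons))
    for i, ang in enumerate(angles):
        d = np.array([np.cos(ang), np.sin(ang)])
        start = np.asarray(spec.disc_center_px) + d * (spec.disc_radius_px + 5)
        end = start + d * spec.axon_length_px
        trace = AxonTrace(np.vstack([start, end]), pixel_size_um=1.0)
        pos = sample_positions(
            spec.pattern, trace.arc_length_um,
            density_per_um=spec.density_per_px,
            jitter_sd_um=spec.jitter_sd_px,
            rng=substream(spec.seed, "fundus-positions", str(i)))
        areas = sample_areas(len(pos), spec.dot_area_px2, spec.dot_area_sd_px2,
                             substream(spec.seed, "fundus-areas", str(i)))
        for s, area in zip(pos, areas):
            center = trace.point_at(float(s))
            a_px = np.sqrt(area * spec.elongation / np.pi)
            theta = float(np.arctan2(d[1], d[0]))
            box, mask = _ellipse_mask(shape, center, a_px,
                                      a_px / spec.elongation, theta)
            if box is not None:
                img[box][mask] = spec.background_level + spec.foreground_level
        # keep only axons fully inside the frame for downstream analysis
        if (0 <= end[0] < shape[0]) and (0 <= end[1] < shape[1]):
            traces.append(trace)
            positions.append(pos)
    if spec.psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, spec.psf_sigma_px)
    return img, traces, positions


def render_fundus_stack(spec: FundusSpec, n_frames: int = 20,
                        jitter_px_sd: float = 2.0, decay_factor: float = 1.0,
                        seed: int | None = None) -> FundusScene:
    """Render a jittered, decayed frame stack of one fundus scene.

    Frame 0 carries zero shift; every later frame is translated by an
    integer shift drawn from a rounded Normal(0, ``jitter_px_sd``) and all
    frames are scaled by ``decay_factor`` (0 < factor <= 1), emulating the
    post-injury fluorescence loss across days. True shifts are returned for
    registration testing.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    if not 0 < decay_factor <= 1:
        raise ParameterError("decay_factor must lie in (0, 1]")
    seed = spec.seed if seed is None else seed
    base, traces, positions = _render_fundus_base(spec)
    rng_shift = substream(seed, "fundus-shifts")
    rng_noise = substream(seed, "fundus-noise")
    frames = np.empty((n_frames,) + spec.image_shape, dtype=np.uint16)
    shifts: list[tuple[int, int]] = []
    scaled = base * decay_factor
    for i in range(n_frames):
        if i == 0 or jitter_px_sd == 0:
            dr = dc = 0
        else:
            dr, dc = np.round(rng_shift.normal(0, jitter_px_sd, 2)).astype(int)
        moved = ndimage.shift(scaled, (dr, dc), order=0,
                              cval=spec.background_level * decay_factor)
        if spec.noise_sd > 0:
            moved = moved + rng_noise.normal(0, spec.noise_sd, moved.shape)
        frames[i] = np.clip(moved, 0, INTENSITY_MAX).astype(np.uint16)
        shifts.append((int(dr), int(dc)))
    return FundusScene(frames=frames, true_shifts_px=shifts, base_image=base,
                       axon_traces=traces, axon_positions_px=positions)


def render_nucleus_field(n_cells: int, image_shape=(1024, 1024),
                         radius_px: float = 6.0, seed: int = 0, *,
                         min_sep_px: float | None = None,
                         foreground_level: float = 2000.0,
                         background_level: float = 100.0,
                         noise_sd: float = 20.0,
                         max_tries_per_cell: int = 2000):
    """Non-overlapping bright disks on a dark field, for counting tests.

    Disk centres are placed by rejection sampling with a minimum separation
    (default: 2·radius + 2 px). Raises :class:`PlacementError` when the
    request exceeds packing feasibility after bounded retries.

    Returns ``(image, centers_px, n_cells)``.
    """
    if n_cells < 0:
        raise ParameterError("n_cells must be >= 0")
    rng = substream(seed, "nuclei")
    sep = (2 * radius_px + 2.0) if min_sep_px is None else min_sep_px
    margin = radius_px + 2
    centers: list[np.ndarray] = []
    for _ in range(n_cells):
        for attempt in range(max_tries_per_cell):
            cand = rng.uniform([margin, margin],
                               [image_shape[0] - margin,
                                image_shape[1] - margin])
            if all(np.hypot(*(cand - c)) >= sep for c in centers):
                centers.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place disk {len(centers) + 1} of {n_cells} "
                f"after {max_tries_per_cell} tries")
    img = np.full(image_shape, float(background_level))
    rr, cc = np.ogrid[: image_shape[0], : image_shape[1]]
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px ** 2] = (
            background_level + foreground_level)
    if noise_sd > 0:
        img = img + rng.normal(0, noise_sd, img.shape)
    img = np.clip(img, 0, INTENSITY_MAX).astype(np.uint16)
    return img, np.asarray(centers).reshape(-1, 2), n_cells
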