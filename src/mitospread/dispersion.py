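"""Morisita Iδ dispersion analysis of 1-D point patterns along axons.

The axon's arc length is tiled with ``q`` equal compartments (quadrats) of
width ``w``; with ``x_i`` particles in compartment ``i`` and ``N = Σ x_i``,
the Morisita index of dispersion is

    Iδ = q · Σ x_i (x_i − 1) / [ N (N − 1) ]

Iδ equals 0 when no compartment holds more than one particle (perfectly even
at that scale), stays near 1 for complete spatial randomness at every scale,
and rises above 1 — up to ``q`` — for clustered counts. Sweeping ``w`` yields
a curve whose shape distinguishes the patterns: evenly spaced particles give
an Iδ-versus-width curve that starts near 0 and rises sigmoidally toward 1,
random placement gives a flat curve at 1, and clustering gives values above 1
at widths near the cluster scale.

Mitochondria in healthy unmyelinated retinal-ganglion-cell axons show the
uniform signature; this module provides the statistic, the width sweep,
cross-axon aggregation, and a declared numeric rule that reduces a curve to
a uniform/random/clustered call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "CompartmentCounts",
    "IdCurve",
    "AggregateCurve",
    "PatternCall",
    "compartmentalize",
    "id_index",
    "id_index_from_counts",
    "id_curve",
    "aggregate_curves",
    "classify_pattern",
    "DEFAULT_WIDTHS_UM",
    "DEFAULT_WIDTHS_PX",
    "MIN_AXON_LENGTH_PX",
]

#: Default compartment-width sweep for physically calibrated (μm) data.
DEFAULT_WIDTHS_UM = np.arange(2.0, 51.0, 2.0)

#: Default sweep for pixel-calibrated fundus data (no μm calibration).
DEFAULT_WIDTHS_PX = np.arange(4.0, 101.0, 4.0)

#: Minimum analyzable axon length for pixel-calibrated fundus data.
MIN_AXON_LENGTH_PX = 120.0


@dataclass(frozen=True)
class CompartmentCounts:
    """Quadrat counts for one compartment width.

    ``q = floor(L / w)`` equal half-open compartments ``[k·w, (k+1)·w)``
    anchored at position 0; the trailing partial compartment is discarded
    (the index assumes equal quadrat sizes) and positions falling there are
    tallied in ``n_dropped``.
    """

    width_um: float
    q: int
    counts: np.ndarray
    n_dropped: int

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class IdCurve:
    """Iδ over an ascending grid of compartment widths.

    Widths where the index is undefined (fewer than two particles in the
    tiled region) carry NaN and are flagged in ``defined``; they are never
    interpolated.
    """

    widths_um: np.ndarray
    id_values: np.ndarray
    q: np.ndarray
    n: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.id_values)


@dataclass
class AggregateCurve:
    """Per-width mean ± SEM of several IdCurves sharing one width grid.

    ``sem_id`` is NaN (flagged) where fewer than two curves define Iδ;
    ``n_curves`` reports how many curves contributed at each width.
    """

    widths_um: np.ndarray
    mean_id: np.ndarray
    sem_id: np.ndarray
    n_curves: np.ndarray


@dataclass
class PatternCall:
    """A uniform/random/clustered/indeterminate call with its provenance.

    The call is reproducible from the stored curve statistics and rule
    parameters: ``small_width_mean_id`` is the mean Iδ over the smallest
    ``small_band`` defined widths, compared against 1 ± ``delta``.
    """

    label: str
    small_width_mean_id: float
    delta: float
    small_band: int
    monotone_tol: float
    reason: str = ""


def compartmentalize(positions_um, axon_length_um: float,
                     width_um: float) -> CompartmentCounts:
    """Bin sorted 1-D positions into equal half-open compartments.

    Parameters
    ----------
    positions_um
        Sorted positions within [0, axon_length_um].
    axon_length_um
        Total arc length L of the axon.
    width_um
        Compartment width w, 0 < w <= L.

    Raises
    ------
    ParameterError
        If w is outside (0, L] or positions violate their contract.
    """
    pos = np.asarray(positions_um, dtype=float)
    if not 0 < width_um <= axon_length_um:
        raise ParameterError(
            f"width {width_um} outside (0, {axon_length_um}]")
    if pos.size and (np.any(np.diff(pos) < 0)):
        raise ParameterError("positions must be sorted ascending")
    if pos.size and (pos[0] < 0 or pos[-1] > axon_length_um):
        raise ParameterError("positions must lie within [0, axon length]")
    q = int(np.floor(axon_length_um / width_um))
    in_range = pos < q * width_um
    idx = np.floor(pos[in_range] / width_um).astype(int)
    counts = np.bincount(idx, minlength=q)
    return CompartmentCounts(width_um=float(width_um), q=q, counts=counts,
                             n_dropped=int(pos.size - in_range.sum()))


def id_index_from_counts(counts) -> float:
    """Morisita Iδ from raw quadrat counts.

    Numerator and denominator are accumulated in exact integer arithmetic;
    only the final ratio is a float. Returns NaN when N < 2 (undefined).
    """
    x = [int(c) for c in np.asarray(counts).ravel()]
    if any(c < 0 for c in x):
        raise ParameterError("counts must be non-negative integers")
    q = len(x)
    n_total = sum(x)
    if n_total < 2:
        return float("nan")
    num = q * sum(c * (c - 1) for c in x)
    den = n_total * (n_total - 1)
    return num / den


def id_index(cc: CompartmentCounts) -> float:
    """Iδ of one set of compartment counts (NaN when fewer than 2 counts)."""
    return id_index_from_counts(cc.counts)


def id_curve(positions_um, axon_length_um: float, width_grid=None) -> IdCurve:
    """Sweep Iδ over a grid of compartment widths.

    Widths exceeding the axon length, or yielding N < 2, are flagged NaN;
    the sweep never aborts on a single width.
    """
    widths = DEFAULT_WIDTHS_UM if width_grid is None else np.asarray(
        width_grid, dtype=float)
    if widths.size == 0 or np.any(np.diff(widths) <= 0):
        raise ParameterError("width grid must be non-empty and ascending")
    values = np.full(widths.shape, np.nan)
    qs = np.zeros(widths.shape, dtype=int)
    ns = np.zeros(widths.shape, dtype=int)
    for i, w in enumerate(widths):
        if w > axon_length_um:
            continue
        cc = compartmentalize(positions_um, axon_length_um, w)
        qs[i], ns[i] = cc.q, cc.n_total
        values[i] = id_index(cc)
    return IdCurve(widths_um=widths, id_values=values, q=qs, n=ns)


def aggregate_curves(curves) -> AggregateCurve:
    """Mean ± SEM per width over curves sharing one width grid.

    Undefined (NaN) entries are excluded per width; the number of curves
    actually used at each width is reported. SEM uses the n−1 variance and
    is NaN-flagged where fewer than two curves contribute.
    """
    if not curves:
        raise ParameterError("need at least one curve")
    widths = curves[0].widths_um
    for c in curves[1:]:
        if not np.allclose(c.widths_um, widths):
            raise ParameterError("curves must share one width grid")
    stack = np.vstack([c.id_values for c in curves])
    defined = ~np.isnan(stack)
    n = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nanmean(np.where(defined, stack, np.nan),
                                          axis=0), np.nan)
    sem = np.full(widths.shape, np.nan)
    for j in range(len(widths)):
        if n[j] >= 2:
            vals = stack[defined[:, j], j]
            sem[j] = vals.std(ddof=1) / np.sqrt(n[j])
    return AggregateCurve(widths_um=widths, mean_id=mean, sem_id=sem,
                          n_curves=n)


#: Half-width of the "random" band around Iδ = 1, calibrated by simulation:
#: at densities 1.2–1.5/μm on 200 μm axons with a 2–50 μm width sweep,
#: complete spatial randomness keeps the small-band mean Iδ above 0.89
#: (min of 400 Monte-Carlo draws) while jittered lattices — with or without
#: a 21% fission transform — stay below 0.87. delta = 0.12 puts the
#: uniform/random boundary in that gap.
DEFAULT_DELTA = 0.12


def classify_pattern(curve: IdCurve, delta: float = DEFAULT_DELTA,
                     small_band: int = 3,
                     monotone_tol: float = 0.1) -> PatternCall:
    """Reduce an Iδ-versus-width curve to a distribution-pattern call.

    Let m be the mean Iδ over the ``small_band`` smallest defined widths.
    The call is ``clustered`` if m > 1 + delta, ``random`` if |m − 1| <=
    delta, and ``uniform`` if m < 1 − delta *and* the curve is non-decreasing
    toward 1 across the grid within ``monotone_tol`` (the sigmoidal rise of
    an even pattern); a low m without that monotone rise is ``indeterminate``.

    The defaults (delta per :data:`DEFAULT_DELTA`, band of 3, tolerance 0.1)
    are a declared convention calibrated by simulation against the package's
    reference processes; no published numeric rule exists for reading these
    curves. At small compartment widths that hold several particles even an
    ideal lattice scores Iδ ≈ (m−1)/m rather than 0, so the boundary must
    sit well below 1 yet above the lattice band — hence the calibration.
    """
    defined_idx = np.flatnonzero(curve.defined)
    if len(defined_idx) < small_band:
        return PatternCall("indeterminate", float("nan"), delta, small_band,
                           monotone_tol,
                           reason=f"only {len(defined_idx)} defined widths")
    band = defined_idx[:small_band]
    m = float(curve.id_values[band].mean())
    if m > 1 + delta:
        label, reason = "clustered", "small-width Iδ above 1 + delta"
    elif m >= 1 - delta:
        label, reason = "random", "small-width Iδ within 1 ± delta"
    else:
        vals = curve.id_values[defined_idx]
        if np.all(np.diff(vals) >= -monotone_tol):
            label, reason = "uniform", "low small-width Iδ, monotone rise"
        else:
            label = "indeterminate"
            reason = "low small-width Iδ but non-monotone curve"
    return PatternCall(label, m, delta, small_band, monotone_tol, reason)
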