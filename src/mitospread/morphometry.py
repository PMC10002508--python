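"""Density, per-particle area statistics, and group comparisons.

Mitochondrial fission leaves a characteristic morphometric triad: linear
density (count per μm of axon) rises, mean particle area falls, and the area
histogram grows a heavier small-area mode — higher kurtosis and skewness —
while total area is conserved. This module computes those quantities per
axon and compares groups with a rank-sum test.

Moment conventions: skewness = m3 / m2^(3/2) and kurtosis = m4 / m2^2 − 3
(excess, so a normal sample scores ~0), both from raw (biased) central
moments of the unbinned areas. SEM uses the n−1 variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .imaging import ParticleSet
from .trace import AxonTrace

__all__ = [
    "AxonSummary",
    "AreaHistogram",
    "density",
    "summarize_axon",
    "area_stats",
    "compare_groups",
    "percent_reduction",
]


@dataclass
class AxonSummary:
    """Per-axon morphometry record."""

    axon_id: str
    n_particles: int
    axon_length_um: float
    density_per_um: float
    mean_area_um2: float
    group: str = ""


@dataclass
class AreaHistogram:
    """Area histogram plus moments of the raw (unbinned) areas.

    ``skewness`` and ``kurtosis_excess`` are NaN-flagged when undefined:
    degenerate (zero-variance) samples, or fewer than 4 particles for the
    kurtosis. ``sem`` is NaN for a single particle.
    """

    bin_edges_um2: np.ndarray
    counts: np.ndarray
    n: int
    mean_um2: float
    sem_um2: float
    skewness: float
    kurtosis_excess: float
    degenerate: bool = False


def density(particles: ParticleSet, trace: AxonTrace) -> float:
    """Linear density: particle count per μm of axon arc length."""
    L = trace.arc_length_um
    if L <= 0:
        raise ParameterError("trace has zero length")
    return len(particles) / L


def summarize_axon(axon_id: str, particles: ParticleSet, trace: AxonTrace,
                   group: str = "") -> AxonSummary:
    n = len(particles)
    return AxonSummary(
        axon_id=axon_id, n_particles=n, axon_length_um=trace.arc_length_um,
        density_per_um=density(particles, trace),
        mean_area_um2=float(particles.areas_um2.mean()) if n else float("nan"),
        group=group)


def area_stats(areas_um2, bins="auto") -> AreaHistogram:
    """Histogram, mean ± SEM, skewness and excess kurtosis of areas.

    Moments are computed on the raw areas, never on binned values. Requests
    the sample cannot support are flagged NaN rather than returned as zero:
    the SEM needs n >= 2, the skewness n >= 3 and non-zero variance, the
    kurtosis n >= 4.
    """
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size < 1:
        raise ParameterError("need at least one particle")
    counts, edges = np.histogram(areas, bins=bins)
    n = areas.size
    mean = float(areas.mean())
    sem = float(areas.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    m2 = float(np.mean((areas - mean) ** 2))
    degenerate = m2 == 0.0
    if degenerate or n < 3:
        skew = float("nan")
    else:
        skew = float(stats.skew(areas, bias=True))
    if degenerate or n < 4:
        kurt = float("nan")
    else:
        kurt = float(stats.kurtosis(areas, fisher=True, bias=True))
    return AreaHistogram(bin_edges_um2=edges, counts=counts, n=n,
                         mean_um2=mean, sem_um2=sem, skewness=skew,
                         kurtosis_excess=kurt, degenerate=degenerate)


def compare_groups(summaries_by_group: dict, metrics=("density_per_um",
                                                      "mean_area_um2")
                   ) -> pd.DataFrame:
    """Two-group morphometry comparison via the Mann–Whitney U test.

    Takes exactly two groups of per-axon summaries (each with >= 3 axons) and
    returns, per metric, group means ± SEM, the rank-sum U statistic, the
    two-sided p-value and the effect direction. No multiple-comparison
    correction is applied (documented, deliberate).
    """
    if len(summaries_by_group) != 2:
        raise ParameterError("compare_groups takes exactly two groups")
    (name_a, grp_a), (name_b, grp_b) = summaries_by_group.items()
    for name, grp in ((name_a, grp_a), (name_b, grp_b)):
        if len(grp) < 3:
            raise ParameterError(f"group {name!r} needs >= 3 axons")
    rows = []
    for metric in metrics:
        a = np.array([getattr(s, metric) for s in grp_a], dtype=float)
        b = np.array([getattr(s, metric) for s in grp_b], dtype=float)
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({
            "metric": metric,
            f"mean_{name_a}": a.mean(),
            f"sem_{name_a}": a.std(ddof=1) / np.sqrt(len(a)),
            f"mean_{name_b}": b.mean(),
            f"sem_{name_b}": b.std(ddof=1) / np.sqrt(len(b)),
            "U": float(u),
            "p_two_sided": float(p),
            "direction": (f"{name_a} > {name_b}" if a.mean() > b.mean()
                          else f"{name_a} < {name_b}" if a.mean() < b.mean()
                          else "equal"),
        })
    return pd.DataFrame(rows)


def percent_reduction(mean_before: float, mean_after: float) -> float:
    """Percent reduction of a group mean, e.g. surviving-cell counts.

    Returns 100 · (before − after) / before.
    """
    if mean_before <= 0:
        raise ParameterError("baseline mean must be > 0")
    return 100.0 * (mean_before - mean_after) / mean_before
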