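"""Pairwise geodesic distance and cooccurrence potential.

Two animals' smoothed paths, evaluated on the shared refined time grid over
the overlap of their monitoring domains, yield a per-hour WGS84 geodesic
distance series.  The *cooccurrence potential* is a Gaussian KDE over the
grid times at which that distance is below a threshold delta (1800 m by
default): a density of opportunities for interaction rather than a count of
close fixes, which makes it robust to movement between fixes at the raw
sampling resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NoOverlapError, ParameterError
from .geodesy import geodesic_distance
from .smoothing import SplineModel, TimeDensity, estimate_time_density, refined_grid

#: Default cooccurrence distance threshold (m)
DEFAULT_DELTA = 1800.0


@dataclass
class DistanceSeries:
    """Geodesic distance (m) between a pair on the shared overlap grid."""

    pair: tuple[str, str]
    times: np.ndarray
    dist_m: np.ndarray


@dataclass
class CooccurrenceResult:
    """Times within ``delta`` and their density.

    ``potential`` is ``None`` (explicitly absent) when the pair never came
    within ``delta`` on the grid — zero cooccurrence, not a zero density.
    """

    pair: tuple[str, str]
    delta_m: float
    co_times: np.ndarray
    potential: TimeDensity | None


def overlap_grid(domain_a: tuple[float, float], domain_b: tuple[float, float],
                 resolution_minutes: float = 60.0) -> np.ndarray:
    """Shared refined grid on the intersection of two monitoring domains."""
    lo = max(domain_a[0], domain_b[0])
    hi = min(domain_a[1], domain_b[1])
    if not lo < hi:
        raise NoOverlapError(
            f"domains {domain_a} and {domain_b} do not overlap")
    grid = refined_grid((lo, hi), resolution_minutes)
    if len(grid) < 2:
        raise NoOverlapError(
            f"domains {domain_a} and {domain_b} share fewer than two grid "
            "points at the requested resolution")
    return grid


def distance_series(model_a: SplineModel, model_b: SplineModel,
                    resolution_minutes: float = 60.0) -> DistanceSeries:
    """Per-time geodesic distance between two smoothed paths.

    Both models are evaluated on the shared global grid restricted to the
    overlap of their domains; the result is symmetric in the pair order.
    """
    grid = overlap_grid(model_a.domain, model_b.domain, resolution_minutes)
    lon_a, lat_a = model_a.positions(grid)
    lon_b, lat_b = model_b.positions(grid)
    d = geodesic_distance(lon_a, lat_a, lon_b, lat_b)
    return DistanceSeries((model_a.animal_id, model_b.animal_id), grid, d)


def cooccurrence_potential(dist: DistanceSeries,
                           delta_m: float = DEFAULT_DELTA,
                           bandwidth="auto") -> CooccurrenceResult:
    """KDE over grid times with distance strictly below ``delta_m``."""
    if delta_m <= 0:
        raise ParameterError("cooccurrence threshold delta must be positive")
    co_times = dist.times[dist.dist_m < delta_m]
    if len(co_times) < 2:
        # zero or a single cooccurring instant: no meaningful density
        return CooccurrenceResult(dist.pair, delta_m, co_times, None)
    potential = estimate_time_density(co_times, bandwidth)
    return CooccurrenceResult(dist.pair, delta_m, co_times, potential)
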