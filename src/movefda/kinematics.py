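"""Speed, rest/transit classification, and rest-period densities.

The spline model gives coordinate derivatives in degrees/day.  Speed
combines them Euclidean-style after converting each to a local metric rate:

    v(t) = sqrt( (M_lat(phi) * dlat/dt)^2 + (M_lon(phi) * dlon/dt)^2 )

where M_lat, M_lon are per-point WGS84 meters-per-degree scale factors at
the path's current latitude phi (small geodesic arcs by default, spherical
constants behind a flag).  Grid times with speed below a cutoff (0.25 m/s
by default — stationary or near-stationary movement) are classified as
rest, and a Gaussian KDE over those times gives the rest-period density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .geodesy import meters_per_degree
from .smoothing import (SplineModel, TimeDensity, estimate_time_density,
                        refined_grid)

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0

#: Default rest/transit speed cutoff (m/s)
DEFAULT_REST_CUTOFF = 0.25


@dataclass
class SpeedSeries:
    """Metric speed along the smoothed path on the refined grid."""

    animal_id: str
    times: np.ndarray
    speed_mps: np.ndarray


@dataclass
class RestProfile:
    """Rest classification and (optional) rest-time density.

    ``density`` is ``None`` — explicitly absent, not zero — when no grid
    time fell below the cutoff.
    """

    animal_id: str
    cutoff_mps: float
    rest_times: np.ndarray
    density: TimeDensity | None


def path_speed(model: SplineModel, grid=None, *,
               resolution_minutes: float = 60.0,
               scale_method: str = "arc") -> SpeedSeries:
    """Speed (m/s) along the smoothed path on the refined grid."""
    if grid is None:
        grid = refined_grid(model.domain, resolution_minutes)
    grid = np.asarray(grid, dtype=float)
    _, lat = model.positions(grid)
    dlat, dlon = model.derivatives(grid)
    m_lat, m_lon = meters_per_degree(lat, method=scale_method)
    v_m_per_day = np.hypot(m_lat * dlat, m_lon * dlon)
    return SpeedSeries(model.animal_id, grid, v_m_per_day / SECONDS_PER_DAY)


def classify_rest(speed: SpeedSeries,
                  cutoff_mps: float = DEFAULT_REST_CUTOFF) -> np.ndarray:
    """Grid times with speed strictly below the cutoff."""
    if cutoff_mps <= 0:
        raise ParameterError("rest cutoff must be positive")
    rest = speed.times[speed.speed_mps < cutoff_mps]
    if len(rest) == 0:
        logger.info("no rest times below %.3g m/s for %s",
                    cutoff_mps, speed.animal_id)
    return rest


def rest_density(rest_times, bandwidth="auto") -> TimeDensity | None:
    """Gaussian KDE over rest times; ``None`` for an empty rest set."""
    rest_times = np.asarray(rest_times, dtype=float)
    if len(rest_times) == 0:
        return None
    return estimate_time_density(rest_times, bandwidth)


def rest_profile(model: SplineModel, grid=None, *,
                 cutoff_mps: float = DEFAULT_REST_CUTOFF,
                 bandwidth="auto",
                 resolution_minutes: float = 60.0,
                 scale_method: str = "arc") -> RestProfile:
    """Speed -> rest classification -> rest density, in one call."""
    speed = path_speed(model, grid, resolution_minutes=resolution_minutes,
                       scale_method=scale_method)
    rest = classify_rest(speed, cutoff_mps)
    dens = rest_density(rest, bandwidth)
    return RestProfile(model.animal_id, cutoff_mps, rest, dens)
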