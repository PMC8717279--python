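"""Penalized B-spline smoothing of telemetry coordinates.

Each coordinate (latitude and longitude, in degrees) is modelled as a curve
x(t) = sum_k c_k phi_k(t) over a cubic B-spline basis, fitted by penalized
least squares::

    min_c ||y - Phi c||^2 + lambda c^T R c

where R is the roughness (integrated squared second derivative) penalty
matrix, evaluated by Riemann quadrature of products of basis second
derivatives on a fine uniform grid.  The penalty strength lambda is chosen
per coordinate by generalized cross-validation (GCV),

    GCV(lambda) = MSE(lambda) / (1 - df(lambda)/M)^2,

with df = trace of the smoother matrix.  The squared-denominator
(Craven-Wahba) convention is the default; a linear-denominator variant is
available behind a flag.

Knots are placed where sampling is dense: a Gaussian kernel density is
estimated over the observation times, and observation times whose density
exceeds a quantile threshold become interior knots (thinned to a minimum
spacing).  This keeps the basis rich where the data can support it and
simple across multi-day telemetry gaps.

Smoothed positions are evaluated on a refined uniform grid (60-minute
spacing by default) anchored at study time 0, so every animal's grid aligns
exactly and pairwise comparisons need no interpolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.interpolate import BSpline
from scipy.special import ndtr  # Gaussian CDF

from .exceptions import (DegenerateKnotsError, DomainError, EmptyInputError,
                         ParameterError, TuningError)
from .telemetry import Track

logger = logging.getLogger(__name__)

_DOMAIN_TOL = 1e-9


# ---------------------------------------------------------------------------
# Kernel density over study time
# ---------------------------------------------------------------------------

def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a 1-D Gaussian KDE (days)."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 2:
        raise ParameterError("need >= 2 distinct values for automatic bandwidth")
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s for s in (sd, iqr / 1.34) if s > 0)
    return 0.9 * spread * len(x) ** (-0.2)


@dataclass
class TimeDensity:
    """Gaussian kernel density over a set of study times (1/day units).

    Evaluable anywhere; normalized to total mass 1 over the real line.
    """

    sample_times: np.ndarray
    bandwidth: float

    def __post_init__(self):
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if self.bandwidth <= 0:
            raise ParameterError("bandwidth must be positive")
        if len(self.sample_times) == 0:
            raise EmptyInputError("density needs at least one sample time")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.sample_times.min()), float(self.sample_times.max())

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        h, xs = self.bandwidth, self.sample_times
        out = np.empty(len(t))
        # chunk evaluation points to bound the broadcast to ~8M doubles
        step = max(1, int(8e6 / max(len(xs), 1)))
        inv = 1.0 / (h * np.sqrt(2.0 * np.pi))
        for i in range(0, len(t), step):
            z = (t[i:i + step, None] - xs[None, :]) / h
            out[i:i + step] = inv * np.exp(-0.5 * z * z).mean(axis=1)
        return out

    def mass(self, a: float, b: float) -> float:
        """Exact probability mass on [a, b] (Gaussian CDF differences)."""
        z_b = (b - self.sample_times) / self.bandwidth
        z_a = (a - self.sample_times) / self.bandwidth
        return float((ndtr(z_b) - ndtr(z_a)).mean())

    def grid(self, n: int = 2001) -> tuple[np.ndarray, np.ndarray]:
        """Density sampled on a uniform grid spanning support +/- 8 bandwidths."""
        lo, hi = self.support
        t = np.linspace(lo - 8 * self.bandwidth, hi + 8 * self.bandwidth, n)
        return t, self(t)


def estimate_time_density(times, bandwidth="auto") -> TimeDensity:
    """KDE of sampled times; ``bandwidth="auto"`` applies Silverman's rule."""
    times = np.asarray(times, dtype=float)
    if isinstance(bandwidth, str):
        if bandwidth != "auto":
            raise ParameterError(f"unknown bandwidth {bandwidth!r}")
        bandwidth = silverman_bandwidth(times)
    return TimeDensity(times, float(bandwidth))


# ---------------------------------------------------------------------------
# Knot selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnotVector:
    """Interior and boundary knots plus spline order (4 = cubic)."""

    interior: np.ndarray
    boundary: tuple[float, float]
    order: int = 4

    def __post_init__(self):
        object.__setattr__(self, "interior",
                           np.asarray(self.interior, dtype=float))
        a, b = self.boundary
        if not a < b:
            raise ParameterError("boundary knots must satisfy a < b")
        if np.any(np.diff(self.interior) <= 0):
            raise ParameterError("interior knots must be strictly increasing")
        if len(self.interior) and (
                self.interior[0] <= a or self.interior[-1] >= b):
            raise ParameterError("interior knots must lie strictly inside "
                                 "the boundary")
        if self.order < 3:
            raise ParameterError("second-derivative penalty needs order >= 3")

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def full(self) -> np.ndarray:
        a, b = self.boundary
        return np.concatenate([np.full(self.order, a), self.interior,
                               np.full(self.order, b)])

    @property
    def n_basis(self) -> int:
        return len(self.interior) + self.order


def select_knots(density: TimeDensity, times, *, quantile: float = 0.05,
                 min_spacing_days: float = 2.0 / 24.0,
                 order: int = 4) -> KnotVector:
    """Interior knots at observation times where sampling density is high.

    The threshold is the ``quantile``-th quantile of density values at the
    observation times; retained times are thinned left-to-right to
    ``min_spacing_days``.  Boundary knots sit at the first/last observation.
    """
    times = np.unique(np.asarray(times, dtype=float))
    if not 0.0 <= quantile < 1.0:
        raise ParameterError("knot quantile must be in [0, 1)")
    vals = density(times)
    thresh = float(np.quantile(vals, quantile))
    keep = vals >= thresh if quantile == 0.0 else vals > thresh
    candidates = times[keep]
    if len(candidates) == 0:
        raise DegenerateKnotsError(
            f"no times exceed the density threshold (quantile={quantile}); "
            "try a lower quantile")
    a, b = float(times[0]), float(times[-1])
    thinned = []
    last = -np.inf
    for t in candidates:
        if t - last >= min_spacing_days:
            thinned.append(t)
            last = t
    interior = np.asarray([t for t in thinned if a < t < b])
    return KnotVector(interior, (a, b), order=order)


# ---------------------------------------------------------------------------
# Basis, penalty and fitting
# ---------------------------------------------------------------------------

def _derivative_operator(knots: np.ndarray, degree: int) -> sparse.csr_matrix:
    # maps coefficients of a degree-k spline on `knots` to coefficients of its
    # first derivative (degree k-1 spline on knots[1:-1])
    n = len(knots) - degree - 1
    denom = knots[degree + 1:degree + n] - knots[1:n]
    with np.errstate(divide="ignore"):
        scale = np.where(denom > 0, degree / np.where(denom > 0, denom, 1.0), 0.0)
    rows, cols, vals = [], [], []
    for j in range(n - 1):
        rows += [j, j]
        cols += [j, j + 1]
        vals += [-scale[j], scale[j]]
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n - 1, n))


class BSplineBasis:
    """B-spline basis on a :class:`KnotVector` with sparse design matrices."""

    def __init__(self, knots: KnotVector):
        self.knots = knots
        self.full = knots.full
        self.degree = knots.degree
        self.n_basis = knots.n_basis

    def design_matrix(self, x, nu: int = 0) -> sparse.csr_matrix:
        """Sparse (len(x), K) matrix of basis (or nu-th derivative) values."""
        x = np.asarray(x, dtype=float)
        a, b = self.knots.boundary
        if np.any(x < a - _DOMAIN_TOL) or np.any(x > b + _DOMAIN_TOL):
            raise DomainError(
                f"evaluation points outside fitted domain [{a}, {b}]")
        x = np.clip(x, a, b)
        if nu == 0:
            return BSpline.design_matrix(x, self.full, self.degree).tocsr()
        if nu > self.degree:
            return sparse.csr_matrix((len(x), self.n_basis))
        knots, deg = self.full, self.degree
        op = sparse.identity(self.n_basis, format="csr")
        for _ in range(nu):
            op = _derivative_operator(knots, deg) @ op
            knots, deg = knots[1:-1], deg - 1
        return (BSpline.design_matrix(x, knots, deg) @ op).tocsr()

    def penalty_matrix(self, n_quad: int | None = None) -> sparse.csr_matrix:
        """Roughness penalty R by Riemann quadrature of phi'' products.

        R_jk = sum_l phi''_j(t_l) phi''_k(t_l) h on a uniform grid of
        ``n_quad`` points (default max(1000, 20 K)).
        """
        if n_quad is None:
            n_quad = max(1000, 20 * self.n_basis)
        a, b = self.knots.boundary
        tq = np.linspace(a, b, n_quad)
        h = (b - a) / (n_quad - 1)
        D2 = self.design_matrix(tq, nu=2)
        return (D2.T @ D2).tocsr() * h


@dataclass
class SplineModel:
    """Fitted penalized spline for one animal (both coordinates).

    Positions and derivatives at any time inside ``domain`` come from the
    basis expansion with the stored coefficients; no extrapolation.
    """

    animal_id: str
    basis: BSplineBasis
    coef_lat: np.ndarray
    coef_lon: np.ndarray
    lambda_lat: float
    lambda_lon: float
    df_lat: float
    df_lon: float
    epoch: object = None

    @property
    def domain(self) -> tuple[float, float]:
        return self.basis.knots.boundary

    def positions(self, grid) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) in degrees at the given times."""
        Phi = self.basis.design_matrix(np.asarray(grid, dtype=float))
        return Phi @ self.coef_lon, Phi @ self.coef_lat

    def derivatives(self, grid) -> tuple[np.ndarray, np.ndarray]:
        """(dlat/dt, dlon/dt) in degrees/day at the given times."""
        D = self.basis.design_matrix(np.asarray(grid, dtype=float), nu=1)
        return D @ self.coef_lat, D @ self.coef_lon

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        kv = self.basis.knots
        return json.dumps({
            "animal_id": self.animal_id,
            "order": kv.order,
            "boundary": list(kv.boundary),
            "interior_knots": kv.interior.tolist(),
            "coef_lat": self.coef_lat.tolist(),
            "coef_lon": self.coef_lon.tolist(),
            "lambda_lat": self.lambda_lat,
            "lambda_lon": self.lambda_lon,
            "df_lat": self.df_lat,
            "df_lon": self.df_lon,
            "epoch": str(self.epoch) if self.epoch is not None else None,
        })

    @classmethod
    def from_json(cls, text: str) -> "SplineModel":
        d = json.loads(text)
        kv = KnotVector(np.asarray(d["interior_knots"]),
                        tuple(d["boundary"]), order=d["order"])
        return cls(d["animal_id"], BSplineBasis(kv),
                   np.asarray(d["coef_lat"]), np.asarray(d["coef_lon"]),
                   d["lambda_lat"], d["lambda_lon"],
                   d["df_lat"], d["df_lon"], d["epoch"])


class _CoordinateSolver:
    """Shared factorizations for repeated fits over a lambda grid.

    The normal equations (Phi^T Phi + lambda R) c = Phi^T y are solved in
    the eigenbasis of R.  There lambda enters only on the diagonal and the
    penalty's null space (linear trends, where the eigenvalue is zero) is
    never swamped numerically, so the fit approaches the ordinary
    least-squares line exactly as lambda grows without bound.  Effective
    degrees of freedom trace((Phi^T Phi + lambda R)^{-1} Phi^T Phi) are
    cached per lambda, so a GCV grid search shares them across coordinates.
    """

    def __init__(self, basis: BSplineBasis, times: np.ndarray):
        self.basis = basis
        self.Phi = basis.design_matrix(times)
        self.n_obs = len(times)
        G = (self.Phi.T @ self.Phi).toarray()
        R = basis.penalty_matrix().toarray()
        evals, V = np.linalg.eigh(0.5 * (R + R.T))
        evals = np.clip(evals, 0.0, None)
        # the penalty null space (linear trends) must carry an exactly zero
        # eigenvalue or a huge lambda would falsely penalize it
        cut = len(evals) * np.finfo(float).eps * (evals.max() or 1.0)
        evals[evals < cut] = 0.0
        self._evals = evals
        self._V = V
        self._H = V.T @ G @ V
        self._df_cache: dict[float, float] = {}
        self._jittered = False

    def _system(self, lam: float) -> np.ndarray:
        if lam < 0:
            raise ParameterError("penalty lambda must be >= 0")
        M = self._H.copy()
        M[np.diag_indices_from(M)] += lam * self._evals
        return M

    @staticmethod
    def _residual_ok(M, sol, rhs) -> bool:
        r = M @ sol - rhs
        return bool(np.linalg.norm(r) <= 1e-8 * max(1.0, np.linalg.norm(rhs)))

    def _solve_system(self, M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        try:
            sol = np.linalg.solve(M, rhs)
            if np.all(np.isfinite(sol)) and self._residual_ok(M, sol, rhs):
                return sol
        except np.linalg.LinAlgError:
            pass
        jitter = 1e-10 * float(np.abs(np.diag(M)).mean())
        if not self._jittered:
            logger.info("normal equations singular; adding jitter %.3e",
                        jitter)
            self._jittered = True
        Mj = M.copy()
        Mj[np.diag_indices_from(Mj)] += jitter
        try:
            return np.linalg.solve(Mj, rhs)
        except np.linalg.LinAlgError:
            # fall back to the minimum-norm solution (interpolation limit
            # with more basis functions than observations)
            sol, *_ = np.linalg.lstsq(M, rhs, rcond=None)
            return sol

    def df(self, lam: float) -> float:
        """Effective degrees of freedom trace(S) at one lambda (cached)."""
        lam = float(lam)
        if lam not in self._df_cache:
            M = self._system(lam)
            X = self._solve_system(M, self._H)
            self._df_cache[lam] = float(np.trace(X))
        return self._df_cache[lam]

    def solve(self, y: np.ndarray, lam: float):
        """Return (coef, df, mse) for one coordinate at one lambda."""
        M = self._system(lam)
        b = self._V.T @ (self.Phi.T @ y)
        coef = self._V @ self._solve_system(M, b)
        resid = y - self.Phi @ coef
        mse = float(resid @ resid) / self.n_obs
        return coef, self.df(lam), mse


def fit_penalized(track: Track, knots: KnotVector,
                  lambda_lat: float, lambda_lon: float) -> SplineModel:
    """Penalized least-squares fit of both coordinates with fixed penalties."""
    basis = BSplineBasis(knots)
    solver = _CoordinateSolver(basis, track.times)
    c_lat, df_lat, _ = solver.solve(track.lat, lambda_lat)
    c_lon, df_lon, _ = solver.solve(track.lon, lambda_lon)
    return SplineModel(track.animal_id, basis, c_lat, c_lon,
                       float(lambda_lat), float(lambda_lon),
                       df_lat, df_lon, epoch=track.epoch)


def gcv_score(track: Track, knots: KnotVector, lam: float,
              coordinate: str, *, denominator: str = "squared") -> float:
    """GCV criterion for one coordinate at one penalty value.

    ``denominator="squared"`` is the Craven-Wahba convention
    MSE/(1 - df/M)^2; ``"linear"`` divides by (1 - df/M) once.
    """
    y = {"lat": track.lat, "lon": track.lon}[coordinate]
    solver = _CoordinateSolver(BSplineBasis(knots), track.times)
    _, df, mse = solver.solve(y, lam)
    return _gcv_from_parts(mse, df, solver.n_obs, denominator)


def _gcv_from_parts(mse: float, df: float, n_obs: int,
                    denominator: str = "squared") -> float:
    if df >= n_obs:
        raise ParameterError(
            f"GCV undefined: df={df:.2f} >= M={n_obs}")
    denom = 1.0 - df / n_obs
    if denominator == "squared":
        return mse / denom ** 2
    if denominator == "linear":
        return mse / denom
    raise ParameterError(f"unknown GCV denominator {denominator!r}")


DEFAULT_LAMBDA_GRID = np.logspace(-8, 4, 25)


@dataclass
class GcvTrace:
    """Full GCV traces so a user can inspect and override the selection."""

    lambdas: np.ndarray
    score_lat: np.ndarray
    score_lon: np.ndarray
    lambda_lat: float
    lambda_lon: float


def tune_smoothing(track: Track, knots: KnotVector,
                   grid=None, *, denominator: str = "squared",
                   equal_lambda: bool = False) -> GcvTrace:
    """Grid-search GCV per coordinate; ties resolve to the smaller lambda.

    With ``equal_lambda=True`` a single penalty minimizing the summed GCV of
    both coordinates is selected (roughness penalized equally in latitude
    and longitude).  The returned trace carries all scores: automated
    selection is a starting point, and callers may override it after
    inspection (e.g. when abrupt real movement must not be smoothed away).
    """
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.sort(
        np.asarray(grid, dtype=float))
    if len(grid) == 0 or np.any(grid < 0):
        raise ParameterError("lambda grid must be nonempty and nonnegative")
    solver = _CoordinateSolver(BSplineBasis(knots), track.times)
    scores = {"lat": np.full(len(grid), np.nan),
              "lon": np.full(len(grid), np.nan)}
    for i, lam in enumerate(grid):
        for coord, y in (("lat", track.lat), ("lon", track.lon)):
            try:
                _, df, mse = solver.solve(y, lam)
                scores[coord][i] = _gcv_from_parts(mse, df, solver.n_obs,
                                                   denominator)
            except ParameterError:
                continue
    if np.all(np.isnan(scores["lat"])) or np.all(np.isnan(scores["lon"])):
        raise TuningError("no candidate lambda produced a defined GCV score")
    if equal_lambda:
        total = scores["lat"] + scores["lon"]
        best = int(np.nanargmin(total))
        lam_lat = lam_lon = float(grid[best])
    else:
        lam_lat = float(grid[int(np.nanargmin(scores["lat"]))])
        lam_lon = float(grid[int(np.nanargmin(scores["lon"]))])
    return GcvTrace(grid, scores["lat"], scores["lon"], lam_lat, lam_lon)


# ---------------------------------------------------------------------------
# Refined-grid evaluation
# ---------------------------------------------------------------------------

def refined_grid(domain: tuple[float, float],
                 resolution_minutes: float = 60.0) -> np.ndarray:
    """Uniform evaluation grid inside ``domain``, anchored at study time 0.

    All animals share one global grid (multiples of the resolution from the
    study epoch); this returns the multiples falling inside the domain, so
    two animals' grids align exactly wherever their domains overlap.
    """
    if resolution_minutes <= 0:
        raise ParameterError("grid resolution must be positive")
    step = resolution_minutes / 1440.0
    a, b = domain
    k0 = int(np.ceil(a / step - 1e-9))
    k1 = int(np.floor(b / step + 1e-9))
    if k1 < k0:
        raise DomainError("domain shorter than one grid step")
    return np.arange(k0, k1 + 1) * step


def evaluate_path(model: SplineModel, grid=None, *,
                  resolution_minutes: float = 60.0):
    """Smoothed (lon, lat) on ``grid`` (default: refined 60-min grid)."""
    if grid is None:
        grid = refined_grid(model.domain, resolution_minutes)
    grid = np.asarray(grid, dtype=float)
    lon, lat = model.positions(grid)
    return grid, lon, lat


def path_derivative(model: SplineModel, grid=None, *,
                    resolution_minutes: float = 60.0):
    """Exact basis-expansion derivatives (dlat/dt, dlon/dt), degrees/day."""
    if grid is None:
        grid = refined_grid(model.domain, resolution_minutes)
    grid = np.asarray(grid, dtype=float)
    dlat, dlon = model.derivatives(grid)
    return grid, dlat, dlon
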