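import numpy as np
import pytest

import movefda as m


@pytest.fixture
def rng():
    return np.random.default_rng(20211209)


@pytest.fixture
def toy_csv(tmp_path):
    """Three-animal Movebank-style CSV builder."""
    def _write(rows, name="toy.csv"):
        header = ("timestamp,location-long,location-lat,"
                  "individual-local-identifier\n")
        path = tmp_path / name
        path.write_text(header + "\n".join(rows) + "\n")
        return path
    return _write


@pytest.fixture
def sine_track(rng):
    """Smooth deterministic track: sinusoidal movement near the equator."""
    t = np.linspace(0.0, 10.0, 241)
    lat = 0.05 * np.sin(2 * np.pi * t / 5.0)
    lon = 0.05 * np.cos(2 * np.pi * t / 7.0)
    return m.Track("sine", t, lon, lat)


@pytest.fixture
def sine_model(sine_track):
    density = m.estimate_time_density(sine_track.times)
    knots = m.select_knots(density, sine_track.times)
    return m.fit_penalized(sine_track, knots, 1e-6, 1e-6)


def constant_model(animal_id, lon, lat, domain=(0.0, 10.0)):
    """Spline model of an animal standing still at (lon, lat)."""
    t = np.linspace(domain[0], domain[1], 101)
    track = m.Track(animal_id, t, np.full_like(t, lon), np.full_like(t, lat))
    knots = m.KnotVector(np.array([np.mean(domain)]), domain)
    return m.fit_penalized(track, knots, 0.0, 0.0)


@pytest.fixture
def sim_pair_coupled():
    """60-day pair with innovations coupled (rho=0.9) in days [25, 35]."""
    config = m.SimConfig(seed=7, duration_days=60.0)
    schedule = m.AssociationSchedule(((25.0, 35.0),), rho=0.9)
    a, b, schedule = m.simulate_associated_pair(config, schedule)
    return a, b, schedule


def quick_fit(track, lam=1e-4):
    """Knot placement + fixed-penalty fit (no GCV search), for speed."""
    density = m.estimate_time_density(track.times)
    knots = m.select_knots(density, track.times)
    return m.fit_penalized(track, knots, lam, lam)
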