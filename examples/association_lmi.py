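"""Localized mutual information: recovering a known association window.

Two animals' movements are coupled (innovation correlation 0.9) only during
days 25-35 of a 60-day run.  The localized mutual information curve — MI of
the paired latitude and longitude series inside a sliding 48-hour-radius
window, combined across coordinates — should peak inside that window and
stay low elsewhere, even though the animals' home ranges are far apart
(association without proximity).
"""

import numpy as np

import movefda as m
from movefda.pipeline import fit_track

config = m.SimConfig(seed=3, duration_days=60.0)
schedule = m.AssociationSchedule(((25.0, 35.0),), rho=0.9)
a, b, _ = m.simulate_associated_pair(config, schedule,
                                     home_center_b=(1.0, 0.5))

cfg = m.AnalysisConfig(lambda_grid=(1e-6, 1e-4, 1e-2))
model_a, model_b = fit_track(a, cfg), fit_track(b, cfg)

dist = m.distance_series(model_a, model_b)
print(f"median separation: {np.median(dist.dist_m) / 1000:.0f} km "
      "(far beyond the 1800 m cooccurrence threshold)")

series = m.lmi_series(model_a, model_b, window_hours=48.0)
series = m.scale_lmi(series, policy="global-max")
t, raw, ok = series.times, series.raw, series.defined

peak = t[np.nanargmax(np.where(ok, raw, -np.inf))]
inside = ok & (t >= 25.0) & (t <= 35.0)
outside = ok & ((t < 23.0) | (t > 37.0))
print(f"LMI defined at {ok.sum()} of {len(t)} grid hours "
      f"(complete 48 h windows only)")
print(f"peak raw LMI {np.nanmax(raw[ok]):.3f} nats at day {peak:.1f} "
      f"(true coupling window: days 25-35)")
print(f"median raw LMI inside window {np.median(raw[inside]):.3f} vs "
      f"outside {np.median(raw[outside]):.3f} nats "
      f"({np.median(raw[inside]) / np.median(raw[outside]):.1f}x contrast)")
print("scaled curve is in [0, 1]: "
      f"max {np.nanmax(series.scaled[ok]):.2f} at the peak, readable "
      "like a time-varying correlation")
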