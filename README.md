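# movefda

Functional data analysis of animal telemetry: smooth irregular GPS tracks
with penalized B-splines, derive speed and rest-period densities, measure
pairwise geodesic distance and cooccurrence potential, and quantify
time-varying association between animals with a localized mutual
information function.

## Who this is for

Movement ecologists with GPS collar data (Movebank-style CSVs of
timestamped fixes per individual) who want a continuous, differentiable
estimate of each animal's path and, from it, comparable hour-by-hour
measures of behavior and pairwise interaction — even when collars sample
irregularly, drop out for days, and cover staggered monitoring windows.

## The model in brief

Each coordinate is a curve x(t) = Σ_k c_k φ_k(t) over a cubic B-spline
basis, fitted by penalized least squares

    min_c ||y − Φc||² + λ cᵀRc,

with R the integrated-squared-second-derivative roughness penalty and λ
chosen per coordinate by generalized cross-validation,
GCV(λ) = MSE(λ)/(1 − df(λ)/M)². Knots are placed where the kernel density
of sampling times is high, so multi-day gaps are bridged smoothly instead
of overfit. All animals are evaluated on one unified refined time grid
(60 min by default), giving:

- **speed** √((M_lat·x̂′_lat)² + (M_lon·x̂′_lon)²) in m/s via per-latitude
  WGS84 meters-per-degree factors, with rest hours classified below a
  0.25 m/s cutoff and summarized by a kernel density of rest times;
- **distance** d(t) = WGS84 geodesic between the two smoothed positions,
  and the **cooccurrence potential**, a kernel density over the hours with
  d(t) < δ (default 1800 m);
- **localized mutual information** I(t;λ) =
  √(I_L(X_lat;Y_lat)² + I_L(X_lon;Y_lon)²), the per-coordinate mutual
  information of the two animals' positions inside a sliding window
  [t−λ, t+λ] (default λ = 48 h), scaled into [0,1] to read like a
  time-varying correlation of movement.

See `docs/methods.md` for estimator details and design rationale.

## Worked example

`examples/association_lmi.py` simulates two animals whose movements are
coupled (innovation correlation 0.9) only during days 25–35 of a 60-day
run, with home ranges ~124 km apart, then fits both splines and computes
the LMI curve:

```text
$ python examples/association_lmi.py
median separation: 124 km (far beyond the 1800 m cooccurrence threshold)
LMI defined at 1345 of 1441 grid hours (complete 48 h windows only)
peak raw LMI 0.497 nats at day 28.3 (true coupling window: days 25-35)
median raw LMI inside window 0.223 vs outside 0.059 nats (3.8x contrast)
scaled curve is in [0, 1]: max 1.00 at the peak, readable like a time-varying correlation
```

The peak lands inside the true coupling window and the curve contrasts
inside vs outside by ~4x — association is detected *without* spatial
proximity, which distance-threshold methods cannot see. The other examples
(`smooth_single_track.py`, `pair_cooccurrence.py`) walk through
single-animal smoothing/kinematics and distance/cooccurrence analysis the
same way.

A thin CLI wraps the same library calls:

```sh
movefda simulate --pair --seed 3 --duration 30 --window 10 20 --out pair.csv
movefda all pair.csv --out products/
```

writing per-animal model JSON and path/speed/rest CSVs, per-pair distance,
cooccurrence and LMI CSVs, and a run manifest with a config hash.

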