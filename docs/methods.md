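# Methods

`movefda` treats an animal's telemetry as discrete, noisy observations of an
inherently continuous kinematic process, and analyses the fitted *curve*
rather than the raw fixes. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Penalized spline smoothing

Latitude and longitude (decimal degrees, WGS84) are smoothed separately
against study time t (fractional days since the epoch). For observations
y at times t_1..t_M the coordinate curve is x(t) = Σ_k c_k φ_k(t) over a
cubic B-spline basis (order 4; the second-derivative roughness penalty needs
at least cubic pieces), with coefficients solving

    min_c ||y − Φc||² + λ cᵀRc .

R is the roughness penalty, computed by Riemann quadrature of products of
basis second derivatives on a uniform grid of max(1000, 20K) points over the
fitted domain. The normal equations are solved in the eigenbasis of R:
there λ enters only on the diagonal, the penalty's null space (linear
trends) carries exactly zero eigenvalue (eigenvalues below K·ε·max are
zeroed), and the fit converges to the ordinary least-squares line as λ→∞
without catastrophic cancellation. If a system is numerically singular
(e.g. more basis functions than observations at λ=0) a one-time jitter of
1e-10 times the mean diagonal is added and, failing that, the minimum-norm
solution is used; both paths are logged.

**Knot placement.** Telemetry alternates dense hourly stretches with
multi-hour to multi-day collar gaps. Interior knots are the observation
times whose Gaussian-KDE sampling density exceeds the q-th quantile
(default q = 0.05) of density values at the observation times, thinned
left-to-right to a minimum spacing of 2 h. The quantile parameterization
makes the threshold scale-free; the spacing floor prevents coincident or
near-coincident knots when fixes arrive minutes apart. Gaps get no interior
knots, so the curve stays simple where the data cannot support detail.

**Penalty selection.** λ is chosen per coordinate by grid search (default
25 log-spaced values, 1e-8..1e4) on generalized cross-validation,

    GCV(λ) = MSE(λ) / (1 − df(λ)/M)² ,

with df = trace of the smoother matrix, cached per λ and shared between
coordinates. The squared denominator (Craven–Wahba) is the default; a
linear-denominator variant sits behind a flag. Ties resolve to the smaller
λ (less smoothing preserves genuine abrupt movement). The full GCV trace is
returned so an analyst can override the automatic choice — automated
criteria can smooth away real, sharp territorial shifts, so visual
inspection remains a legitimate final step; the package deliberately does
not automate it. An `equal_lambda` option ties both coordinates to one
penalty for species without strongly anisotropic movement.

**Refined unified grid.** Smoothed positions are evaluated on a uniform
grid (default 60 min) of multiples of the resolution counted from study
time 0. Because every animal's grid consists of the same global multiples,
any two animals' grids align exactly on their domain overlap — no
interpolation between grids is ever needed. Evaluation outside an animal's
fitted domain is an error; the model interpolates, never extrapolates.

## Kinematics and rest

Derivatives of the basis expansion give degree rates (degrees/day), which
are converted to metric rates with per-point WGS84 scale factors at the
path's current latitude φ: M_lat(φ) and M_lon(φ) are measured as 0.001°
geodesic arcs scaled up (so they are exactly consistent with the distance
metric below); spherical constants (111,320 and 111,320·cos φ) are
available behind a flag and agree to ~0.5%. Speed is the Euclidean
combination √((M_lat·dlat/dt)² + (M_lon·dlon/dt)²), reported in m/s.

Grid hours with speed below 0.25 m/s — stationary or nearly so — are
classified as rest; the cutoff is configurable. A Gaussian KDE over rest
times gives the rest-period density; multi-day bandwidths (≈4–12 days)
resolve weekly-scale shifts in resting behavior. An empty rest set yields
an explicitly absent density, never a zero curve.

## Distance and cooccurrence potential

Pairwise distance is the WGS84 ellipsoidal geodesic between the two
smoothed positions at each shared grid hour. The geodesic is a vectorized
Vincenty inverse solution; on regional telemetry-scale pairs it agrees with
an independent reference implementation (geosphere's Karney-based
`distGeo`) to under a micrometre, far inside the 1 mm test bound. The
iteration is not used near its antipodal singularity, which telemetry for a
single study region cannot produce.

Grid hours with distance strictly below δ = 1800 m (configurable) form the
cooccurrence set; a Gaussian KDE over those times (Silverman bandwidth by
default) is the *cooccurrence potential* — a density of interaction
opportunities rather than a count of close fixes, chosen because animals
can cover well over a kilometre between hourly fixes, so a tight radius on
raw fixes undercounts possible encounters. An empty cooccurrence set is
reported as absent potential.

## Localized mutual information

Mutual information I(X;Y) = ∫∫ p(x,y) log[p(x,y)/(p(x)p(y))] is zero iff
the coordinates are independent and grows with dependence of any form, not
just linear association. The default estimator is an equal-frequency
(copula) histogram plug-in: each margin is rank-binned into B near-equal
count bins and the discrete MI of the joint table is reported in nats.
Negative estimates cannot occur for this estimator (it is a KL divergence);
the k-NN (KSG) alternative used for cross-checking is clamped at zero.

**Bin rule.** B = max(2, ⌊(n/5)^(1/3)⌋). The plug-in estimator's bias
under independence is approximately (B−1)²/(2n) nats, so B must grow
markedly slower than √n for the null to vanish: with B ∝ √n the bias is a
constant ≈ 0.1 nats at any sample size, whereas the cube-root rule gives
≈ 0.003 nats at n = 10⁵ while remaining consistent under dependence (the
ρ = 0.9 bivariate normal, analytic MI 0.8304 nats, is recovered within
0.02 at n = 2·10⁵). Perfect dependence (y = x) yields exactly the entropy
of the bin assignment — log B when B divides n.

**Localization.** At each refined-grid time t_i both animals' latitude
series (and, separately, longitude series) are restricted to the window
[t_i − λ, t_i + λ] with λ = 48 h by default (a 4-day total window), MI is
estimated per coordinate, and the two values are combined as the unweighted
Euclidean norm. Windows are the refined-grid evaluations themselves, so a
48 h radius at 60-min resolution holds 97 samples. LMI is *defined only
where the window is complete* (like rolling statistics that stay undefined
until the window fills): truncated boundary windows hold fewer effectively
independent samples of the smooth paths, which inflates the plug-in
estimate — in simulation, boundary windows spuriously saturated near the
2-bin ceiling and produced false global peaks. Truncated windows can be
re-enabled via `min_window_fraction`, with a hard floor of 10 samples
either way. Distance-from-center weighting of window samples is
deliberately not implemented.

**Scaling.** Raw LMI in nats is mapped to [0,1] either by the pointwise
maximum across a set of pairs sharing a grid (the strongest pair reads 1.0
at every instant; the default for comparative plots) or by each series' own
global maximum (used by the pipeline, whose pairs generally have different
overlap grids). 0/0 scales to 0. Scaled values are invariant to the
logarithm base.

Windowed five-number summaries (min, quartiles, max by linear-interpolation
percentiles) of distance and scaled LMI support tabular comparison of peak
association episodes.

## Synthetic telemetry

The generator exists so every stage is testable without downloads. Each
coordinate follows a discretized Ornstein–Uhlenbeck process around a home
center, x_{t+Δ} = x_t + θ(μ−x_t)Δ + σ√Δ·ε — the simplest home-ranging
kinematic with closed-form stationary variance σ²/(2θ). Defaults emulate
hourly big-cat telemetry near the equator: σ = 0.06 deg/√day and θ = 2/day
give a stationary s.d. of ≈ 0.03° (≈ 3 km) and position decorrelation over
≈ half a day; 15% of nominal hourly fixes are lost to gaps with log-uniform
lengths between 2 h and 3 days (the onset probability is solved from the
target missing fraction); observation noise is 0.0005° (≈ 55 m). Centers
sit near the equator so degree→meter conversion stays simple in tests.

Associated pairs share per-step innovations inside scheduled windows
(ε_B = ρ·ε_A + √(1−ρ²)·η, default ρ = 0.9), independent outside. Coupling
acts on innovations, not positions, so association without spatial
proximity is representable by coupling animals with distant home centers.

**What the synthetic tests do not show.** OU motion has no behavioral
states, diel rhythm, terrain, or memory; gaps are independent of behavior;
noise is Gaussian and stationary. Passing the recovery tests demonstrates
that the estimator chain detects dependence injected at the innovation
level under realistic sampling irregularity — not that every form of real
animal association is detectable. Within a 4-day window the smoothed paths
of even independent animals are slowly varying, so windowed MI has a
noise floor (median ≈ 0.03–0.06 nats under the default conditions) and
occasional spurious interior peaks; LMI peaks should be read comparatively,
not as significance statements (none are provided).

## Problem sizes and determinism

Test and acceptance runs use desk-scale problems: tracks of 15–60 days at
hourly sampling (~400–1400 fixes, spline bases of a few hundred functions),
20-seed batches for recovery rates, and 10⁵–2·10⁵ samples for estimator
calibration. All randomness flows through explicit seeds
(`numpy.random.default_rng`); reruns with the same seed and configuration
are byte-identical, and the pipeline writes a config-hash manifest to make
that checkable.

## Known limitations

- No measurement-error model: fixes are taken at face value and the
  smoother's λ absorbs noise implicitly.
- Binary rest/transit classification only; no multi-state behavioral model.
- Pairwise association only; no partial/conditional MI for triads.
- No significance testing or uncertainty bands on LMI or densities.
- Vincenty's inverse is unsuitable for near-antipodal point pairs, which do
  not occur in single-region telemetry.
- The GCV optimum can oversmooth sharp territorial shifts; the API exposes
  the full trace for manual override rather than automating visual tuning.
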