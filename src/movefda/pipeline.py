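"""End-to-end analysis: tracks -> spline models -> kinematics -> pair measures.

`run_full_analysis` wires the stages in order — time-density knot placement,
GCV-tuned penalized spline fits, refined-grid evaluation, speed and rest
densities per animal, then distance, cooccurrence potential, and localized
mutual information per requested pair — writing deterministic CSV/JSON
products plus a run manifest into an output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import (LmiSeries, MiConfig, lmi_series, scale_lmi,
                          summarize_window)
from .config import AnalysisConfig
from .exceptions import MoveFdaError, NoOverlapError
from .kinematics import classify_rest, path_speed, rest_density
from .proximity import cooccurrence_potential, distance_series
from .smoothing import (SplineModel, estimate_time_density, evaluate_path,
                        fit_penalized, path_derivative, refined_grid,
                        select_knots, tune_smoothing)
from .telemetry import Track, monitoring_table

logger = logging.getLogger(__name__)


def fit_track(track: Track, config: AnalysisConfig) -> SplineModel:
    """Knot placement + GCV tuning + penalized fit for one animal."""
    density = estimate_time_density(track.times,
                                    config.time_density_bandwidth)
    knots = select_knots(density, track.times,
                         quantile=config.knot_quantile,
                         min_spacing_days=config.knot_min_spacing_hours / 24.0)
    trace = tune_smoothing(track, knots, np.asarray(config.lambda_grid),
                           denominator=config.gcv_denominator,
                           equal_lambda=config.equal_lambda)
    return fit_penalized(track, knots, trace.lambda_lat, trace.lambda_lon)


def _density_frame(density, domain, resolution_min) -> pd.DataFrame:
    t = refined_grid(domain, resolution_min)
    vals = density(t) if density is not None else np.zeros(len(t))
    return pd.DataFrame({"time": t, "density": vals})


def run_full_analysis(tracks: Sequence[Track],
                      pairs: Sequence[tuple[str, str]],
                      config: AnalysisConfig,
                      outdir) -> Path:
    """Run every stage for the given tracks and pairs; returns the outdir.

    Products per animal: ``model_<id>.json``, ``path_<id>.csv`` (time, lon,
    lat, dlon, dlat), ``speed_<id>.csv`` (time, speed_mps, is_rest),
    ``rest_density_<id>.csv``.  Per pair ``a-b``: ``distance_<a>-<b>.csv``
    (time, dist_m, is_cooccurring), ``cooccurrence_<a>-<b>.csv``,
    ``lmi_<a>-<b>.csv`` (time, raw_lmi, scaled_lmi, defined), and a pair
    manifest.  Plus ``monitoring.csv``, ``peak_windows.csv`` and
    ``manifest.json``.  Pairs without domain overlap are skipped with a
    logged reason and recorded in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = config.grid_resolution_min
    by_id = {t.animal_id: t for t in tracks}

    monitoring_table(list(tracks)).to_csv(outdir / "monitoring.csv",
                                          index=False)

    models: dict[str, SplineModel] = {}
    for track in tracks:
        logger.info("stage fit: %s", track.animal_id)
        model = fit_track(track, config)
        models[track.animal_id] = model
        (outdir / f"model_{track.animal_id}.json").write_text(model.to_json())

        grid, lon, lat = evaluate_path(model, resolution_minutes=res)
        _, dlat, dlon = path_derivative(model, grid)
        pd.DataFrame({"time": grid, "lon": lon, "lat": lat,
                      "dlon": dlon, "dlat": dlat}).to_csv(
            outdir / f"path_{track.animal_id}.csv", index=False)

        speed = path_speed(model, grid, scale_method=config.scale_method)
        rest = classify_rest(speed, config.rest_cutoff_mps)
        is_rest = speed.speed_mps < config.rest_cutoff_mps
        pd.DataFrame({"time": grid, "speed_mps": speed.speed_mps,
                      "is_rest": is_rest}).to_csv(
            outdir / f"speed_{track.animal_id}.csv", index=False)
        dens = rest_density(rest, config.rest_bandwidth)
        _density_frame(dens, model.domain, res).to_csv(
            outdir / f"rest_density_{track.animal_id}.csv", index=False)

    mi_config = MiConfig(estimator=config.mi_estimator, bins=config.mi_bins,
                         min_samples=config.mi_min_samples)
    skipped: list[dict] = []
    lmis: list[LmiSeries] = []
    dists = {}
    for a, b in pairs:
        if a not in by_id or b not in by_id:
            raise MoveFdaError(f"pair ({a}, {b}) not found in the loaded data")
        tag = f"{a}-{b}"
        try:
            logger.info("stage distance: %s", tag)
            dist = distance_series(models[a], models[b], res)
        except NoOverlapError as exc:
            logger.warning("stage distance: pair %s skipped: %s", tag, exc)
            skipped.append({"pair": [a, b], "reason": str(exc)})
            continue
        dists[(a, b)] = dist
        co = cooccurrence_potential(dist, config.delta_m,
                                    config.cooccurrence_bandwidth)
        pd.DataFrame({"time": dist.times, "dist_m": dist.dist_m,
                      "is_cooccurring": dist.dist_m < config.delta_m}).to_csv(
            outdir / f"distance_{tag}.csv", index=False)
        _density_frame(co.potential,
                       (dist.times[0], dist.times[-1]), res).to_csv(
            outdir / f"cooccurrence_{tag}.csv", index=False)
        (outdir / f"pair_{tag}.json").write_text(json.dumps({
            "pair": [a, b], "delta_m": config.delta_m,
            "overlap_window": [float(dist.times[0]), float(dist.times[-1])],
            "n_cooccurring": int(len(co.co_times)),
            "potential_bandwidth": (co.potential.bandwidth
                                    if co.potential else None),
        }, indent=2))

        logger.info("stage lmi: %s", tag)
        lmis.append(lmi_series(models[a], models[b],
                               window_hours=config.lmi_window_hours,
                               resolution_minutes=res, config=mi_config))

    # scale each pair's curve on its own (grids differ across pairs);
    # cross-pair pointwise scaling applies when grids coincide
    rows = []
    for lmi in lmis:
        scaled = scale_lmi(lmi, policy="global-max")
        tag = f"{scaled.pair[0]}-{scaled.pair[1]}"
        pd.DataFrame({"time": scaled.times, "raw_lmi": scaled.raw,
                      "scaled_lmi": scaled.scaled,
                      "defined": scaled.defined}).to_csv(
            outdir / f"lmi_{tag}.csv", index=False)
        if scaled.defined.any():
            peak = float(scaled.times[np.nanargmax(
                np.where(scaled.defined, scaled.raw, -np.inf))])
            half = config.lmi_window_hours / 24.0 / 2.0
            window = (peak - half, peak + half)
            summary = summarize_window(dists[scaled.pair], scaled, window)
            for metric, quants in (("distance", summary.distance_quantiles),
                                   ("lmi", summary.lmi_quantiles)):
                rows.append({"pair": tag,
                             "window_start": summary.window[0],
                             "window_end": summary.window[1],
                             "metric": metric,
                             "min": quants[0], "q1": quants[1],
                             "q2": quants[2], "q3": quants[3],
                             "max": quants[4]})
    pd.DataFrame(rows, columns=["pair", "window_start", "window_end",
                                "metric", "min", "q1", "q2", "q3",
                                "max"]).to_csv(
        outdir / "peak_windows.csv", index=False)

    manifest = {
        "movefda_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "animals": sorted(models),
        "pairs": [list(p) for p in pairs],
        "skipped_pairs": skipped,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
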