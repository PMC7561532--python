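"""End-to-end orchestration: synthetic data or CSV inputs through
preprocessing, imputation, movement-state modeling, time budgets, home
ranges, and step-selection regression, with a JSON run report.

Every tunable defaults to the analysis protocol: 2-h fix interval,
8-day bursts with at most 4 consecutive missed fixes, 95% isopleths,
10 random steps per used step, 0.85 predictive-power threshold. The
global seed fans out to per-stage seeds by stable hashing of stage
names so stages can be rerun in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import budget as budget_mod
from . import issa as issa_mod
from .ctcrw import fit_ctcrw, impute_missing
from .hmm import default_start_grid, multistart_fit, select_model, state_posteriors, viterbi
from .homerange import ranges_table, seasonal_ranges
from .io import read_tracks, write_tracks
from .landscape import LandscapeStack
from .preprocess import extract_bursts, filter_speed, rarefy, steps_from_burst
from .synth import LandscapeSpec, TrackSpec, make_landscape, simulate_track
from .temporal import assign_temporal, light_period_durations

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    landscape_spec: LandscapeSpec = field(default_factory=lambda: LandscapeSpec(grid_size=1024))
    track_specs: list = field(default_factory=list)
    tracks_csv: str | None = None  # real relocation table instead of synth
    landscape_dir: str | None = None  # saved landscape stack instead of synth
    n_animals: int = 3
    reference_lat: float = 46.7
    reference_lon: float = -60.6
    interval_h: float = 2.0
    min_days: float = 8.0
    max_consecutive_missing: int = 4
    isopleth: float = 95.0
    homerange_interval_h: float = 7.0
    n_random_steps: int = 10
    predictive_threshold: float = 0.85
    min_strata: int = 20
    hmm_states: tuple = (2, 3, 4)
    seed: int = 0
    outdir: str = "carnmove_run"


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; writes artifacts under ``config.outdir``.

    Any stage error propagates with the stage name prepended; artifacts
    written before the failure are preserved.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    stage = "synth"
    try:
        if config.landscape_dir is not None:
            landscape = LandscapeStack.load(config.landscape_dir)
        else:
            landscape = make_landscape(config.landscape_spec)
        landscape.save(out / "landscape")
        if config.tracks_csv is not None:
            fixes = read_tracks(config.tracks_csv)
        else:
            specs = config.track_specs or [
                TrackSpec(seed=stage_seed(config.seed, f"track{i}"))
                for i in range(config.n_animals)
            ]
            tracks = []
            for i, spec in enumerate(specs):
                sim, _ = simulate_track(spec, landscape)
                tracks.append(sim.assign(id=f"animal{i}"))
            fixes = pd.concat(tracks, ignore_index=True)
        write_tracks(fixes, out / "tracks_raw.csv")
        report["stages"][stage] = {
            "n_fixes": int(len(fixes)),
            "n_animals": int(fixes["id"].nunique()),
        }

        stage = "preprocess"
        observed = fixes[~fixes["missing"].astype(bool)]
        cleaned, removed = filter_speed(observed)
        rarefied = rarefy(cleaned, config.interval_h)
        bursts = extract_bursts(
            rarefied, config.interval_h, config.min_days, config.max_consecutive_missing
        )
        report["stages"][stage] = {
            "n_observed": int(len(observed)),
            "n_removed_speed": int(len(removed)),
            "n_rarefied": int(len(rarefied)),
            "n_in_burst_observed": int(sum(b.n_slots - b.n_missing for b in bursts)),
            "n_bursts": len(bursts),
            "burst_days": [round(b.length_days, 2) for b in bursts],
        }

        stage = "ctcrw"
        n_imputed = 0
        imputed_bursts = []
        for j, b in enumerate(bursts):
            if b.n_missing > 0:
                params = fit_ctcrw(b)
                b = impute_missing(b, params, seed=stage_seed(config.seed, f"impute{j}"))
                n_imputed += int((b.fixes["source"] == "imputed").sum())
            imputed_bursts.append(b)
        bursts = imputed_bursts
        report["stages"][stage] = {"n_imputed": n_imputed}

        stage = "temporal"
        steps_parts = []
        for j, b in enumerate(bursts):
            s = steps_from_burst(b)
            s["burst_id"] = j
            elev = _sample_dem_clipped(landscape, s["x_end"].to_numpy(), s["y_end"].to_numpy())
            s = assign_temporal(
                s.rename(columns={"t_end": "timestamp"}),
                config.reference_lat,
                config.reference_lon,
                elev,
            ).rename(columns={"timestamp": "t_end"})
            steps_parts.append(s)
        steps = pd.concat(steps_parts, ignore_index=True)
        report["stages"][stage] = {"n_steps": int(len(steps))}

        stage = "hmm"
        candidates, decodings = {}, {}
        for n in config.hmm_states:
            model = multistart_fit(steps, n, start_grid=default_start_grid(n))
            candidates[n] = model
            decodings[n] = state_posteriors(model, steps)
        chosen, criteria = select_model(
            candidates, decodings, predictive_threshold=config.predictive_threshold
        )
        (out / "movement_model.json").write_text(chosen.to_json())
        decoding = decodings[chosen.n_states]
        steps["state"] = decoding.path
        steps["state_prob"] = decoding.max_posterior
        steps.to_csv(out / "steps_decoded.csv", index=False)
        report["stages"][stage] = {
            "selected_states": chosen.n_states,
            "criteria": criteria,
            "state_means_m": chosen.mu.tolist(),
        }

        stage = "budget"
        retained = steps[~steps["imputed"].astype(bool)]
        counts = budget_mod.counts_from_decoded(retained)
        durations = _mean_light_durations(retained, config)
        table = budget_mod.budget_table(counts, durations)
        table.to_csv(out / "time_budget.csv", index=False)
        report["stages"][stage] = {"n_retained_steps": int(len(retained))}

        stage = "homerange"
        hr_fixes = rarefy(cleaned, config.homerange_interval_h)
        elev = _sample_dem_clipped(landscape, hr_fixes["x"].to_numpy(), hr_fixes["y"].to_numpy())
        hr_fixes = assign_temporal(hr_fixes, config.reference_lat, config.reference_lon, elev)
        ranges, skipped = seasonal_ranges(hr_fixes, isopleth=config.isopleth)
        ranges_table(ranges).to_csv(out / "home_ranges.csv", index=False)
        report["stages"][stage] = {"n_ranges": len(ranges), "skipped": skipped}

        stage = "issa"
        strata = issa_mod.build_strata(
            retained,
            landscape,
            n_random=config.n_random_steps,
            seed=stage_seed(config.seed, "issa"),
        )
        fits = {}
        skipped_sets = []
        for key, ds in issa_mod.partition_steps(strata).items():
            try:
                fits[key] = issa_mod.fit_clogit(ds, min_strata=config.min_strata, dataset_key=key)
            except (ValueError, np.linalg.LinAlgError) as exc:
                skipped_sets.append({"dataset": list(key), "reason": str(exc)})
        results = issa_mod.results_long(fits)
        results.to_csv(out / "selection_results.csv", index=False)
        report["stages"][stage] = {
            "n_strata": int(strata["stratum"].nunique()) if len(strata) else 0,
            "n_datasets_fit": len(fits),
            "skipped": skipped_sets,
        }
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _sample_dem_clipped(landscape, x, y):
    """DEM elevations with coordinates clipped to the grid envelope.

    Imputed fixes can fall marginally outside the raster; their season
    depends only on elevation regime, so edge clipping is harmless.
    """
    xmin, ymin, xmax, ymax = landscape.bounds
    eps = 1e-6 * landscape.cellsize
    return landscape.dem.sample(
        np.clip(x, xmin, xmax - eps), np.clip(y, ymin, ymax - eps)
    )


def _mean_light_durations(steps: pd.DataFrame, config: RunConfig) -> dict:
    """Mean daily light-period durations per season over the span."""
    durations = {}
    for season, grp in steps.groupby("season", sort=True):
        dates = pd.to_datetime(grp["t_end"]).dt.date.unique()
        sample = dates[:: max(1, len(dates) // 20)]
        per_light: dict[str, list] = {}
        for d in sample:
            for light, hours in light_period_durations(
                config.reference_lat, config.reference_lon, d
            ).items():
                per_light.setdefault(light, []).append(hours)
        for light, vals in per_light.items():
            durations[(str(season), light)] = float(np.mean(vals))
    return durations
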