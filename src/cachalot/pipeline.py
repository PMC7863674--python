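"""End-to-end orchestration: simulate -> filter -> home range ->
pseudo-absences -> fit -> predict -> dive report.

One configuration (YAML-able dict) drives every stage; a manifest
records the seeds, per-stage row counts and output checksums so a rerun
with the same config and seed is bit-identical. Stages run in fixed
order and a failure halts the run with a stage-tagged error, keeping
partial outputs on disk.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dive as dive_mod
from . import ensemble, envlayers, homerange, pseudoabsence, synthetic, tracks

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "cachalot_out",
    "seasons": ["wet", "dry"],
    "simulate": {
        "extent": [55.0, 61.4, -22.4, -16.0],
        "cell_size": 0.08,
        "n_individuals": 4,
        "duration_days": 25,
        "fixes_per_day": 8,
        "mean_speed_kmh": 2.9,
        "bias_weight": 0.7,
        "outlier_prob": 0.02,
        "suitability": {
            "intercept": -1.0,
            "coefficients": {"ssh": 3.0, "bottom_temperature": -2.5},
        },
        "dive_n_records": 400,
    },
    "filters": {"vmax_kmh": 7.0, "min_locations": 10},
    "homerange": {"multiplier": None, "levels": [0.5, 0.9]},
    "pseudo_absence": {"method": "convex-hull", "inflate": 0.0, "n_runs": 3},
    "fit": {
        "algorithms": ["RF", "LDA", "NB"],
        "folds": 10,
        "repeats": 3,
        "train_fraction": 0.8,
        "vif_threshold": 4.0,
        "tune_rf": True,
        "stacking": False,
    },
    "dive": {"deep_threshold_m": 200.0},
}

SEASON_STARTS = {"wet": "2018-12-01", "dry": "2016-05-04"}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and an override dict."""

    def merge(base, extra):
        for k, v in (extra or {}).items():
            if isinstance(v, dict) and isinstance(base.get(k), dict):
                merge(base[k], v)
            else:
                base[k] = v
        return base

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path:
        with open(path) as fh:
            merge(cfg, yaml.safe_load(fh) or {})
    return merge(cfg, overrides or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _seeds(master: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n) % (2**31)]


def stage_simulate(cfg: dict, state: dict, outdir: Path) -> None:
    sim = cfg["simulate"]
    suit_spec = synthetic.SuitabilitySpec(
        intercept=sim["suitability"]["intercept"],
        coefficients=dict(sim["suitability"]["coefficients"]))
    seeds = _seeds(cfg["seed"], 4 * len(cfg["seasons"]))
    state["stacks"], state["suits"], state["raw_tracks"] = {}, {}, {}
    counts = {}
    for i, season in enumerate(cfg["seasons"]):
        env_spec = synthetic.EnvFieldSpec(
            extent=tuple(sim["extent"]), cell_size=sim["cell_size"],
            season=season, seed=seeds[4 * i])
        stack = synthetic.generate_env_stack(env_spec)
        suit = synthetic.true_suitability(stack, suit_spec)
        track_spec = synthetic.TrackSimSpec(
            n_individuals=sim["n_individuals"],
            fixes_per_day=sim["fixes_per_day"],
            mean_speed_kmh=sim["mean_speed_kmh"],
            bias_weight=sim["bias_weight"],
            outlier_prob=sim["outlier_prob"],
            start_date=SEASON_STARTS[season],
            duration_days=sim["duration_days"],
            seed=seeds[4 * i + 1])
        trks = synthetic.generate_tracks(stack, suit, track_spec)
        state["stacks"][season] = stack
        state["suits"][season] = suit
        state["raw_tracks"][season] = synthetic.tracks_to_frame(trks)
        state["raw_tracks"][season]["id"] = (
            state["raw_tracks"][season]["id"] + f"_{season}")
        counts[season] = len(state["raw_tracks"][season])
        synthetic.tracks_to_csv(trks, outdir / f"tracks_raw_{season}.csv")
        stack.to_csv(outdir / f"env_{season}.csv")
    dive_spec = synthetic.DiveSimSpec(n_records=sim["dive_n_records"],
                                      seed=seeds[2])
    state["dives"] = synthetic.generate_dive_records(dive_spec)
    state["dives"].to_csv(outdir / "dives.csv", index=False)
    state["manifest"]["simulate"] = {"fixes": counts,
                                     "dives": len(state["dives"])}


def stage_tracks(cfg: dict, state: dict, outdir: Path) -> None:
    filt = cfg["filters"]
    state["clean_tracks"], summaries = {}, []
    counts = {}
    for season, raw in state["raw_tracks"].items():
        stack = state["stacks"][season]
        kept = []
        for _, g in raw.groupby("id"):
            g = tracks.speed_filter(g, filt["vmax_kmh"])
            g = tracks.land_filter(g, stack)
            kept.append(g)
        clean = pd.concat(kept, ignore_index=True)
        clean["season"] = tracks.assign_season(clean["timestamp"])
        clean = tracks.eligible_tracks(clean, filt["min_locations"])
        state["clean_tracks"][season] = clean
        counts[season] = len(clean)
        clean.to_csv(outdir / f"tracks_filtered_{season}.csv", index=False)
        summaries.append(tracks.summarize_all(clean))
    summary = pd.concat(summaries, ignore_index=True)
    summary.to_csv(outdir / "track_summaries.csv", index=False)
    tracks.season_means(summary).to_csv(outdir / "season_means.csv", index=False)
    state["manifest"]["tracks"] = {"kept_fixes": counts,
                                   "summaries": len(summary)}


def stage_homerange(cfg: dict, state: dict, outdir: Path) -> None:
    info = {}
    state["home_ranges"] = {}
    for season, clean in state["clean_tracks"].items():
        ud, meta = homerange.season_home_range(
            clean["lon"].to_numpy(), clean["lat"].to_numpy(),
            multiplier=cfg["homerange"]["multiplier"])
        state["home_ranges"][season] = ud
        rows = []
        for level in cfg["homerange"]["levels"]:
            c = homerange.probability_contour(ud, level, with_polygons=False)
            rows.append({"season": season, "level": level,
                         "area_km2": c.area_km2, "fragments": c.n_fragments})
        pd.DataFrame(rows).to_csv(outdir / f"homerange_{season}.csv", index=False)
        if meta["diagnostics"] is not None:
            meta["diagnostics"].to_csv(outdir / f"bandwidth_sweep_{season}.csv",
                                       index=False)
        info[season] = {"h_ref": meta["h_ref"], "multiplier": meta["multiplier"],
                        "mass": ud.total_mass}
    state["manifest"]["homerange"] = info


def stage_pseudo_absence(cfg: dict, state: dict, outdir: Path) -> None:
    pa = cfg["pseudo_absence"]
    seeds = _seeds(cfg["seed"] + 1, len(cfg["seasons"]))
    state["backgrounds"], state["envelopes"], state["runs"] = {}, {}, {}
    info = {}
    for i, season in enumerate(cfg["seasons"]):
        stack = state["stacks"][season]
        clean = state["clean_tracks"][season]
        variables = [n for n in stack.layers if n != "bathymetry"]
        bg = pseudoabsence.fit_background_pca(stack, variables)
        scores = pseudoabsence.presence_scores(bg, stack,
                                               clean["lon"].to_numpy(),
                                               clean["lat"].to_numpy())
        env = pseudoabsence.presence_envelope(scores, pa["method"], pa["inflate"])
        runs = pseudoabsence.build_runs(bg, env, n=len(clean),
                                        n_runs=pa["n_runs"],
                                        master_seed=seeds[i])
        state["backgrounds"][season] = bg
        state["envelopes"][season] = env
        state["runs"][season] = runs
        all_runs = pd.concat(
            [r.cells.assign(run=r.run) for r in runs], ignore_index=True)
        all_runs.to_csv(outdir / f"pseudo_absences_{season}.csv", index=False)
        with open(outdir / f"envelope_{season}.json", "w") as fh:
            json.dump({"seed": seeds[i], **env.describe()}, fh, indent=2)
        info[season] = {"n_presences": len(clean), "n_runs": len(runs),
                        "explained_variance": bg.explained.tolist()}
    state["manifest"]["pseudo_absence"] = info


def _run_design(state, cfg, season, run):
    """Presence + pseudo-absence design for one run, 0-1 scaled covariates."""
    stack = state["stacks"][season]
    clean = state["clean_tracks"][season]
    variables = state["backgrounds"][season].variables
    scaled = envlayers.scale_stack(stack, variables)
    pres = envlayers.extract_at_points(scaled, clean["lon"].to_numpy(),
                                      clean["lat"].to_numpy(), variables)
    pres = pres.loc[pres["valid"]]
    absn = envlayers.extract_at_points(scaled, run.cells["lon"].to_numpy(),
                                       run.cells["lat"].to_numpy(), variables)
    absn = absn.loc[absn["valid"]]
    X = pd.concat([pres[variables], absn[variables]], ignore_index=True)
    y = np.r_[np.ones(len(pres), dtype=int), np.zeros(len(absn), dtype=int)]
    return X, y, variables, scaled.scaling


def stage_fit(cfg: dict, state: dict, outdir: Path) -> None:
    fit = cfg["fit"]
    registry = ensemble.default_registry()
    if fit["algorithms"] != "all":
        registry = {k: registry[k] for k in fit["algorithms"]}
    state["fits"], state["tuned"], state["stacks_model"] = {}, {}, {}
    state["designs"] = {}
    metric_rows = []
    info = {}
    for season in cfg["seasons"]:
        runs = state["runs"][season]
        seeds = _seeds(cfg["seed"] + 2, len(runs))
        state["fits"][season], state["tuned"][season] = [], []
        state["stacks_model"][season] = []
        state["designs"][season] = []
        for k, run in enumerate(runs):
            X, y, variables, scaling = _run_design(state, cfg, season, run)
            Xtr, Xval, ytr, yval = ensemble.partition_data(
                X, y, fit["train_fraction"], seeds[k])
            vif = envlayers.vif_screen(Xtr, fit["vif_threshold"])
            if not vif["pass"].all():
                log.warning("season %s run %d: VIF >= %.1f for %s", season,
                            run.run, fit["vif_threshold"],
                            ", ".join(vif.loc[~vif["pass"], "variable"]))
            results = ensemble.fit_all_algorithms(
                Xtr, ytr, Xval, yval, registry, run=run.run, seed=seeds[k],
                folds=fit["folds"], repeats=fit["repeats"])
            state["fits"][season].append(results)
            state["designs"][season].append(
                {"variables": variables, "scaling": scaling,
                 "X_val": Xval, "y_val": yval})
            tab = ensemble.metrics_table(results)
            tab.insert(0, "season", season)
            metric_rows.append(tab)
            if fit["tune_rf"]:
                tuned = ensemble.tune_random_forest(
                    Xtr, ytr, Xval, yval, run=run.run, seed=seeds[k],
                    folds=fit["folds"], repeats=fit["repeats"])
                tuned.importances = ensemble.variable_importance(
                    tuned.model, Xval, yval, variables, seed=seeds[k])
                state["tuned"][season].append(tuned)
                trow = ensemble.metrics_table([tuned])
                trow.insert(0, "season", season)
                metric_rows.append(trow)
            if fit["stacking"]:
                stacked = ensemble.stack_models(Xtr, ytr, registry,
                                                seed=seeds[k],
                                                folds=min(fit["folds"], 10))
                state["stacks_model"][season].append(stacked)
        info[season] = {"runs": len(runs), "algorithms": len(registry)}
    metrics = pd.concat(metric_rows, ignore_index=True)
    metrics.to_csv(outdir / "metrics.csv", index=False)
    state["metrics"] = metrics
    state["manifest"]["fit"] = info


def stage_predict(cfg: dict, state: dict, outdir: Path) -> None:
    info = {}
    state["maps"] = {}
    for season in cfg["seasons"]:
        stack = state["stacks"][season]
        layers = []
        for tuned, design in zip(state["tuned"][season],
                                 state["designs"][season]):
            layers.append(ensemble.predict_grid(
                tuned.model, stack, design["variables"], design["scaling"]))
        maps = ensemble.aggregate_runs(layers, method="RF_tuned", season=season)
        state["maps"][season] = maps
        glon, glat = stack.cell_centres()
        pd.DataFrame({
            "lon": glon.ravel(), "lat": glat.ravel(),
            "mean_probability": maps.mean.ravel(),
            "cv_percent": maps.cv_percent.ravel(),
        }).to_csv(outdir / f"prediction_{season}.csv", index=False)
        finite_cv = maps.cv_percent[np.isfinite(maps.cv_percent)]
        info[season] = {
            "runs": maps.n_runs,
            "mean_probability": float(np.nanmean(maps.mean)),
            "median_cv_percent": float(np.median(finite_cv)),
        }
    state["manifest"]["predict"] = info


def stage_dive(cfg: dict, state: dict, outdir: Path) -> None:
    summary = dive_mod.diel_depth_test(
        state["dives"], cfg["dive"]["deep_threshold_m"])
    profile = dive_mod.dive_summary(state["dives"])
    payload = {**profile, **{k: v for k, v in summary.__dict__.items()}}
    with open(outdir / "dive_report.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    state["manifest"]["dive"] = {
        "n_deep_day": summary.n_day, "n_deep_night": summary.n_night,
        "depth_p_value": summary.depth_p_value,
    }


STAGES = [
    ("simulate", stage_simulate),
    ("tracks", stage_tracks),
    ("homerange", stage_homerange),
    ("pabs", stage_pseudo_absence),
    ("fit", stage_fit),
    ("predict", stage_predict),
    ("dive", stage_dive),
]


def run_pipeline(config: dict | None = None, out_dir=None,
                 stages: list[str] | None = None) -> dict:
    """Run the full analysis (or a prefix of it) from one configuration.

    Returns the manifest, which is also written to ``manifest.json`` in
    the output directory along with every stage product.
    """
    cfg = load_config(overrides=config or {})
    outdir = Path(out_dir or cfg["out_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {"manifest": {"seed": cfg["seed"], "config": cfg}}
    wanted = stages or [name for name, _ in STAGES]
    for name, fn in STAGES:
        if name not in wanted:
            continue
        log.info("stage %s", name)
        try:
            fn(cfg, state, outdir)
        except Exception as exc:
            raise StageError(name, exc) from exc
    checks = {p.name: _sha256(p) for p in sorted(outdir.glob("*.csv"))}
    state["manifest"]["checksums"] = checks
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(state["manifest"], fh, indent=2, default=str)
    state["out_dir"] = outdir
    return state
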