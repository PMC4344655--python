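"""End-to-end orchestration: simulate -> climatology -> preprocess -> scan
-> select -> characterize, from a single YAML-able config with one seed.

Each stage reads and writes a shared run directory so stages are
independently runnable and restartable; ``run_all`` chains them and writes
a manifest with content hashes of every artifact, so a rerun with the same
config and seed is verifiably bit-identical.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .characterize import class_summary, export_class_map, summary_ranges
from .climatology import climatology_extremes, longterm_mean, monthly_climatology
from .features import (FeatureTable, assess_collinearity, build_feature_table,
                       range_standardize, resample_bicubic, StandardizationParams)
from .grids import GridGeo, MonthlyStack, RasterGrid, combine_masks, read_grid, read_stack, write_grid, write_stack
from .selection import Scenario, enumerate_scenarios, run_scan, scan_table, select_best
from .som import SOMModel, TrainConfig, assign_labels, input_weight_planes, neighbor_weight_distances
from .synthetic import (SBS_BBOX, SynthConfig, VARIABLES, coarse_geo, make_truth,
                        synth_monthly_stack, synth_variable_fields)

__all__ = ["DEFAULTS", "validate_config", "run_all",
           "stage_simulate", "stage_climatology", "stage_preprocess",
           "stage_scan", "stage_select", "stage_characterize"]

log = logging.getLogger("seascapes")

DEFAULTS: dict = {
    "seed": 0,
    "bbox": list(SBS_BBOX),                  # lon_min, lon_max, lat_min, lat_max
    "grid": {"n_rows": 60, "n_cols": 60},
    "synthetic": {
        "K": 9,
        "noise_level": 0.04,
        "min_separation": 0.5,
        "smooth_len": 2.0,
        "seasonal_amplitude": 1.5,
        "years": 11,
        "land_fraction": 0.1,
        "coarse_factor": 3,
        "monthly_noise_sd": 0.15,            # degC, SST month-to-month noise
        "chla_monthly_log_sd": 0.3,          # lognormal monthly chla scatter
    },
    "scan": {"k_min": 4, "k_max": 25, "refine_restarts": 2},
    "train": {"steps": 1000, "radius": 3, "init": "pca_plane"},
    "si_sample": 10000,
    "sbs_inset_frac": 0.1,                   # stand-in seascape polygon inset
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {path}{key} must be a mapping")
            out[key] = _merge(defaults[key], val, f"{path}{key}.")
        else:
            out[key] = val
    return out


def validate_config(config: dict | None = None) -> dict:
    """Fill defaults, reject unknown keys, check cross-field consistency."""
    cfg = _merge(DEFAULTS, config or {})
    if cfg["scan"]["k_min"] > cfg["scan"]["k_max"]:
        raise ValueError("scan.k_min exceeds scan.k_max")
    lon0, lon1, lat0, lat1 = cfg["bbox"]
    if not (lon0 < lon1 and lat0 < lat1):
        raise ValueError("bbox must satisfy lon_min < lon_max and lat_min < lat_max")
    SynthConfig(seed=int(cfg["seed"]),
                **{k: cfg["synthetic"][k] for k in
                   ("K", "noise_level", "min_separation", "smooth_len",
                    "seasonal_amplitude", "years", "land_fraction", "coarse_factor")})
    TrainConfig(steps=cfg["train"]["steps"], init_radius=cfg["train"]["radius"],
                init=cfg["train"]["init"])
    return cfg


def _geo(cfg: dict) -> GridGeo:
    lon0, lon1, lat0, lat1 = cfg["bbox"]
    return GridGeo(lon0, lon1, lat0, lat1,
                   cfg["grid"]["n_rows"], cfg["grid"]["n_cols"])


def _synth_config(cfg: dict) -> SynthConfig:
    s = cfg["synthetic"]
    return SynthConfig(K=s["K"], noise_level=s["noise_level"],
                       min_separation=s["min_separation"], smooth_len=s["smooth_len"],
                       seasonal_amplitude=s["seasonal_amplitude"], years=s["years"],
                       land_fraction=s["land_fraction"], coarse_factor=s["coarse_factor"],
                       seed=int(cfg["seed"]))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, rundir: Path) -> None:
    """Planted truth, SST and chlorophyll monthly stacks, coarse fields.

    The SST seasonal cycle is anchored to the planted climatological
    extremes: month m = (max+min)/2 + (max-min)/2 * sin(2*pi*(m-1)/12) plus
    monthly noise, so the derived climatology recovers the planted Max/Min
    SST fields. Current/salinity analogues are generated at 1/coarse_factor
    resolution to exercise the regridding step.
    """
    geo = _geo(cfg)
    sc = _synth_config(cfg)
    inputs = rundir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    truth = make_truth(geo, sc)
    fields = synth_variable_fields(truth, sc)
    ss = np.random.SeedSequence([sc.seed, 100])
    s_sst, s_chla = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))

    center = (fields["max_sst"].masked_values() + fields["min_sst"].masked_values()) / 2
    amp = (fields["max_sst"].masked_values() - fields["min_sst"].masked_values()) / 2
    center_grid = RasterGrid(geo=geo, values=center, mask=truth.sea_mask.copy(),
                             units="degC", name="sst")
    sst_stack = synth_monthly_stack(geo, center_grid, amp, sc.years,
                                    cfg["synthetic"]["monthly_noise_sd"], s_sst)
    write_stack(sst_stack, inputs / "sst_monthly.nc", name="sst")

    rng = np.random.default_rng(s_chla)
    sig = cfg["synthetic"]["chla_monthly_log_sd"]
    chla_mean = fields["chla"].masked_values()
    chla_grids, times = [], []
    for y in range(sc.years):
        for m in range(1, 13):
            vals = chla_mean * np.exp(sig * rng.standard_normal(geo.shape) - sig * sig / 2)
            vals[~truth.sea_mask] = np.nan
            chla_grids.append(RasterGrid(geo=geo, values=vals, mask=truth.sea_mask.copy(),
                                         units="mg m-3", name="chla"))
            times.append((2003 + y, m))
    write_stack(MonthlyStack(grids=chla_grids, times=times),
                inputs / "chla_monthly.nc", name="chla")

    cgeo = coarse_geo(geo, sc.coarse_factor)
    coarse = synth_variable_fields(truth, sc, geo=cgeo,
                                   variables=("currents", "salinity"), seed_offset=2)
    write_grid(coarse["currents"], inputs / "currents_coarse.nc")
    write_grid(coarse["salinity"], inputs / "salinity_coarse.nc")

    truth_grid = RasterGrid(geo=geo, values=truth.labels, mask=truth.labels > 0,
                            units="class", name="truth")
    write_grid(truth_grid, inputs / "truth_labels.nc")
    pd.DataFrame(truth.class_means, columns=list(VARIABLES),
                 index=pd.RangeIndex(1, sc.K + 1, name="regime")
                 ).to_csv(inputs / "class_means.csv")


def stage_climatology(cfg: dict, rundir: Path) -> None:
    """Derive the six variable grids from the simulated inputs."""
    inputs, vardir = rundir / "inputs", rundir / "variables"
    vardir.mkdir(parents=True, exist_ok=True)

    sst = read_stack(inputs / "sst_monthly.nc", "sst")
    avg = longterm_mean(sst)
    vmax, vmin = climatology_extremes(monthly_climatology(sst))
    chla = longterm_mean(read_stack(inputs / "chla_monthly.nc", "chla"))
    sea = avg.mask  # SST-derived validity stands in for the land mask

    # target the stack's own geo so all six files stay bit-co-registered
    cur = resample_bicubic(read_grid(inputs / "currents_coarse.nc", "currents"),
                           avg.geo, target_mask=sea)
    sal = resample_bicubic(read_grid(inputs / "salinity_coarse.nc", "salinity"),
                           avg.geo, target_mask=sea)

    for name, grid in zip(VARIABLES, (avg, vmax, vmin, chla, cur, sal)):
        grid.name = name
        write_grid(grid, vardir / f"{name}.nc")


def stage_preprocess(cfg: dict, rundir: Path) -> None:
    """Assemble, screen, and range-standardize the feature table."""
    vardir = rundir / "variables"
    grids = {v: read_grid(vardir / f"{v}.nc", v) for v in VARIABLES}
    sea = combine_masks(list(grids.values()))
    table = build_feature_table(grids, sea)
    corr, flags = _collinearity_report(table, rundir)
    std, params = range_standardize(table)
    table.to_csv(rundir / "features.csv")
    std.to_csv(rundir / "features_std.csv")
    params.to_json(rundir / "standardization.json")
    log.info("feature table: %d sea pixels, %d collinear pair(s) flagged",
             len(table), len(flags))


def _collinearity_report(table: FeatureTable, rundir: Path):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # flags are persisted, not raised here
        corr, flags = assess_collinearity(table)
    corr.to_csv(rundir / "collinearity.csv")
    return corr, flags


def stage_scan(cfg: dict, rundir: Path) -> None:
    """Train and silhouette-score every lattice topology in the scan range."""
    geo = _geo(cfg)
    std = FeatureTable.from_csv(rundir / "features_std.csv", geo, standardized=True)
    tc = TrainConfig(steps=cfg["train"]["steps"], init_radius=cfg["train"]["radius"],
                     init=cfg["train"]["init"], seed=int(cfg["seed"]))
    scen = enumerate_scenarios(cfg["scan"]["k_min"], cfg["scan"]["k_max"])
    mdir = rundir / "models"
    mdir.mkdir(parents=True, exist_ok=True)

    def report(res):
        log.info("scenario %dx%d: mean SI %.4f (%d non-empty)",
                 res.scenario.X, res.scenario.Y, res.mean_si, res.n_nonempty)

    t0 = time.perf_counter()
    results = run_scan(std, scen, train_config=tc,
                       sample_size=cfg["si_sample"], seed=int(cfg["seed"]),
                       refine_restarts=cfg["scan"]["refine_restarts"],
                       progress=report)
    log.info("scan of %d scenarios in %.1f s", len(results), time.perf_counter() - t0)
    scan_table(results).to_csv(rundir / "scan.csv", index=False)
    for r in results:
        r.model.to_json(mdir / f"scenario_{r.scenario.X}x{r.scenario.Y}.json")


def stage_select(cfg: dict, rundir: Path) -> dict:
    """Pick the best scenario from the scan and write its model and map."""
    geo = _geo(cfg)
    scan = pd.read_csv(rundir / "scan.csv")
    valid = scan[scan["valid"]]
    if valid.empty:
        raise ValueError("no valid scenarios in scan.csv")
    best = valid.sort_values(["mean_si", "k", "X"],
                             ascending=[False, True, True]).iloc[0]
    model = SOMModel.from_json(rundir / "models" /
                               f"scenario_{int(best.X)}x{int(best.Y)}.json")
    model.to_json(rundir / "som_model.json")
    std = FeatureTable.from_csv(rundir / "features_std.csv", geo, standardized=True)
    labels = assign_labels(model, std)
    export_class_map(labels, std.pixel_index, geo, rundir / "class_map.nc")
    planes = input_weight_planes(model)
    pd.DataFrame(planes).to_csv(rundir / "weight_planes.csv", index_label="neuron")
    pd.DataFrame(neighbor_weight_distances(model),
                 columns=["neuron_i", "neuron_j", "weight_distance"]
                 ).to_csv(rundir / "neighbor_distances.csv", index=False)
    return {"X": int(best.X), "Y": int(best.Y), "mean_si": float(best.mean_si)}


def sbs_standin_mask(geo: GridGeo, inset_frac: float) -> np.ndarray:
    """Synthetic stand-in for the seascape-of-interest polygon: the bbox
    inset by ``inset_frac`` on every side (True = inside)."""
    lons, lats = geo.lon_centers(), geo.lat_centers()
    dx = (geo.lon_max - geo.lon_min) * inset_frac
    dy = (geo.lat_max - geo.lat_min) * inset_frac
    in_lon = (lons >= geo.lon_min + dx) & (lons <= geo.lon_max - dx)
    in_lat = (lats >= geo.lat_min + dy) & (lats <= geo.lat_max - dy)
    return np.outer(in_lat, in_lon)


def stage_characterize(cfg: dict, rundir: Path) -> None:
    """Class summary table and per-variable spread of class means."""
    geo = _geo(cfg)
    raw = FeatureTable.from_csv(rundir / "features.csv", geo)
    cmap = read_grid(rundir / "class_map.nc", "class_map")
    labels = cmap.values[raw.pixel_index[:, 0], raw.pixel_index[:, 1]]
    sbs = sbs_standin_mask(geo, cfg["sbs_inset_frac"])
    summary = class_summary(raw, labels, sbs)
    summary.to_csv(rundir / "class_summary.csv")
    summary_ranges(summary).to_csv(rundir / "class_mean_ranges.csv", index_label="variable")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_STAGES = [("simulate", stage_simulate), ("climatology", stage_climatology),
           ("preprocess", stage_preprocess), ("scan", stage_scan),
           ("select", stage_select), ("characterize", stage_characterize)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: dict | None, outdir) -> dict:
    """Run every stage and write a manifest of artifact hashes.

    Returns the manifest dict; any stage failure aborts with the stage name
    in the raised error.
    """
    cfg = validate_config(config)
    rundir = Path(outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    with open(rundir / "config.yml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    best = None
    for name, stage in _STAGES:
        t0 = time.perf_counter()
        try:
            out = stage(cfg, rundir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if name == "select":
            best = out
        log.info("stage %s done in %.1f s", name, time.perf_counter() - t0)

    artifacts = sorted(p for p in rundir.rglob("*")
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": int(cfg["seed"]),
        "selected": best,
        "artifacts": {str(p.relative_to(rundir)): _sha256(p) for p in artifacts},
    }
    with open(rundir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
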