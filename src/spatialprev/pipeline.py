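"""Configuration-driven end-to-end runner: simulate/load -> describe ->
model -> map -> scan -> report.

A single declarative YAML (or dict) config drives the whole workflow.  Every
stage serializes its outputs under the run directory so later stages can be
re-run in isolation, and a manifest echoes every seed, version and defaulted
assumption used on the way.
"""

from __future__ import annotations

import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bym import (FitResult, ModelSpec, fit_model, odds_ratio_table,
                  posterior_prevalence_map, select_best_model)
from .geo import AreaMap, read_area_map
from .scan import (AreaCaseData, clusters_to_dataframe, monte_carlo_pvalues,
                   secondary_clusters)
from .survey import weighted_crosstab, weighted_prevalence
from .synthetic import (TruthSet, aggregate_to_areas, default_factor_spec,
                        default_truth, make_lattice_map, simulate_survey)

__all__ = ["run_pipeline", "write_choropleth", "load_config", "validate_config"]

STAGES = ("data", "describe", "fit", "map", "scan")

_TOP_KEYS = {"input", "simulate", "seed", "factors", "model", "scan", "describe", "outdir"}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def validate_config(config: dict) -> dict:
    """Schema check; returns the config with defaults applied."""
    bad = sorted(set(config) - _TOP_KEYS)
    if bad:
        raise ValueError(f"unknown config keys: {bad}")
    has_input = "input" in config
    has_sim = "simulate" in config
    if has_input == has_sim:
        raise ValueError("config needs exactly one of 'input' or 'simulate'")
    if "seed" not in config:
        raise ValueError("config must set an explicit 'seed'")
    cfg = dict(config)
    cfg.setdefault("model", {})
    cfg["model"] = {**{"models": [1, 2, 3, 4],
                       "prior_a": 0.5, "prior_b": 0.0005, "beta_prior_precision": 1e-4,
                       "iterations": 20000, "burn_in": 5000, "thin": 5,
                       "reference_levels": {}},
                    **cfg["model"]}
    cfg.setdefault("scan", {})
    cfg["scan"] = {**{"directions": ["high", "low"], "max_fraction": 0.5,
                      "replications": 999, "alpha": 0.05, "use_weights": False},
                   **cfg["scan"]}
    if has_input:
        need = {"records_csv", "centroids_csv", "adjacency_gal"}
        missing = need - set(cfg["input"])
        if missing:
            raise ValueError(f"input block missing keys: {sorted(missing)}")
    return cfg


def _build_truth(area_map: AreaMap, sim_cfg: dict, seed: int) -> TruthSet:
    tcfg = sim_cfg.get("truth", {})
    return default_truth(
        area_map,
        beta0=float(tcfg.get("beta0", -1.0)),
        beta=tcfg.get("beta"),
        tau_s=float(tcfg.get("tau_s", 2.0)),
        tau_u=float(tcfg.get("tau_u", 10.0)),
        seed=seed,
    )


def _stage_data(cfg: dict, outdir: Path, manifest: dict):
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    if "simulate" in cfg:
        sim = cfg["simulate"]
        rows, cols = int(sim.get("rows", 5)), int(sim.get("cols", 4))
        area_map = make_lattice_map(rows, cols)
        seed = int(cfg["seed"])
        truth = _build_truth(area_map, sim, seed)
        factor_spec = sim.get("factors") or default_factor_spec()
        design = {k: sim[k] for k in
                  ("n_regions", "psus_per_area", "respondents_per_psu",
                   "weight_dispersion", "urban_fraction") if k in sim}
        records = simulate_survey(area_map, truth, design=design,
                                  factor_spec=factor_spec, seed=seed + 1)
        _write_map(area_map, datadir)
        records.to_csv(datadir / "records.csv", index=False)
        pd.DataFrame({"area_id": area_map.area_ids, "f_s": truth.f_s,
                      "f_u": truth.f_u}).to_csv(datadir / "truth_fields.csv", index=False)
        manifest["simulate"] = {"rows": rows, "cols": cols, "design": design,
                                "beta0": truth.beta0, "beta": truth.beta,
                                "tau_s": truth.tau_s, "tau_u": truth.tau_u,
                                "data_seed": seed + 1, "truth_seed": seed}
    else:
        inp = cfg["input"]
        area_map = read_area_map(inp["centroids_csv"], inp["adjacency_gal"])
        records = pd.read_csv(inp["records_csv"], dtype={"area_id": str, "psu_id": str,
                                                         "stratum_id": str})
        _write_map(area_map, datadir)
        records.to_csv(datadir / "records.csv", index=False)
        manifest["input"] = dict(inp)
    return records, area_map


def _write_map(area_map: AreaMap, datadir: Path) -> None:
    pd.DataFrame({"id": area_map.area_ids,
                  "lon": area_map.centroids[:, 0],
                  "lat": area_map.centroids[:, 1]}).to_csv(datadir / "centroids.csv", index=False)
    with open(datadir / "adjacency.gal", "w") as fh:
        fh.write(f"{area_map.n_areas}\n")
        for a in area_map.area_ids:
            nbrs = sorted(area_map.neighbors[a])
            fh.write(f"{a} {len(nbrs)}\n")
            fh.write(" ".join(nbrs) + "\n")


def _load_data(outdir: Path):
    datadir = outdir / "data"
    records = pd.read_csv(datadir / "records.csv",
                          dtype={"area_id": str, "psu_id": str, "stratum_id": str})
    area_map = read_area_map(datadir / "centroids.csv", datadir / "adjacency.gal")
    return records, area_map


def _factor_columns(records: pd.DataFrame) -> list[str]:
    reserved = {"outcome", "weight", "stratum_id", "psu_id", "area_id"}
    return [c for c in records.columns if c not in reserved]


def _stage_describe(cfg, records, outdir: Path, manifest: dict) -> None:
    est = weighted_prevalence(records)
    factors = (cfg.get("describe") or {}).get("factors") or _factor_columns(records)
    rows = [{"factor": "(overall)", "level": "", "weighted_percent": 100 * est.point,
             "unweighted_n": len(records), "F": np.nan, "p_value": np.nan,
             "ci_low": 100 * est.ci_low, "ci_high": 100 * est.ci_high}]
    for fac in factors:
        ct = weighted_crosstab(records, "outcome", fac)
        for lv in ct.levels:
            rows.append({"factor": fac, "level": lv,
                         "weighted_percent": ct.weighted_percent[lv],
                         "unweighted_n": ct.unweighted_n[lv],
                         "F": ct.F_stat, "p_value": ct.p_value,
                         "ci_low": np.nan, "ci_high": np.nan})
    pd.DataFrame(rows).to_csv(outdir / "describe.csv", index=False)
    manifest["describe"] = {"prevalence": est.point, "design_df": est.design_df,
                            "factors": factors}


def _resolve_factor_spec(cfg: dict, records) -> dict | None:
    """Factor levels for modelling: explicit config > simulation spec > inferred."""
    if cfg.get("factors"):
        return {f: list(v) for f, v in cfg["factors"].items()}
    if "simulate" in cfg:
        return {f: list(v) for f, v in
                (cfg["simulate"].get("factors") or default_factor_spec()).items()}
    return None


def _stage_fit(cfg, records, area_map, outdir: Path, manifest: dict) -> dict[int, FitResult]:
    m = cfg["model"]
    factor_spec = _resolve_factor_spec(cfg, records)
    fits: dict[int, FitResult] = {}
    comp_rows = []
    for num in m["models"]:
        spec = ModelSpec.from_number(
            int(num), prior_a=m["prior_a"], prior_b=m["prior_b"],
            beta_prior_precision=m["beta_prior_precision"],
            reference_levels=m["reference_levels"] or None,
        )
        fit = fit_model(records, area_map, spec, factor_spec=factor_spec,
                        mcmc={"iterations": m["iterations"], "burn_in": m["burn_in"],
                              "thin": m["thin"], "seed": int(cfg["seed"]) + 100 + int(num)})
        fit.save(outdir / "fits" / f"model{num}")
        odds_ratio_table(fit).to_csv(outdir / "fits" / f"model{num}" / "odds_ratios.csv",
                                     index=False)
        fits[int(num)] = fit
        comp_rows.append({"model": int(num), "dic": fit.dic, "pd": fit.pd,
                          "mean_deviance": float(fit.samples.deviance.mean())})
    comp = pd.DataFrame(comp_rows)
    if len(fits) >= 2:
        best = select_best_model(fits)
        comp["best"] = comp["model"] == best
        manifest["best_model"] = int(best)
    comp.to_csv(outdir / "model_comparison.csv", index=False)
    manifest["model"] = {k: v for k, v in m.items()}
    return fits


def _stage_map(cfg, records, area_map, fits, outdir: Path, manifest: dict) -> None:
    best = select_best_model(fits) if len(fits) >= 2 else next(iter(fits))
    fit = fits[best]
    prev = posterior_prevalence_map(fit, records, area_map)
    prev.index.name = "id"
    prev.to_csv(outdir / "prevalence_map.csv")
    write_choropleth(
        {a: {"mean": prev.loc[a, "mean"], "median": prev.loc[a, "median"],
             "q025": prev.loc[a, "q025"], "q975": prev.loc[a, "q975"]}
         for a in area_map.area_ids},
        area_map, outdir / "prevalence_map.geojson",
    )
    manifest["map"] = {"model": int(best)}


def _stage_scan(cfg, records, area_map, outdir: Path, manifest: dict) -> None:
    s = cfg["scan"]
    data = aggregate_to_areas(records, area_map.area_ids, use_weights=s["use_weights"])
    data.to_csv(outdir / "area_cases.csv")
    frames = []
    for di, direction in enumerate(s["directions"]):
        cands = monte_carlo_pvalues(data, area_map, direction=direction,
                                    max_fraction=s["max_fraction"],
                                    replications=int(s["replications"]),
                                    seed=int(cfg["seed"]) + 200 + di)
        reported = secondary_clusters(cands, s["alpha"])
        df = clusters_to_dataframe(reported)
        frames.append(df)
        if reported:
            write_choropleth(
                {a: {"cluster_rank": next((c.rank for c in reported
                                           if a in c.member_areas), None)}
                 for a in area_map.area_ids},
                area_map, outdir / f"clusters_{direction}.geojson",
            )
    report = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    report.to_csv(outdir / "clusters.csv", index=False)
    manifest["scan"] = {"max_fraction": s["max_fraction"],
                        "replications": int(s["replications"]),
                        "alpha": s["alpha"], "use_weights": s["use_weights"],
                        "directions": list(s["directions"]),
                        "aggregation": "weighted+largest-remainder" if s["use_weights"]
                                       else "unweighted counts"}


def run_pipeline(config: dict, outdir=None, stages=STAGES) -> Path:
    """Run the configured workflow; returns the run directory.

    ``stages`` selects a subset of ``("data", "describe", "fit", "map",
    "scan")``; any stage other than ``data`` will reuse serialized data
    from a previous run in the same directory when present.  A manifest
    (seeds, package version, every defaulted assumption) and a status file
    are always written; on stage failure, partial outputs are retained and
    the status file records the failing stage.
    """
    cfg = validate_config(config)
    outdir = Path(outdir or cfg.get("outdir") or "run")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": int(cfg["seed"]),
                      "stages": list(stages)}
    status = {"completed": [], "failed": None}
    records = area_map = None
    fits: dict[int, FitResult] = {}
    try:
        for stage in STAGES:
            if stage not in stages and stage != "data":
                continue
            t0 = time.perf_counter()
            if stage == "data":
                if "data" in stages or not (outdir / "data" / "records.csv").exists():
                    records, area_map = _stage_data(cfg, outdir, manifest)
                else:
                    records, area_map = _load_data(outdir)
            elif stage == "describe":
                _stage_describe(cfg, records, outdir, manifest)
            elif stage == "fit":
                fits = _stage_fit(cfg, records, area_map, outdir, manifest)
            elif stage == "map":
                if not fits:
                    fits = _load_fits(outdir)
                _stage_map(cfg, records, area_map, fits, outdir, manifest)
            elif stage == "scan":
                _stage_scan(cfg, records, area_map, outdir, manifest)
            manifest.setdefault("wall_time_s", {})[stage] = round(time.perf_counter() - t0, 3)
            status["completed"].append(stage)
    except Exception as exc:  # keep partial outputs + status on failure
        status["failed"] = {"stage": stage, "error": repr(exc)}
        _write_json(outdir / "manifest.json", manifest)
        _write_json(outdir / "status.json", status)
        raise
    _write_json(outdir / "manifest.json", manifest)
    _write_json(outdir / "status.json", status)
    return outdir


def _load_fits(outdir: Path) -> dict[int, FitResult]:
    fitdir = outdir / "fits"
    if not fitdir.exists():
        raise FileNotFoundError("no fitted models found; run the fit stage first")
    fits = {}
    for sub in sorted(fitdir.iterdir()):
        if (sub / "meta.json").exists():
            fit = FitResult.load(sub)
            fits[fit.spec.number] = fit
    return fits


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_choropleth(area_values: dict, area_map: AreaMap, path) -> Path:
    """Write one GeoJSON feature per area (point geometry at the centroid).

    ``area_values`` maps area id -> value or dict of properties.  Numeric
    properties are rounded to 6 decimals; a missing area gets a null value
    and a warning.  An empty map yields an empty FeatureCollection.
    """
    features = []
    idx = area_map.index
    missing = [a for a in area_map.area_ids if a not in area_values]
    if missing:
        warnings.warn(f"no value for areas {missing}; writing null properties")
    for a in area_map.area_ids:
        lon, lat = area_map.centroids[idx[a]]
        val = area_values.get(a)
        if isinstance(val, dict):
            props = {k: _round6(v) for k, v in val.items()}
        else:
            props = {"value": _round6(val)}
        props["area_id"] = a
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [round(float(lon), 6),
                                                          round(float(lat), 6)]},
            "properties": props,
        })
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def _round6(v):
    if v is None:
        return None
    if isinstance(v, (int, np.integer)):
        return int(v)
    try:
        return round(float(v), 6)
    except (TypeError, ValueError):
        return v
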