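"""End-to-end pipeline: detections -> events -> indices -> curves -> model.

Produces the study's standard report bundle as plain delimited text with a
JSON metadata sidecar:

* ``events_summary.csv`` — independent-event sums and per-camera means by
  species, hunting effort and placement;
* ``rai_trail_index.csv`` — pooled RAI (trail/forest) and trail index with
  location-bootstrap percentile CIs per species x effort;
* ``differences.csv`` — forest-vs-trail RAI contrasts and cross-effort
  trail-index contrasts with significance flags (CI excluding zero);
* ``activity_curves.csv`` / ``activity_subsets.csv`` — activity densities
  for every kept disturbance subset, and the kept/dropped bookkeeping;
* ``nocturnality_<species>.csv`` — beta-binomial coefficient tables, plus
  prediction grids.

Bit-exact reproducibility under a fixed seed is part of the contract; the
sidecar records the seed and row/subsets dropped at each stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, activity, events, nocturnality, sun

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    detections: str = ""
    deployments: str = ""
    hunting_calendar: str = ""
    outdir: str = "results/run"
    human_threshold_s: float = events.HUMAN_THRESHOLD_S
    wildlife_threshold_s: float = events.WILDLIFE_THRESHOLD_S
    min_subset_events: int = activity.MIN_EVENTS
    bootstrap_reps: int = 1000
    seed: int = 1
    ci_level: float = 0.95
    species: list[str] = field(default_factory=list)
    human_label: str = "human"
    sun_lat: float = sun.DEFAULT_LAT
    sun_lon: float = sun.DEFAULT_LON
    model_method: str = "ml"
    visibility_layers: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def load_inputs(config: RunConfig) -> dict:
    det = events.read_detections(config.detections)
    dep = events.read_deployments(config.deployments)
    cal = events.read_hunting_calendar(config.hunting_calendar)
    return {"detections": det, "deployments": dep, "calendar": cal}


def independent_events(config: RunConfig, detections: pd.DataFrame, calendar) -> dict:
    """Split detections into species/human streams and apply the class
    thresholds (8 s recreation, 5 min wildlife), then annotate effort."""
    is_human = detections["class_label"] == config.human_label
    human = events.filter_independent(detections[is_human], config.human_threshold_s)
    wild = events.filter_independent(detections[~is_human], config.wildlife_threshold_s)
    human = events.annotate_effort(human, calendar)
    wild = events.annotate_effort(wild, calendar)
    return {"human": human, "wildlife": wild}


def events_summary(
    wild: pd.DataFrame, deployments: pd.DataFrame, trapdays: pd.DataFrame
) -> pd.DataFrame:
    """Independent-event sums and per-camera means by species x effort x placement.

    The mean divides the stratum sum by the number of that placement's
    cameras with positive trap days in the stratum, recomputable from
    sibling columns.
    """
    dep = deployments[["camera_id", "placement"]]
    ev = wild.merge(dep, on="camera_id", how="left")
    td = trapdays.merge(dep, on="camera_id", how="left")
    n_cams = (
        td[td["n_active_days"] > 0]
        .groupby(["effort", "placement"])["camera_id"]
        .nunique()
        .rename("n_cameras")
    )
    sums = (
        ev.groupby(["class_label", "effort", "placement"])
        .size()
        .rename("n_events")
        .reset_index()
        .rename(columns={"class_label": "species"})
    )
    out = sums.merge(n_cams, on=["effort", "placement"], how="left")
    out["mean_per_camera"] = out["n_events"] / out["n_cameras"]
    return out.sort_values(["species", "effort", "placement"]).reset_index(drop=True)


def abundance_tables(
    config: RunConfig,
    wild: pd.DataFrame,
    trapdays: pd.DataFrame,
    deployments: pd.DataFrame,
    calendar,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled RAI + trail index with CIs, and the contrast table.

    One location-draw matrix per species is shared across efforts and
    statistics, so trail-vs-forest and cross-effort contrasts are paired
    replicate-by-replicate.
    """
    rng = np.random.default_rng(config.seed)
    species_list = config.species or sorted(wild["class_label"].unique())
    efforts = [e for e in ("high", "medium", "low") if e in set(calendar.labels)]
    rai_rows, diff_rows = [], []
    for sp in species_list:
        ev_sp = wild[wild["class_label"] == sp]
        loc_tables = {
            eff: abundance.pooled_location_table(ev_sp, trapdays, deployments, eff)
            for eff in efforts
        }
        n_loc = len(loc_tables[efforts[0]])
        draws = abundance.location_draws(n_loc, config.bootstrap_reps, rng)
        ests = {
            eff: abundance.stratum_estimates(
                loc_tables[eff], draws=draws, ci_level=config.ci_level, label=f"{sp}:{eff}"
            )
            for eff in efforts
        }
        for eff in efforts:
            e = ests[eff]
            rai_rows.append(
                {
                    "species": sp, "effort": eff,
                    "rai_trail": e["rai_trail"].value,
                    "rai_trail_ci_low": e["rai_trail"].ci_low,
                    "rai_trail_ci_high": e["rai_trail"].ci_high,
                    "rai_forest": e["rai_forest"].value,
                    "rai_forest_ci_low": e["rai_forest"].ci_low,
                    "rai_forest_ci_high": e["rai_forest"].ci_high,
                    "trail_index": e["trail_index"].value,
                    "trail_index_ci_low": e["trail_index"].ci_low,
                    "trail_index_ci_high": e["trail_index"].ci_high,
                }
            )
            d = abundance.difference_with_ci(
                e["rai_forest"], e["rai_trail"],
                label=f"{sp}:{eff}:forest-vs-trail", ci_level=config.ci_level,
            )
            diff_rows.append(
                {
                    "species": sp, "contrast": "rai_forest_vs_trail", "effort": eff,
                    "difference": d.difference, "ci_low": d.ci_low, "ci_high": d.ci_high,
                    "significant": d.significant,
                }
            )
        for eff_a, eff_b in (("high", "medium"), ("high", "low"), ("medium", "low")):
            if eff_a not in ests or eff_b not in ests:
                continue
            d = abundance.difference_with_ci(
                ests[eff_a]["trail_index"], ests[eff_b]["trail_index"],
                label=f"{sp}:trail_index:{eff_a}-vs-{eff_b}", ci_level=config.ci_level,
            )
            diff_rows.append(
                {
                    "species": sp, "contrast": f"trail_index_{eff_a}_vs_{eff_b}", "effort": "",
                    "difference": d.difference, "ci_low": d.ci_low, "ci_high": d.ci_high,
                    "significant": d.significant,
                }
            )
    return pd.DataFrame(rai_rows), pd.DataFrame(diff_rows)


def activity_tables(
    config: RunConfig,
    wild: pd.DataFrame,
    human: pd.DataFrame,
    deployments: pd.DataFrame,
    calendar,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Solar-radian annotation, median recreation split, subset build, KDE."""
    td_period = events.compute_trap_days(deployments, calendar, by_period=True)
    rec_rai = abundance.recreation_rai_per_camera(human, td_period, deployments)
    splits = activity.median_split_recreation(rec_rai, deployments)
    wild = wild.copy()
    wild["solar_radians"] = [
        sun.to_solar_radians(t, config.sun_lat, config.sun_lon) for t in wild["event_time"]
    ]
    kept, subset_report = activity.build_subsets(
        wild, deployments, splits, min_events=config.min_subset_events
    )
    rng = np.random.default_rng(config.seed + 1)
    curve_rows = []
    for key, times in kept.items():
        curve = activity.fit_activity_kde(
            times, B=config.bootstrap_reps, seed=int(rng.integers(2**31))
        )
        sp, eff, plc, rec, zone = key
        curve_rows.append(
            pd.DataFrame(
                {
                    "species": sp, "effort": eff, "placement": plc,
                    "recreation": rec, "zone": zone,
                    "solar_radians": curve.grid, "density": curve.density,
                    "ci_low": curve.ci_low, "ci_high": curve.ci_high,
                    "n_events": curve.n_events, "kappa": curve.kappa,
                }
            )
        )
    curves = (
        pd.concat(curve_rows, ignore_index=True)
        if curve_rows
        else pd.DataFrame(
            columns=["species", "effort", "placement", "recreation", "zone",
                     "solar_radians", "density", "ci_low", "ci_high", "n_events", "kappa"]
        )
    )
    return curves, subset_report


def nocturnality_tables(
    config: RunConfig,
    wild: pd.DataFrame,
    human: pd.DataFrame,
    deployments: pd.DataFrame,
    calendar,
) -> dict[str, dict]:
    """Per-species day/night aggregation, design, beta-binomial fit, predictions."""
    td_period = events.compute_trap_days(deployments, calendar, by_period=True)
    rec_rai = abundance.recreation_rai_per_camera(human, td_period, deployments)
    layers = {**nocturnality.DEFAULT_VISIBILITY_LAYER, **config.visibility_layers}
    out = {}
    for sp in config.species or sorted(wild["class_label"].unique()):
        ev_sp = wild[wild["class_label"] == sp]
        if ev_sp.empty:
            continue
        rows = nocturnality.aggregate_day_night(
            ev_sp, deployments, calendar, recreation_rai=rec_rai,
            lat=config.sun_lat, lon=config.sun_lon,
        )
        rows = rows[rows["recreation_rai"].notna()].copy()
        rows["visibility"] = rows[layers.get(sp, "vis70")]
        try:
            X, k, n, scaling = nocturnality.build_design(rows)
            fit = nocturnality.fit_betabinom(X, k, n, method=config.model_method, scaling=scaling)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("nocturnality fit failed for %s: %s", sp, exc)
            out[sp] = {"error": str(exc)}
            continue
        out[sp] = {"rows": rows, "fit": fit, "summary": fit.summary()}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config)
    dep, cal = inputs["deployments"], inputs["calendar"]
    ev = independent_events(config, inputs["detections"], cal)
    trapdays = events.compute_trap_days(dep, cal)

    summary = events_summary(ev["wildlife"], dep, trapdays)
    rai_tbl, diff_tbl = abundance_tables(config, ev["wildlife"], trapdays, dep, cal)
    curves, subset_report = activity_tables(config, ev["wildlife"], ev["human"], dep, cal)
    noct = nocturnality_tables(config, ev["wildlife"], ev["human"], dep, cal)

    summary.to_csv(outdir / "events_summary.csv", index=False)
    rai_tbl.to_csv(outdir / "rai_trail_index.csv", index=False, float_format="%.6f")
    diff_tbl.to_csv(outdir / "differences.csv", index=False, float_format="%.6f")
    curves.to_csv(outdir / "activity_curves.csv", index=False, float_format="%.6g")
    subset_report.to_csv(outdir / "activity_subsets.csv", index=False)
    for sp, res in noct.items():
        if "summary" in res:
            res["summary"].to_csv(outdir / f"nocturnality_{sp}.csv", float_format="%.6f")

    meta = {
        "seed": config.seed,
        "bootstrap_reps": config.bootstrap_reps,
        "n_detections": int(len(inputs["detections"])),
        "n_wildlife_events": int(len(ev["wildlife"])),
        "n_human_events": int(len(ev["human"])),
        "n_subsets_kept": int(subset_report["kept"].sum()) if len(subset_report) else 0,
        "n_subsets_dropped": int((~subset_report["kept"]).sum()) if len(subset_report) else 0,
        "nocturnality": {
            sp: ("error" if "error" in res else
                 {"converged": bool(res["fit"].converged), "phi": float(res["fit"].phi)})
            for sp, res in noct.items()
        },
    }
    with open(outdir / "run_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return {
        "events_summary": summary, "rai": rai_tbl, "differences": diff_tbl,
        "curves": curves, "subsets": subset_report, "nocturnality": noct, "meta": meta,
    }
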