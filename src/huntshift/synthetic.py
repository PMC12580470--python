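"""Synthetic camera-trap study generator with known ground truth.

Emulates the structure of a paired trail/forest camera-trap study in a
mid-latitude protected area: 61 location pairs (one trail and one forest
camera each), a ~13-month study window, a hunting calendar whose monthly
shares produce low (<5%), medium (5-10%) and high (>10%) effort strata,
diurnal recreation streams on trail cameras (with trigger bursts that
exercise the 8 s independence rule), and species event streams whose
circadian density and night share respond to disturbance covariates through
a known model — so every downstream stage (filtering, RAI, activity curves,
nocturnality regression) can be tested against the generating truth.

Generative choices: event counts per camera-day are Poisson (the minimal
counting model, under which the RAI estimates the true rate without bias);
clock times follow a two-stage scheme — first night vs day by inverse-logit
of the configured nocturnality coefficients on that camera x effort's
covariates, then a time from the circadian von Mises mixture restricted to
the chosen period — so the beta-binomial regression is correctly specified
under the generator; camera outages are independent Bernoulli days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as Date
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from . import sun
from .events import EffortCalendar, classify_shares, format_exclusions

TWO_PI = 2.0 * math.pi

# default monthly hunting weights (Jan..Dec): Feb-May < 5%, Jun-Sep 5-10%,
# Oct-Jan > 10% of the yearly total
DEFAULT_HUNT_WEIGHTS = (14, 3, 3, 3, 3, 6, 6, 7, 7, 15, 18, 15)


@dataclass(frozen=True)
class CircadianTruth:
    """Ground-truth circadian model for one species.

    The von Mises mixture is the species' unconditional clock-time density
    (radians over the 24 h circle, 0 = midnight); ``nocturnality_coefs``
    maps design-column names (as produced by the nocturnality model's
    design builder) to true coefficients on z-scored covariates.
    """

    mixture_weights: tuple[float, ...] = (0.5, 0.5)
    mixture_means: tuple[float, ...] = (TWO_PI * 5.5 / 24, TWO_PI * 19.5 / 24)
    mixture_kappas: tuple[float, ...] = (2.5, 2.5)
    base_rate_trail: float = 0.08
    base_rate_forest: float = 0.08
    nocturnality_coefs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.mixture_weights, float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be a simplex")
        if min(self.mixture_kappas) < 0:
            raise ValueError("kappas must be nonnegative")
        if self.base_rate_trail < 0 or self.base_rate_forest < 0:
            raise ValueError("rates must be nonnegative")


def default_species_params() -> dict[str, CircadianTruth]:
    crepuscular = dict(
        mixture_weights=(0.5, 0.5),
        mixture_means=(TWO_PI * 5.5 / 24, TWO_PI * 19.5 / 24),
        mixture_kappas=(2.5, 2.5),
    )
    nocturnal = dict(
        mixture_weights=(1.0,), mixture_means=(TWO_PI * 1.0 / 24,), mixture_kappas=(1.5,)
    )
    return {
        "red_deer": CircadianTruth(
            **crepuscular, base_rate_trail=0.065, base_rate_forest=0.075,
            nocturnality_coefs={
                "Intercept": 1.0, "effort[medium]": -0.5, "effort[low]": -0.9,
                "placement[forest]": -0.3, "dist_hunting_zone_m": -0.4,
                "recreation_rai": 0.4, "visibility": -0.1,
            },
        ),
        "roe_deer": CircadianTruth(
            **crepuscular, base_rate_trail=0.025, base_rate_forest=0.035,
            nocturnality_coefs={
                "Intercept": 0.0, "effort[medium]": -0.2, "effort[low]": -0.3,
                "placement[forest]": -0.2, "recreation_rai": 0.3,
            },
        ),
        "wild_boar": CircadianTruth(
            **nocturnal, base_rate_trail=0.02, base_rate_forest=0.04,
            nocturnality_coefs={"Intercept": 1.2, "effort[low]": -0.4},
        ),
        "red_fox": CircadianTruth(
            **nocturnal, base_rate_trail=0.05, base_rate_forest=0.008,
            nocturnality_coefs={"Intercept": 0.8, "recreation_rai": 0.2},
        ),
        "lynx": CircadianTruth(
            **nocturnal, base_rate_trail=0.015, base_rate_forest=0.002,
            nocturnality_coefs={"Intercept": 0.9},
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    n_location_pairs: int = 61
    study_start: Date = Date(2020, 11, 15)
    study_end: Date = Date(2021, 12, 5)
    latitude_band: tuple[float, float] = (48.9, 49.1)
    longitude_band: tuple[float, float] = (13.2, 13.6)
    frac_in_hunting_zone: float = 0.4
    max_distance_to_zone_m: float = 3933.0
    monthly_hunt_weights: tuple[float, ...] = DEFAULT_HUNT_WEIGHTS
    total_hunts: int = 400
    species_params: dict[str, CircadianTruth] = field(default_factory=default_species_params)
    recreation_rate_by_camera: float = 6.0  # mean human events per trail-camera day
    recreation_rate_sigma: float = 0.8  # lognormal spread across cameras
    burst_prob: float = 0.15  # chance a human event is a multi-trigger burst
    outage_prob_per_day: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_location_pairs < 2:
            raise ValueError("need at least 2 location pairs")
        n_months = (
            (self.study_end.year - self.study_start.year) * 12
            + self.study_end.month - self.study_start.month + 1
        )
        if n_months < 3:
            raise ValueError("study interval must span at least 3 calendar months")
        if len(self.monthly_hunt_weights) != 12 or min(self.monthly_hunt_weights) < 0:
            raise ValueError("monthly_hunt_weights must be 12 nonnegative values")
        if self.recreation_rate_by_camera < 0 or self.outage_prob_per_day < 0:
            raise ValueError("rates and probabilities must be nonnegative")


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _study_months(config: SimConfig) -> list[Date]:
    out = []
    m = Date(config.study_start.year, config.study_start.month, 1)
    stop = Date(config.study_end.year, config.study_end.month, 1)
    while m <= stop:
        out.append(m)
        m = Date(m.year + (m.month == 12), m.month % 12 + 1, 1)
    return out


# ---------------------------------------------------------------------------
# deployments


def generate_deployments(config: SimConfig) -> pd.DataFrame:
    """One trail and one forest camera per location, with covariates and
    per-camera outage exclusions. Hunting-zone cameras sit at distance 0; the
    rest draw distances in (0, max]."""
    rng = _rng_for(config, 0)
    n = config.n_location_pairs
    rows = []
    in_zone = rng.random(n) < config.frac_in_hunting_zone
    lat = rng.uniform(*config.latitude_band, size=n)
    lon = rng.uniform(*config.longitude_band, size=n)
    dist = np.where(in_zone, 0.0, rng.uniform(1.0, config.max_distance_to_zone_m, size=n))
    n_days = (config.study_end - config.study_start).days + 1
    for i in range(n):
        loc = f"L{i + 1:03d}"
        vis50 = rng.uniform(0.38, 0.65)
        vis70 = rng.uniform(0.67, 0.96)
        vis140 = rng.uniform(0.71, 0.97)
        for placement in ("trail", "forest"):
            outage = rng.random(n_days) < config.outage_prob_per_day
            rows.append(
                {
                    "camera_id": f"{loc}_{placement}",
                    "location_id": loc,
                    "placement": placement,
                    "lat": round(float(lat[i]), 5),
                    "lon": round(float(lon[i]), 5),
                    "in_hunting_zone": bool(in_zone[i]),
                    "dist_hunting_zone_m": round(float(dist[i]), 1),
                    "vis50": round(vis50, 3),
                    "vis70": round(vis70, 3),
                    "vis140": round(vis140, 3),
                    "start": config.study_start,
                    "end": config.study_end,
                    "exclusions": _runs_to_intervals(outage, config.study_start),
                }
            )
    return pd.DataFrame(rows)


def _runs_to_intervals(mask: np.ndarray, start: Date) -> list[tuple[Date, Date]]:
    out = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j + 1 < len(mask) and mask[j + 1]:
                j += 1
            out.append((start + timedelta(days=i), start + timedelta(days=j)))
            i = j + 1
        else:
            i += 1
    return out


def active_days(row) -> list[Date]:
    excluded = set()
    for a, b in row["exclusions"]:
        d = a
        while d <= b:
            excluded.add(d)
            d += timedelta(days=1)
    out = []
    d = row["start"]
    while d <= row["end"]:
        if d not in excluded:
            out.append(d)
        d += timedelta(days=1)
    return out


# ---------------------------------------------------------------------------
# hunting calendar


def generate_hunting_calendar(config: SimConfig) -> tuple[pd.DataFrame, EffortCalendar]:
    """Monthly successful-hunt counts over the study window plus the effort
    calendar.

    Counts are proportional to the configured month-of-year weights, and the
    low/medium/high classification uses each calendar month's share of the
    yearly total (so a month repeated across two study years carries the
    same label in both, as when two hunting seasons pool into one high
    stratum).
    """
    w = np.asarray(config.monthly_hunt_weights, float)
    if w.sum() == 0:
        raise ValueError("all-zero monthly hunt weights")
    yearly = np.round(w / w.sum() * config.total_hunts).astype(int)
    labels_moy = classify_shares(yearly)
    months = _study_months(config)
    counts = [int(yearly[m.month - 1]) for m in months]
    labels = [labels_moy[m.month - 1] for m in months]
    cal = EffortCalendar(months=months, counts=[float(c) for c in counts], labels=labels)
    df = pd.DataFrame(
        {"month": [m.strftime("%Y-%m") for m in months], "hunt_count": counts, "effort": labels}
    )
    return df, cal


# ---------------------------------------------------------------------------
# covariate design shared with the nocturnality model


def _truth_linear_predictor(
    deployments: pd.DataFrame, truth: CircadianTruth, rec_rate: dict[str, float]
) -> dict[tuple[str, str], float]:
    """True logit night-share per (camera_id, effort), z-scoring covariates
    across the generated study exactly as the fitted model will."""
    dep = deployments.copy()
    loc_rec = {
        r["location_id"]: rec_rate.get(f"{r['location_id']}_trail", 0.0) * 100.0
        for _, r in dep.iterrows()
    }
    dep["recreation_rai"] = dep["location_id"].map(loc_rec)
    dep["visibility"] = dep["vis70"]

    def z(x):
        s = x.std(ddof=0)
        return (x - x.mean()) / s if s > 0 else x * 0.0

    zdist = z(dep["dist_hunting_zone_m"])
    zrec = z(dep["recreation_rai"])
    zvis = z(dep["visibility"])
    out = {}
    coefs = truth.nocturnality_coefs
    for i, (_, row) in enumerate(dep.iterrows()):
        for effort in ("high", "medium", "low"):
            feats = {
                "Intercept": 1.0,
                "effort[medium]": 1.0 if effort == "medium" else 0.0,
                "effort[low]": 1.0 if effort == "low" else 0.0,
                "placement[forest]": 1.0 if row["placement"] == "forest" else 0.0,
                "dist_hunting_zone_m": zdist.iloc[i],
                "recreation_rai": zrec.iloc[i],
                "visibility": zvis.iloc[i],
            }
            feats["effort[medium]:placement[forest]"] = (
                feats["effort[medium]"] * feats["placement[forest]"]
            )
            feats["effort[low]:placement[forest]"] = (
                feats["effort[low]"] * feats["placement[forest]"]
            )
            for base in ("dist_hunting_zone_m", "recreation_rai", "visibility"):
                for cat in ("effort[medium]", "effort[low]", "placement[forest]"):
                    feats[f"{cat}:{base}"] = feats[cat] * feats[base]
                for e in ("effort[medium]", "effort[low]"):
                    feats[f"{e}:placement[forest]:{base}"] = (
                        feats[e] * feats["placement[forest]"] * feats[base]
                    )
            lp = sum(v * feats.get(k, 0.0) for k, v in coefs.items())
            out[(row["camera_id"], effort)] = lp
    return out


# ---------------------------------------------------------------------------
# event streams


def _draw_mixture(rng: np.random.Generator, truth: CircadianTruth) -> float:
    comp = rng.choice(len(truth.mixture_weights), p=truth.mixture_weights)
    k = truth.mixture_kappas[comp]
    if k == 0:
        return rng.uniform(0, TWO_PI)
    return float(rng.vonmises(truth.mixture_means[comp] - math.pi, k) + math.pi)


def _clock_to_instant(day: Date, theta: float) -> datetime:
    seconds = theta / TWO_PI * 86400.0
    return datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(seconds=seconds)


def simulate_species_events(
    deployments: pd.DataFrame,
    truth: CircadianTruth,
    calendar: EffortCalendar,
    seed: int,
    species: str = "species",
    rec_rate: dict[str, float] | None = None,
    lat: float = sun.DEFAULT_LAT,
    lon: float = sun.DEFAULT_LON,
) -> pd.DataFrame:
    """Detection stream for one species over the active days of all cameras.

    Per camera-day the trigger count is Poisson at the placement's base
    rate; each event first chooses night vs day by the inverse-logit of the
    true linear predictor for that camera x effort, then draws a clock time
    from the circadian mixture restricted to the chosen period (rejection
    against the nautical-twilight classifier, falling back to a uniform draw
    within the period when the mixture carries almost no mass there).
    """
    rng = np.random.default_rng(seed)
    lp_map = _truth_linear_predictor(deployments, truth, rec_rate or {})
    rows = []
    for _, cam in deployments.iterrows():
        rate = truth.base_rate_trail if cam["placement"] == "trail" else truth.base_rate_forest
        if rate == 0:
            continue
        for day in active_days(cam):
            n = rng.poisson(rate)
            if n == 0:
                continue
            try:
                effort = calendar.stratum_of(day)
            except KeyError:
                continue
            p_night = 1.0 / (1.0 + math.exp(-lp_map[(cam["camera_id"], effort)]))
            for _ in range(n):
                want_night = rng.random() < p_night
                theta = None
                for _try in range(200):
                    cand = _draw_mixture(rng, truth)
                    inst = _clock_to_instant(day, cand)
                    if sun.is_night(inst, lat, lon) == want_night:
                        theta = cand
                        break
                if theta is None:
                    inst = _uniform_in_period(rng, day, want_night, lat, lon)
                else:
                    inst = _clock_to_instant(day, theta)
                rows.append(
                    {"camera_id": cam["camera_id"], "timestamp": inst, "class_label": species}
                )
    df = pd.DataFrame(rows, columns=["camera_id", "timestamp", "class_label"])
    return df.sort_values(["camera_id", "timestamp"]).reset_index(drop=True)


def _uniform_in_period(
    rng: np.random.Generator, day: Date, want_night: bool, lat: float, lon: float
) -> datetime:
    st = sun.twilight_times(lat, lon, day)
    if want_night:
        nxt = sun.twilight_times(lat, lon, day + timedelta(days=1))
        span = (nxt.nautical_dawn_end - st.nautical_dusk_start).total_seconds()
        return st.nautical_dusk_start + timedelta(seconds=rng.uniform(0, span))
    span = (st.nautical_dusk_start - st.nautical_dawn_end).total_seconds()
    return st.nautical_dawn_end + timedelta(seconds=rng.uniform(0, span))


def simulate_recreation_events(
    deployments: pd.DataFrame,
    rates: dict[str, float],
    seed: int,
    burst_prob: float = 0.15,
) -> pd.DataFrame:
    """Human detection stream on trail cameras only.

    Clock times follow a midday-peaked normal (13:00 +- 2.5 h, clipped to
    04-22 h). A configurable fraction of events are bursts — several extra
    triggers 1-6 s apart, emulating groups passing in quick succession —
    which downstream 8 s filtering must collapse to single events.
    """
    if min(rates.values(), default=0.0) < 0:
        raise ValueError("recreation rates must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for _, cam in deployments.iterrows():
        if cam["placement"] != "trail":
            continue
        rate = rates.get(cam["camera_id"], 0.0)
        if rate == 0:
            continue
        for day in active_days(cam):
            n = rng.poisson(rate)
            for _ in range(n):
                hour = float(np.clip(rng.normal(13.0, 2.5), 4.0, 22.0))
                t0 = datetime(day.year, day.month, day.day, tzinfo=timezone.utc) + timedelta(
                    hours=hour
                )
                rows.append({"camera_id": cam["camera_id"], "timestamp": t0, "class_label": "human"})
                if rng.random() < burst_prob:
                    extra = rng.integers(1, 5)
                    t = t0
                    for _k in range(extra):
                        t = t + timedelta(seconds=float(rng.uniform(1.0, 6.0)))
                        rows.append(
                            {"camera_id": cam["camera_id"], "timestamp": t, "class_label": "human"}
                        )
    df = pd.DataFrame(rows, columns=["camera_id", "timestamp", "class_label"])
    return df.sort_values(["camera_id", "timestamp"]).reset_index(drop=True)


def draw_recreation_rates(config: SimConfig, deployments: pd.DataFrame) -> dict[str, float]:
    """Lognormal per-trail-camera daily human event rates around the mean."""
    rng = _rng_for(config, 1)
    out = {}
    mu = math.log(config.recreation_rate_by_camera) - config.recreation_rate_sigma**2 / 2
    for cam in deployments.loc[deployments["placement"] == "trail", "camera_id"]:
        out[cam] = float(rng.lognormal(mu, config.recreation_rate_sigma))
    return out


# ---------------------------------------------------------------------------
# full study


def simulate_study(config: SimConfig) -> dict:
    """Generate the complete synthetic study: deployments, hunting calendar,
    recreation and species detection streams. Deterministic in ``config.seed``."""
    deployments = generate_deployments(config)
    hunts, calendar = generate_hunting_calendar(config)
    rates = draw_recreation_rates(config, deployments)
    rec = simulate_recreation_events(
        deployments, rates, seed=int(_rng_for(config, 2).integers(2**31)),
        burst_prob=config.burst_prob,
    )
    frames = [rec]
    for i, (species, truth) in enumerate(sorted(config.species_params.items())):
        frames.append(
            simulate_species_events(
                deployments, truth, calendar,
                seed=int(_rng_for(config, 3 + i).integers(2**31)),
                species=species, rec_rate=rates,
            )
        )
    detections = pd.concat(frames, ignore_index=True)
    detections = detections.sort_values(["camera_id", "timestamp"]).reset_index(drop=True)
    return {
        "config": config,
        "deployments": deployments,
        "hunting": hunts,
        "calendar": calendar,
        "recreation_rates": rates,
        "detections": detections,
    }


# ---------------------------------------------------------------------------
# writers (same delimited formats the event pipeline reads)


def write_study(study: dict, outdir) -> dict[str, str]:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = study["config"].seed
    paths = {}

    dep = study["deployments"].copy()
    dep["exclusions"] = dep["exclusions"].apply(format_exclusions)
    paths["deployments"] = str(outdir / "deployments.csv")
    _write_with_header(dep, paths["deployments"], seed)

    det = study["detections"].copy()
    det["timestamp"] = det["timestamp"].map(lambda t: t.isoformat())
    paths["detections"] = str(outdir / "detections.csv")
    _write_with_header(det, paths["detections"], seed)

    paths["hunting"] = str(outdir / "hunting_calendar.csv")
    _write_with_header(study["hunting"][["month", "hunt_count"]], paths["hunting"], seed)
    return paths


def _write_with_header(df: pd.DataFrame, path: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# generated by huntshift.synthetic, seed={seed}\n")
        df.to_csv(fh, index=False)
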