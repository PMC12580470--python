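"""Relative abundance index (RAI), trail index, and location-level bootstrap.

The RAI is independent events per 100 trapping days, pooled over the cameras
of a stratum (species x hunting effort x placement). Trail use relative to
forest use is summarized by the trail index

    trail_index = ln((RAI_trail + 1) / (RAI_forest + 1)),

positive when a species is recorded relatively more on trails. The natural
log reproduces the published worked values; the +1 shift keeps zero-event
strata finite.

Uncertainty comes from a nonparametric bootstrap over *camera locations*:
location ids are resampled with replacement, and a resampled location
contributes both its trail and its forest camera, so trail and forest RAIs
inside one replicate are computed from the same draw. Confidence intervals
are percentile (2.5/97.5). Contrasts (trail vs forest, stratum vs stratum)
difference the statistic replicate-by-replicate on shared location draws and
call the difference significant when the CI excludes zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def rai(n_events: float, trap_days: float) -> float:
    """Independent events per 100 trap-days. ``trap_days`` must be positive."""
    if trap_days <= 0:
        raise ValueError("trap_days must be positive; exclude inactive cameras upstream")
    if n_events < 0:
        raise ValueError("n_events must be nonnegative")
    return 100.0 * n_events / trap_days


def trail_index(rai_trail: float, rai_forest: float) -> float:
    """ln((RAI_trail + 1)/(RAI_forest + 1)); antisymmetric under swapping."""
    if rai_trail < 0 or rai_forest < 0:
        raise ValueError("RAI values must be nonnegative")
    return math.log((rai_trail + 1.0) / (rai_forest + 1.0))


@dataclass
class StratifiedEstimate:
    """Point estimate with bootstrap replicates and a percentile CI."""

    label: str
    value: float
    replicates: np.ndarray
    ci_low: float
    ci_high: float
    n_events: float | None = None
    trap_days: float | None = None
    n_dropped_replicates: int = 0


@dataclass
class DifferenceEstimate:
    label: str
    difference: float
    ci_low: float
    ci_high: float
    significant: bool


def location_draws(n_locations: int, B: int, rng: np.random.Generator) -> np.ndarray:
    """(B, n_locations) matrix of location indices resampled with replacement.

    Share one matrix across strata so cross-stratum contrasts are paired.
    """
    if n_locations < 1:
        raise ValueError("need at least one location")
    return rng.integers(0, n_locations, size=(B, n_locations))


def _percentile_ci(reps: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    return (
        float(np.percentile(reps, 100 * alpha)),
        float(np.percentile(reps, 100 * (1 - alpha))),
    )


def bootstrap_locations(
    per_location: pd.DataFrame,
    statistic,
    B: int = 1000,
    seed: int | None = None,
    draws: np.ndarray | None = None,
    ci_level: float = 0.95,
    label: str = "",
) -> StratifiedEstimate:
    """Bootstrap a statistic of a location multiset.

    ``per_location`` has one row per location id; ``statistic`` maps a
    DataFrame of (possibly repeated) location rows to a float. Replicates on
    which the statistic is undefined (raises ``ValueError`` or returns NaN,
    e.g. all resampled trap days zero) are dropped and counted.
    """
    if len(per_location) < 1:
        raise ValueError("need at least one location")
    point = statistic(per_location)
    if draws is None:
        rng = np.random.default_rng(seed)
        draws = location_draws(len(per_location), B, rng)
    reps = []
    dropped = 0
    for idx in draws:
        try:
            v = statistic(per_location.iloc[idx])
        except ValueError:
            v = float("nan")
        if np.isnan(v):
            dropped += 1
        else:
            reps.append(v)
    if dropped:
        logger.info("bootstrap %s: %d/%d replicate(s) undefined, dropped", label, dropped, len(draws))
    reps = np.asarray(reps, dtype=float)
    lo, hi = _percentile_ci(reps, ci_level) if len(reps) else (float("nan"),) * 2
    return StratifiedEstimate(
        label=label, value=float(point), replicates=reps, ci_low=lo, ci_high=hi,
        n_dropped_replicates=dropped,
    )


def difference_with_ci(
    est_a: StratifiedEstimate, est_b: StratifiedEstimate, label: str = "", ci_level: float = 0.95
) -> DifferenceEstimate:
    """a - b with a percentile CI on replicate-wise differences.

    Replicate vectors must be equal length and built on the same location
    draws wherever the strata share locations.
    """
    if len(est_a.replicates) != len(est_b.replicates):
        raise ValueError("replicate vectors must have equal length for paired differencing")
    diff = est_a.value - est_b.value
    reps = est_a.replicates - est_b.replicates
    lo, hi = _percentile_ci(reps, ci_level)
    return DifferenceEstimate(
        label=label, difference=diff, ci_low=lo, ci_high=hi,
        significant=bool(lo > 0 or hi < 0),
    )


# ---------------------------------------------------------------------------
# pooled tables


def pooled_location_table(
    events: pd.DataFrame,
    trapdays: pd.DataFrame,
    deployments: pd.DataFrame,
    effort: str,
) -> pd.DataFrame:
    """Per-location event counts and trap days for one effort stratum.

    One row per location id with trail/forest event counts and trap days —
    the resampling unit of the bootstrap (paired cameras move together).
    ``events`` must carry ``camera_id`` and ``effort``.
    """
    dep = deployments[["camera_id", "location_id", "placement"]]
    td = trapdays[trapdays["effort"] == effort].merge(dep, on="camera_id", how="left")
    ev = events[events["effort"] == effort].merge(dep, on="camera_id", how="left")
    ev_counts = ev.groupby(["location_id", "placement"]).size().unstack(fill_value=0)
    td_sum = td.groupby(["location_id", "placement"])["n_active_days"].sum().unstack(fill_value=0)
    out = pd.DataFrame(index=td_sum.index)
    for plc in ("trail", "forest"):
        out[f"events_{plc}"] = ev_counts[plc] if plc in ev_counts else 0
        out[f"days_{plc}"] = td_sum[plc] if plc in td_sum else 0.0
    return out.fillna(0).reset_index()


def _pooled_rai(tbl: pd.DataFrame, placement: str) -> float:
    days = tbl[f"days_{placement}"].sum()
    if days <= 0:
        raise ValueError(f"no active {placement} trap days in replicate")
    return 100.0 * tbl[f"events_{placement}"].sum() / days


def stratum_estimates(
    loc_table: pd.DataFrame,
    B: int = 1000,
    seed: int | None = None,
    draws: np.ndarray | None = None,
    ci_level: float = 0.95,
    label: str = "",
) -> dict[str, StratifiedEstimate]:
    """Pooled trail RAI, forest RAI, and trail index with shared-draw bootstrap."""
    if draws is None:
        rng = np.random.default_rng(seed)
        draws = location_draws(len(loc_table), B, rng)
    out = {}
    out["rai_trail"] = bootstrap_locations(
        loc_table, lambda t: _pooled_rai(t, "trail"), draws=draws, ci_level=ci_level,
        label=f"{label}:rai_trail",
    )
    out["rai_forest"] = bootstrap_locations(
        loc_table, lambda t: _pooled_rai(t, "forest"), draws=draws, ci_level=ci_level,
        label=f"{label}:rai_forest",
    )
    out["trail_index"] = bootstrap_locations(
        loc_table,
        lambda t: trail_index(_pooled_rai(t, "trail"), _pooled_rai(t, "forest")),
        draws=draws, ci_level=ci_level, label=f"{label}:trail_index",
    )
    return out


def recreation_rai_per_camera(
    events: pd.DataFrame,
    trapdays_by_period: pd.DataFrame,
    deployments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Recreation RAI per trail camera per effort *period*.

    ``events`` are independent human events annotated with ``effort`` and
    ``effort_period``; ``trapdays_by_period`` uses ``label#period`` keys from
    :func:`huntshift.events.compute_trap_days` with ``by_period=True``. The
    recreation RAI is a trail-camera quantity: when ``deployments`` is given,
    forest cameras' trap-day rows are excluded. The two high-effort seasons
    stay separate here (the median split needs them separate); pooling
    happens downstream. Cameras with zero trap days in a period get a
    missing RAI and are logged.
    """
    if deployments is not None:
        trail_cams = set(
            deployments.loc[deployments["placement"] == "trail", "camera_id"]
        )
        trapdays_by_period = trapdays_by_period[
            trapdays_by_period["camera_id"].isin(trail_cams)
        ]
    ev = events.copy()
    ev["effort_key"] = ev["effort"] + "#" + ev["effort_period"].astype(int).astype(str)
    counts = ev.groupby(["camera_id", "effort_key"]).size().rename("n_events")
    td = trapdays_by_period.rename(columns={"effort": "effort_key"})
    out = td.merge(counts, on=["camera_id", "effort_key"], how="left")
    out["n_events"] = out["n_events"].fillna(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rai"] = np.where(
            out["n_active_days"] > 0, 100.0 * out["n_events"] / out["n_active_days"], np.nan
        )
    n_missing = out["rai"].isna().sum()
    if n_missing:
        logger.info("%d camera-period(s) with zero trap days: RAI missing", n_missing)
    out[["effort", "period"]] = out["effort_key"].str.split("#", expand=True)
    out["period"] = out["period"].astype(int)
    return out[["camera_id", "effort", "period", "n_events", "n_active_days", "rai"]]
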