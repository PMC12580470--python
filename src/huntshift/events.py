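"""Detection ingestion, independence filtering, trap days, and hunting-effort strata.

Raw camera-trap triggers arrive as one row per image. Downstream indices work
on *independent events*: a new event starts when the gap to the immediately
preceding trigger of the same camera x class is at least a class-specific
threshold (8 s for recreational activity, 5 min for wildlife). Gaps chain
record-to-record, so a long burst of closely spaced triggers collapses to a
single event however long it lasts.

Trapping days — the denominator of the relative abundance index — count whole
calendar days a camera was active and unobstructed, with per-camera exclusion
intervals (outages, snow on the lens) subtracted as a union of days.

Hunting effort strata classify each study month by its share of all successful
hunting events: low < 5%, medium 5-10% (boundaries inclusive), high > 10%.
Non-contiguous windows with the same label (the two high-effort hunting
seasons) pool into a single stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["camera_id", "timestamp", "class_label"]
DEPLOYMENT_COLUMNS = [
    "camera_id",
    "location_id",
    "placement",
    "lat",
    "lon",
    "in_hunting_zone",
    "dist_hunting_zone_m",
    "vis50",
    "vis70",
    "vis140",
    "start",
    "end",
    "exclusions",
]

#: independence thresholds in seconds
HUMAN_THRESHOLD_S = 8.0
WILDLIFE_THRESHOLD_S = 300.0


def read_detections(path, tz: str = "UTC", reject_log: str | None = None) -> pd.DataFrame:
    """Read a detection table (``camera_id,timestamp,class_label``).

    Timestamps are parsed as ISO-8601 with offset and normalized to ``tz``.
    Rows with unparseable timestamps are dropped and reported (with 1-based
    data line numbers) to the log and optionally to ``reject_log``.

    Raises ``ValueError`` if a required column is missing.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"detection file {path} missing required column(s): {missing}")
    parsed = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = parsed.isna() & df["timestamp"].notna()
    if bad.any():
        lines = (df.index[bad] + 1).tolist()
        msg = f"{int(bad.sum())} row(s) with unparseable timestamps at data lines {lines[:20]}"
        logger.warning("%s: %s", path, msg)
        if reject_log is not None:
            with open(reject_log, "w") as fh:
                for ln in lines:
                    fh.write(f"{path}\tline {ln}\t{df.loc[ln - 1, 'timestamp']}\n")
    out = df.loc[~bad & parsed.notna(), DETECTION_COLUMNS].copy()
    out["timestamp"] = parsed[out.index].dt.tz_convert(tz)
    return out.reset_index(drop=True)


def read_deployments(path) -> pd.DataFrame:
    """Read the deployment table; parses dates and the semicolon-joined
    ``start/end`` ISO exclusion ranges into lists of ``(date, date)`` tuples."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in DEPLOYMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"deployment file {path} missing required column(s): {missing}")
    df["start"] = pd.to_datetime(df["start"]).dt.date
    df["end"] = pd.to_datetime(df["end"]).dt.date
    df["exclusions"] = df["exclusions"].apply(parse_exclusions)
    df["in_hunting_zone"] = df["in_hunting_zone"].astype(bool)
    return df


def parse_exclusions(text) -> list[tuple[Date, Date]]:
    """``"2021-01-03/2021-01-05;2021-02-10/2021-02-10"`` -> list of date pairs."""
    if text is None or (isinstance(text, float) and np.isnan(text)) or str(text).strip() == "":
        return []
    out = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        a, _, b = chunk.partition("/")
        d0 = pd.Timestamp(a).date()
        d1 = pd.Timestamp(b).date() if b else d0
        out.append((d0, d1))
    return out


def format_exclusions(intervals: list[tuple[Date, Date]]) -> str:
    return ";".join(f"{a.isoformat()}/{b.isoformat()}" for a, b in intervals)


# ---------------------------------------------------------------------------
# independence filtering


def filter_independent(
    records: pd.DataFrame,
    threshold_seconds: float,
    key: tuple[str, ...] = ("camera_id", "class_label"),
) -> pd.DataFrame:
    """Collapse triggers into independent events.

    Within each ``key`` group, sorted by time, a trigger starts a new event
    when its gap to the *immediately preceding trigger* is >= the threshold;
    a gap strictly below the threshold extends the current event
    (record-to-record chaining). The event time is the first trigger's time.

    Returns columns ``key + (event_time, n_triggers)`` sorted by (key, time).
    """
    if threshold_seconds <= 0:
        raise ValueError("threshold_seconds must be positive")
    if records.empty:
        return pd.DataFrame(columns=[*key, "event_time", "n_triggers"])
    df = records.sort_values([*key, "timestamp"], kind="mergesort").reset_index(drop=True)
    gap = df.groupby(list(key), sort=False)["timestamp"].diff().dt.total_seconds()
    new_event = gap.isna() | (gap >= threshold_seconds)
    event_id = new_event.cumsum()
    out = (
        df.assign(_eid=event_id)
        .groupby([*key, "_eid"], sort=False)
        .agg(event_time=("timestamp", "first"), n_triggers=("timestamp", "size"))
        .reset_index()
        .drop(columns="_eid")
    )
    return out.sort_values([*key, "event_time"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# hunting effort calendar

LOW, MEDIUM, HIGH = "low", "medium", "high"


@dataclass
class EffortCalendar:
    """Monthly hunt counts classified into low/medium/high effort strata.

    ``months`` are the first-of-month dates of the study window in order;
    ``labels`` the stratum of each month. Contiguous runs of equal labels form
    *periods* (so the two high-effort hunting seasons are separate periods of
    one pooled stratum).
    """

    months: list[Date]
    counts: list[float]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.labels:
            self.labels = classify_shares(self.counts)

    def stratum_of(self, d: Date) -> str:
        m = Date(d.year, d.month, 1)
        try:
            return self.labels[self.months.index(m)]
        except ValueError:
            raise KeyError(f"date {d} outside the effort calendar") from None

    def periods(self) -> list[tuple[str, Date, Date]]:
        """Contiguous (label, first_month, last_month_end) runs."""
        out: list[tuple[str, Date, Date]] = []
        for m, lab in zip(self.months, self.labels):
            end = _month_end(m)
            if out and out[-1][0] == lab and out[-1][2] + timedelta(days=1) == m:
                out[-1] = (lab, out[-1][1], end)
            else:
                out.append((lab, m, end))
        return out

    def windows(self, stratum: str) -> list[tuple[Date, Date]]:
        return [(a, b) for lab, a, b in self.periods() if lab == stratum]

    @property
    def strata(self) -> list[str]:
        seen = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen


def _month_end(m: Date) -> Date:
    nxt = Date(m.year + (m.month == 12), m.month % 12 + 1, 1)
    return nxt - timedelta(days=1)


def classify_shares(counts) -> list[str]:
    """Label each month by its share of total hunting events.

    share < 5% -> low; 5% <= share <= 10% -> medium; share > 10% -> high.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("hunt counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero hunt counts: cannot classify effort")
    shares = counts / total
    return [LOW if s < 0.05 else (MEDIUM if s <= 0.10 else HIGH) for s in shares]


def classify_effort(monthly_hunt_counts: dict[Date, float] | pd.Series) -> EffortCalendar:
    """Build an :class:`EffortCalendar` from month -> successful-hunt counts.

    Each month's share is taken relative to its own calendar year's total
    (the convention of yearly hunting statistics), so a study window longer
    than twelve months does not dilute the shares and a month-of-year keeps
    the same label across study years.
    """
    if isinstance(monthly_hunt_counts, pd.Series):
        items = list(monthly_hunt_counts.items())
    else:
        items = sorted(monthly_hunt_counts.items())
    months = [Date(pd.Timestamp(m).year, pd.Timestamp(m).month, 1) for m, _ in items]
    counts = [float(c) for _, c in items]
    labels: list[str | None] = [None] * len(months)
    for year in {m.year for m in months}:
        idx = [i for i, m in enumerate(months) if m.year == year]
        year_labels = classify_shares([counts[i] for i in idx])
        for i, lab in zip(idx, year_labels):
            labels[i] = lab
    return EffortCalendar(months=months, counts=counts, labels=labels)


def read_hunting_calendar(path) -> EffortCalendar:
    """Read ``month,hunt_count`` (month as YYYY-MM) into an effort calendar."""
    df = pd.read_csv(path, comment="#")
    months = {pd.Timestamp(m).date(): c for m, c in zip(df["month"], df["hunt_count"])}
    return classify_effort(months)


# ---------------------------------------------------------------------------
# trap days


def _excluded_days(
    exclusions: list[tuple[Date, Date]], lo: Date, hi: Date, camera_id=None
) -> set[Date]:
    """Union of excluded days clipped to [lo, hi]."""
    days: set[Date] = set()
    for a, b in exclusions:
        if b < lo or a > hi:
            continue
        if a < lo or b > hi:
            logger.warning(
                "camera %s: exclusion %s/%s extends outside deployment window; clipped",
                camera_id, a, b,
            )
        d = max(a, lo)
        stop = min(b, hi)
        while d <= stop:
            days.add(d)
            d += timedelta(days=1)
    return days


def compute_trap_days(
    deployments: pd.DataFrame,
    calendar: EffortCalendar,
    by_period: bool = False,
) -> pd.DataFrame:
    """Active trapping days per camera x effort stratum.

    Days are whole calendar days in the intersection of the deployment window
    and the stratum's month windows, minus the union of excluded days; partial
    first/last deployment days count as active. With ``by_period=True`` the
    two non-contiguous high-effort seasons are reported as ``high#0``/``high#1``
    instead of pooled (used by the per-period recreation split).

    Returns columns ``camera_id, effort, n_active_days``.
    """
    rows = []
    periods = calendar.periods()
    for _, cam in deployments.iterrows():
        dep_lo, dep_hi = cam["start"], cam["end"]
        seen_label_count: dict[str, int] = {}
        acc: dict[str, int] = {}
        for lab, w_lo, w_hi in periods:
            idx = seen_label_count.get(lab, 0)
            seen_label_count[lab] = idx + 1
            lo, hi = max(dep_lo, w_lo), min(dep_hi, w_hi)
            if lo > hi:
                n = 0
            else:
                total = (hi - lo).days + 1
                n = total - len(_excluded_days(cam["exclusions"], lo, hi, cam["camera_id"]))
            key = f"{lab}#{idx}" if by_period else lab
            acc[key] = acc.get(key, 0) + n
        for key, n in acc.items():
            rows.append({"camera_id": cam["camera_id"], "effort": key, "n_active_days": n})
    return pd.DataFrame(rows, columns=["camera_id", "effort", "n_active_days"])


def annotate_effort(events: pd.DataFrame, calendar: EffortCalendar, time_col: str = "event_time") -> pd.DataFrame:
    """Attach the pooled effort stratum (and period index) of each event's date."""
    periods = calendar.periods()
    label_runs: list[tuple[str, Date, Date, int]] = []
    seen: dict[str, int] = {}
    for lab, a, b in periods:
        idx = seen.get(lab, 0)
        seen[lab] = idx + 1
        label_runs.append((lab, a, b, idx))

    def lookup(ts):
        d = ts.date()
        for lab, a, b, idx in label_runs:
            if a <= d <= b:
                return lab, idx
        return None, None

    res = events[time_col].apply(lookup)
    out = events.copy()
    out["effort"] = [r[0] for r in res]
    out["effort_period"] = [r[1] for r in res]
    dropped = out["effort"].isna().sum()
    if dropped:
        logger.warning("%d event(s) outside the effort calendar dropped", dropped)
        out = out[out["effort"].notna()]
    return out.reset_index(drop=True)
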