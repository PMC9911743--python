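"""Daily movement variables from zone-transition logs.

A transition log has one record per zone entry (hen, timestamp, zone).  A
record's zone is held until the next record (half-open intervals); the last
record of a day extends through the night.  For every fully tracked hen-day
we compute, over the lit period: percentage of time in each of the five
zones, stays per hour in each zone, travelled vertical distance (indoor
zones crossed) per hour, and whether the hen entered the winter garden
within 15 min of it opening; plus the sleeping height of the following
night.  A day counts as fully tracked only when a record at or before
lights-on pins down the hen's zone for the whole lit period.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .barn import ZONE_LEVELS, ZONES, BarnCalendar

WG_PROMPT_WINDOW_S = 15 * 60.0

LOG_COLUMNS = ["hen_id", "timestamp", "zone"]

PCT_COLS = [f"pct_time_{z}" for z in ZONES]
STAY_COLS = [f"stays_per_hour_{z}" for z in ZONES]
#: the 13 daily movement variables, in canonical order
VARIABLES = PCT_COLS + STAY_COLS + ["vertical_per_hour", "wg_prompt", "sleeping_height"]


class TransitionLogError(ValueError):
    pass


def vertical_crossings(zone_a: str, zone_b: str) -> int:
    """Number of indoor zones crossed moving between two zones.

    Levels: litter 0, lower tier 1, nest-box tier 2, top tier 3; the winter
    garden is ground-adjacent (level 0), so WG movements cross none.
    """
    try:
        return abs(ZONE_LEVELS[zone_a] - ZONE_LEVELS[zone_b])
    except KeyError as err:
        raise TransitionLogError(f"unknown zone: {err.args[0]!r}") from None


def _dedup_consecutive(df: pd.DataFrame) -> pd.DataFrame:
    """Merge consecutive same-zone records per hen, keeping the first entry."""
    same = (df["zone"] == df.groupby("hen_id")["zone"].shift()).to_numpy()
    return df.loc[~same].reset_index(drop=True)


def validate_transition_log(df: pd.DataFrame) -> pd.DataFrame:
    """Sort, check zone labels and per-hen monotone timestamps, merge
    consecutive duplicate zones.  Raises TransitionLogError on bad input."""
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise TransitionLogError(f"missing columns: {missing}")
    df = df[LOG_COLUMNS].copy()
    bad = ~df["zone"].isin(ZONES)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        labels = sorted(df.loc[bad, "zone"].unique().tolist())
        raise TransitionLogError(
            f"unknown zone label(s) {labels} at file line(s) {lines[:20]}"
        )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    nonmono = df.groupby("hen_id")["timestamp"].diff() <= pd.Timedelta(0)
    if nonmono.any():
        lines = (df.index[nonmono] + 2).tolist()
        raise TransitionLogError(
            f"non-increasing timestamps within hen at file line(s) {lines[:20]}"
        )
    df = df.sort_values(["hen_id", "timestamp"], kind="stable").reset_index(drop=True)
    return _dedup_consecutive(df)


def read_transition_log(path) -> pd.DataFrame:
    """Read a delimited transition log (hen_id, ISO timestamp, zone)."""
    df = pd.read_csv(path)
    return validate_transition_log(df)


def write_transition_log(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f"
    )
    out[LOG_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-hen segment machinery


def _hen_arrays(log: pd.DataFrame, hen) -> tuple[np.ndarray, np.ndarray]:
    sub = log.loc[log["hen_id"] == hen]
    if sub.empty:
        raise KeyError(f"hen {hen!r} not present in log")
    t = sub["timestamp"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    return t, sub["zone"].to_numpy()


def _segments(times: np.ndarray, zones: np.ndarray, t0: float, t1: float):
    """Piecewise-constant zone segments clipped to [t0, t1).

    Returns (zones, starts, ends) or None when no record at or before t0
    (the hen's zone at window start would be unknown → incomplete)."""
    i0 = int(np.searchsorted(times, t0, side="right")) - 1
    if i0 < 0:
        return None
    i1 = int(np.searchsorted(times, t1, side="left"))
    seg_z = zones[i0:i1]
    starts = np.maximum(times[i0:i1], t0)
    ends = np.empty_like(starts)
    ends[:-1] = times[i0 + 1 : i1]
    ends[-1] = t1
    ends = np.minimum(ends, t1)
    keep = ends > starts
    return seg_z[keep], starts[keep], ends[keep]


def _to_epoch(dt) -> float:
    return pd.Timestamp(dt).value / 1e9


def zone_occupancy(
    log: pd.DataFrame, calendar: BarnCalendar, hen, day: int
) -> pd.Series:
    """Seconds spent in each zone during the lit period of ``day``.

    Raises ValueError when the day is not fully tracked for the hen (no
    record at or before lights-on)."""
    sched = calendar[day]
    times, zones = _hen_arrays(log, hen)
    seg = _segments(times, zones, _to_epoch(sched.lights_on), _to_epoch(sched.lights_off))
    if seg is None:
        raise ValueError(f"hen {hen!r} day {day}: no record at or before lights-on")
    seg_z, starts, ends = seg
    out = pd.Series(0.0, index=list(ZONES))
    np.add.at(out.values, [ZONES.index(z) for z in seg_z], ends - starts)
    return out


def sleeping_height(log: pd.DataFrame, calendar: BarnCalendar, hen, day: int) -> float:
    """Vertical level (0–3) of the zone occupied for most of the night
    following ``day``.  NaN when the night is not covered by any record."""
    n0, n1 = calendar.night_window(day)
    times, zones = _hen_arrays(log, hen)
    seg = _segments(times, zones, _to_epoch(n0), _to_epoch(n1))
    if seg is None:
        return float("nan")
    seg_z, starts, ends = seg
    dur = pd.Series(0.0, index=list(ZONES))
    np.add.at(dur.values, [ZONES.index(z) for z in seg_z], ends - starts)
    return float(ZONE_LEVELS[dur.idxmax()])


def _day_row(times, zones, sched, night, hen, day):
    t_on, t_off = _to_epoch(sched.lights_on), _to_epoch(sched.lights_off)
    lit_h = (t_off - t_on) / 3600.0
    seg = _segments(times, zones, t_on, t_off)
    row = {"hen_id": hen, "day": day, "complete": seg is not None,
           "wg_available": bool(sched.wg_available)}
    if seg is None:
        return row
    seg_z, starts, ends = seg
    total = t_off - t_on
    zi = np.array([ZONES.index(z) for z in seg_z])
    occ = np.zeros(len(ZONES))
    np.add.at(occ, zi, ends - starts)
    for k, z in enumerate(ZONES):
        row[f"pct_time_{z}"] = 100.0 * occ[k] / total
    # stays: each maximal same-zone interval intersecting the lit period,
    # including the one already in progress at lights-on
    stays = np.zeros(len(ZONES))
    np.add.at(stays, zi, 1.0)
    for k, z in enumerate(ZONES):
        row[f"stays_per_hour_{z}"] = stays[k] / lit_h
    # vertical distance: indoor zones crossed at transitions inside the lit
    # period (the segment boundaries after the first)
    lv = np.array([ZONE_LEVELS[z] for z in seg_z])
    row["vertical_per_hour"] = float(np.abs(np.diff(lv)).sum()) / lit_h
    # WG prompt entry: a winter-garden entry within 15 min of opening
    wg = 0
    if sched.wg_available and sched.wg_open is not None:
        t_wg = _to_epoch(sched.wg_open)
        # entries are segment starts that coincide with a record timestamp
        rec_mask = np.isin(starts, times)
        enter_wg = (seg_z == "winter_garden") & rec_mask
        wg = int(np.any(enter_wg & (starts >= t_wg) & (starts <= t_wg + WG_PROMPT_WINDOW_S)))
    row["wg_prompt"] = wg
    # sleeping height over the following night
    n0, n1 = night
    nseg = _segments(times, zones, _to_epoch(n0), _to_epoch(n1))
    if nseg is None:
        row["sleeping_height"] = float("nan")
        row["complete"] = False
    else:
        nz, ns, ne = nseg
        ndur = np.zeros(len(ZONES))
        np.add.at(ndur, [ZONES.index(z) for z in nz], ne - ns)
        row["sleeping_height"] = float(ZONE_LEVELS[ZONES[int(np.argmax(ndur))]])
    return row


def daily_variables(log: pd.DataFrame, calendar: BarnCalendar) -> pd.DataFrame:
    """Per hen-day table of the 13 daily movement variables.

    Rows for days that are not fully tracked carry complete=False and NaN
    variables; downstream stages use complete days with wg_available=True.
    """
    rows = []
    for hen in log["hen_id"].unique():
        times, zones = _hen_arrays(log, hen)
        for day in calendar.day_indices:
            sched = calendar[day]
            rows.append(
                _day_row(times, zones, sched, calendar.night_window(day), hen, day)
            )
    df = pd.DataFrame(rows)
    for c in VARIABLES:
        if c not in df.columns:
            df[c] = np.nan
    return df[["hen_id", "day", "complete", "wg_available"] + VARIABLES]


def count_no_transition_days(
    log: pd.DataFrame, calendar: BarnCalendar, window_days: int = 3
) -> pd.Series:
    """Per-hen count of days with zero zone changes, over the first
    ``window_days`` tracked days (lights-on to next lights-on)."""
    first = calendar.day_indices[0]
    window = [d for d in calendar.day_indices if first <= d < first + window_days]
    out = {}
    for hen in log["hen_id"].unique():
        times, zones = _hen_arrays(log, hen)
        n = 0
        covered = False
        for day in window:
            t0 = _to_epoch(calendar[day].lights_on)
            t1 = _to_epoch(calendar.night_window(day)[1])
            if np.searchsorted(times, t0, side="right") == 0:
                continue  # hen not yet tracked that day
            covered = True
            changes = np.sum((times > t0) & (times < t1))
            if changes == 0:
                n += 1
        out[hen] = n if covered else np.nan
    return pd.Series(out, name="no_transition_days").rename_axis("hen_id")
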