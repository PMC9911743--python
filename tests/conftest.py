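"""Shared fixtures: tiny calendars, hand-built transition logs and small
simulated score tables used across the test modules."""

import numpy as np
import pandas as pd
import pytest

from hennorm.barn import BarnCalendar
from hennorm.simulate import SimConfig, make_population, simulate_daily_scores


@pytest.fixture
def calendar3():
    """Three tracked days, winter garden open from day 1."""
    return BarnCalendar.regular(3, wg_closed_days=0)


@pytest.fixture
def calendar1():
    """One tracked day, winter garden open."""
    return BarnCalendar.regular(1, wg_closed_days=0)


def make_log(rows):
    """Build a transition log from (hen, iso-timestamp, zone) triples."""
    df = pd.DataFrame(rows, columns=["hen_id", "timestamp", "zone"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


@pytest.fixture
def make_scores():
    """Factory for small simulated score tables."""

    def _make(n_hens=10, n_days=12, seed=0, **kw):
        cfg = SimConfig(n_hens=n_hens, n_days=n_days, seed=seed, **kw)
        truth = make_population(cfg)
        return truth, simulate_daily_scores(truth, cfg), cfg

    return _make


def random_walk_log(rng, calendar, hen="hen_x", step_s=None):
    """A random adjacency-respecting one-day log on an integer-second grid,
    for comparison against the brute-force one-second oracle."""
    from hennorm.barn import ZONE_ADJACENCY, ZONES

    day = calendar.day_indices[0]
    sched = calendar[day]
    t_on = pd.Timestamp(sched.lights_on)
    night_end = pd.Timestamp(calendar.night_window(day)[1])
    total = int((night_end - t_on).total_seconds())
    zone = ZONES[rng.integers(len(ZONES) - 1)]  # start indoors
    t = 0
    rows = [(hen, t_on, zone)]
    while True:
        t += int(rng.integers(300, 7200))
        if t >= total:
            break
        opts = [
            z for z in ZONE_ADJACENCY[zone]
            if z != "winter_garden"
            or (sched.wg_available and sched.wg_open is not None
                and t_on + pd.Timedelta(seconds=t) >= pd.Timestamp(sched.wg_open))
        ]
        zone = opts[rng.integers(len(opts))]
        rows.append((hen, t_on + pd.Timedelta(seconds=t), zone))
    return make_log(rows)


def brute_force_day(log, calendar, hen, day):
    """One-second discretisation of a hen-day: an independent re-computation
    of every daily movement variable, used as the oracle."""
    from hennorm.barn import ZONE_LEVELS, ZONES
    from hennorm.features import WG_PROMPT_WINDOW_S

    sched = calendar[day]
    sub = log[log["hen_id"] == hen].sort_values("timestamp")
    times = sub["timestamp"].astype("int64").to_numpy() / 1e9
    zones = sub["zone"].to_numpy()

    def zone_at(t):
        i = np.searchsorted(times, t, side="right") - 1
        return zones[i] if i >= 0 else None

    t_on = pd.Timestamp(sched.lights_on).value / 1e9
    t_off = pd.Timestamp(sched.lights_off).value / 1e9
    secs = np.arange(t_on, t_off)
    seq = [zone_at(s) for s in secs]
    if seq[0] is None:
        return None
    total = len(seq)
    row = {}
    for z in ZONES:
        row[f"pct_time_{z}"] = 100.0 * sum(s == z for s in seq) / total
    lit_h = total / 3600.0
    # stays: runs of consecutive identical zones
    runs = {z: 0 for z in ZONES}
    prev = None
    for s in seq:
        if s != prev:
            runs[s] += 1
        prev = s
    for z in ZONES:
        row[f"stays_per_hour_{z}"] = runs[z] / lit_h
    vert = sum(
        abs(ZONE_LEVELS[b] - ZONE_LEVELS[a]) for a, b in zip(seq[:-1], seq[1:])
    )
    row["vertical_per_hour"] = vert / lit_h
    wg = 0
    if sched.wg_available and sched.wg_open is not None:
        t_wg = pd.Timestamp(sched.wg_open).value / 1e9
        for a, b, s in zip(seq[:-1], seq[1:], secs[1:]):
            if b == "winter_garden" and a != b and t_wg <= s <= t_wg + WG_PROMPT_WINDOW_S:
                wg = 1
    row["wg_prompt"] = wg
    n0, n1 = calendar.night_window(day)
    nsecs = np.arange(pd.Timestamp(n0).value / 1e9, pd.Timestamp(n1).value / 1e9)
    nseq = [zone_at(s) for s in nsecs]
    counts = {z: sum(s == z for s in nseq) for z in ZONES}
    row["sleeping_height"] = float(ZONE_LEVELS[max(counts, key=counts.get)])
    return row
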