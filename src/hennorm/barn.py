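"""Barn layout and schedule: tracked zones, their vertical levels, and the
per-day light / winter-garden calendar.

The aviary has three stacked tiers (lower, nest-box, top) above a littered
floor, plus an outdoor covered winter garden (WG) reached through pop holes
at litter level.  Vertical position is coded as the number of stacked tiers
underneath a zone: litter 0, lower tier 1, nest-box tier 2, top tier 3.
The WG is ground-adjacent and coded 0; movements into or out of it cross no
indoor zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta

import pandas as pd
import yaml

ZONES = ("litter", "lower_tier", "nestbox_tier", "top_tier", "winter_garden")

ZONE_LEVELS = {
    "litter": 0,
    "lower_tier": 1,
    "nestbox_tier": 2,
    "top_tier": 3,
    "winter_garden": 0,
}

#: physically adjacent zone pairs (tier ladder plus the WG pop holes)
ZONE_ADJACENCY = {
    "litter": ("lower_tier", "winter_garden"),
    "lower_tier": ("litter", "nestbox_tier"),
    "nestbox_tier": ("lower_tier", "top_tier"),
    "top_tier": ("nestbox_tier",),
    "winter_garden": ("litter",),
}


@dataclass(frozen=True)
class DaySchedule:
    """Light and winter-garden schedule for one day post-transfer."""

    lights_on: datetime
    lights_off: datetime
    wg_open: datetime | None = None
    wg_available: bool = False

    def __post_init__(self):
        if self.lights_on >= self.lights_off:
            raise ValueError("lights_on must precede lights_off")
        if self.wg_open is not None and not (
            self.lights_on <= self.wg_open <= self.lights_off
        ):
            raise ValueError("wg_open must fall within the lit period")

    @property
    def lit_seconds(self) -> float:
        return (self.lights_off - self.lights_on).total_seconds()


@dataclass
class BarnCalendar:
    """Per-day schedules, keyed by integer day post-transfer (day 0 = the
    transfer day itself, excluded from analysis; tracked days start at 1)."""

    days: dict[int, DaySchedule] = field(default_factory=dict)

    def __contains__(self, day: int) -> bool:
        return day in self.days

    def __getitem__(self, day: int) -> DaySchedule:
        return self.days[day]

    @property
    def day_indices(self) -> list[int]:
        return sorted(self.days)

    def night_window(self, day: int) -> tuple[datetime, datetime]:
        """The night following ``day``: lights-off until the next lights-on.

        If the following day is outside the calendar the night is closed at
        the same clock time as the current day's lights-on, one day later.
        """
        sched = self.days[day]
        nxt = self.days.get(day + 1)
        if nxt is not None:
            return sched.lights_off, nxt.lights_on
        return sched.lights_off, sched.lights_on + timedelta(days=1)

    @classmethod
    def regular(
        cls,
        n_days: int,
        start: datetime | str = "2020-01-01",
        lights_on: str = "05:00",
        lights_off: str = "22:00",
        wg_open: str = "10:00",
        wg_closed_days: int = 8,
        first_day: int = 1,
    ) -> "BarnCalendar":
        """A calendar with identical daily schedules; the winter garden is
        closed for the first ``wg_closed_days`` days after transfer."""
        if isinstance(start, str):
            start = datetime.fromisoformat(start)
        t_on = time.fromisoformat(lights_on)
        t_off = time.fromisoformat(lights_off)
        t_wg = time.fromisoformat(wg_open)
        days = {}
        for d in range(first_day, first_day + n_days):
            date = start + timedelta(days=d)
            avail = d > wg_closed_days
            days[d] = DaySchedule(
                lights_on=datetime.combine(date.date(), t_on),
                lights_off=datetime.combine(date.date(), t_off),
                wg_open=datetime.combine(date.date(), t_wg) if avail else None,
                wg_available=avail,
            )
        return cls(days)

    # -- plain-text round trip -------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            int(d): {
                "lights_on": s.lights_on.isoformat(),
                "lights_off": s.lights_off.isoformat(),
                "wg_open": s.wg_open.isoformat() if s.wg_open else None,
                "wg_available": bool(s.wg_available),
            }
            for d, s in self.days.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "BarnCalendar":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        days = {
            int(d): DaySchedule(
                lights_on=datetime.fromisoformat(v["lights_on"]),
                lights_off=datetime.fromisoformat(v["lights_off"]),
                wg_open=(
                    datetime.fromisoformat(v["wg_open"]) if v["wg_open"] else None
                ),
                wg_available=bool(v["wg_available"]),
            )
            for d, v in payload.items()
        }
        return cls(days)

    def day_of(self, ts: pd.Timestamp) -> int | None:
        """Map a timestamp to the day index whose [lights_on, next lights_on)
        window contains it, or None."""
        for d, s in self.days.items():
            if s.lights_on <= ts < self.night_window(d)[1]:
                return d
        return None
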