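"""Tiered geolocation of detection events.

A mobile transceiver records *that* an encounter happened, not *where*.
Positions come from independent fixes (moored receiver arrays, satellite
pop-ups) and are attached to each detection event by a strict three-tier
rule: a fix of the focal on the event day (primary), else the focal's
nearest fix within the window (secondary), else the detected animal's
nearest fix within the window (tertiary); otherwise the event stays
unlocated but is retained.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["assign_locations", "TIERS"]

TIERS = ("primary", "secondary", "tertiary", "unlocated")

DEFAULT_WINDOW_DAYS = 7


def _fix_lookup(fixes: pd.DataFrame) -> dict:
    """(animal_id, date) -> (lat, lon, source); first fix of the day wins."""
    lookup: dict = {}
    for row in fixes.sort_values(["animal_id", "date"]).itertuples(index=False):
        key = (row.animal_id, pd.Timestamp(row.date).normalize())
        lookup.setdefault(key, (row.lat, row.lon, row.source))
    return lookup


def _nearest_offset(lookup, animal, day, lo, hi):
    """Nearest fix for ``animal`` with |offset| in [lo, hi]; ties toward the
    earlier date (negative offset first)."""
    one_day = pd.Timedelta(days=1)
    for o in range(lo, hi + 1):
        for signed in ((-o, o) if o else (0,)):
            fix = lookup.get((animal, day + signed * one_day))
            if fix is not None:
                return signed, fix
    return None


def assign_locations(
    events: pd.DataFrame,
    fixes: pd.DataFrame,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> pd.DataFrame:
    """Attach a position and tier label to every detection event.

    ``events`` needs columns focal_id, time and animal_id (the detected
    individual).  Tier priority is strict: primary (focal fix, offset 0) >
    secondary (focal fix, 1 <= |offset| <= window) > tertiary (detected
    animal's fix, |offset| <= window).  Within a tier the fix minimising
    |day offset| wins, ties broken toward the earlier date.  Every input
    event appears exactly once in the output, unlocated ones included.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    lookup = _fix_lookup(fixes) if len(fixes) else {}
    times = events["time"]
    days = times.dt.tz_localize(None).dt.normalize() if times.dt.tz is not None \
        else times.dt.normalize()

    # resolve each unique (animal, day) key once, then map back to events
    def resolve_focal(key):
        focal, day = key
        hit = _nearest_offset(lookup, focal, day, 0, 0)
        if hit is not None:
            return ("primary",) + hit
        if window_days >= 1:
            hit = _nearest_offset(lookup, focal, day, 1, window_days)
            if hit is not None:
                return ("secondary",) + hit
        return None

    def resolve_target(key):
        animal, day = key
        hit = _nearest_offset(lookup, animal, day, 0, window_days)
        if hit is not None:
            return ("tertiary",) + hit
        return None

    focal_cache = {k: resolve_focal(k) for k in set(zip(events["focal_id"], days))}
    target_cache = {k: resolve_target(k) for k in set(zip(events["animal_id"], days))}

    rows = []
    for (idx, focal, t, animal), day in zip(
        events[["focal_id", "time", "animal_id"]].itertuples(index=True), days
    ):
        hit = focal_cache[(focal, day)] or target_cache[(animal, day)]
        tier, offset, fix = hit if hit is not None else ("unlocated", None, None)
        rows.append(
            {
                "event_id": idx,
                "focal_id": focal,
                "time": t,
                "animal_id": animal,
                "tier": tier,
                "day_offset": offset,
                "lat": fix[0] if fix else None,
                "lon": fix[1] if fix else None,
                "source": fix[2] if fix else None,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "event_id", "focal_id", "time", "animal_id",
            "tier", "day_offset", "lat", "lon", "source",
        ],
    )
    return out
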