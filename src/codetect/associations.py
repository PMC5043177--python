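"""Dyadic association durations and focal-focal co-encounters.

Association between a focal transceiver and another tagged individual is
measured on hour bins: *cumulative hours* is the number of distinct hours
with detection contact over the whole record, and *consecutive-hour events*
are maximal runs of adjacent hour bins, retained when at least
``min_event_hours`` long (default 2).  Long runs are the evidence that some
pairings are not chance re-encounters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encounters import HourlyPresence

__all__ = [
    "cumulative_hours",
    "consecutive_events",
    "summarize_dyads",
    "top_fraction",
    "co_encounters",
    "CoEncounterSeries",
]

DEFAULT_MIN_EVENT_HOURS = 2


def cumulative_hours(presence: HourlyPresence) -> pd.DataFrame:
    """Distinct detection-hours per dyad.

    Dyads never detected are simply absent (no zero rows).
    """
    t = presence.table
    if t.empty:
        return pd.DataFrame(columns=["focal_id", "animal_id", "cumulative_hours"])
    out = (
        t.groupby(["focal_id", "animal_id"], observed=True)
        .size()
        .rename("cumulative_hours")
        .reset_index()
    )
    return out


def _runs(hours: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers in a sorted unique array,
    as (start, length)."""
    if hours.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(hours) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [hours.size - 1]))
    return [(int(hours[s]), int(e - s + 1)) for s, e in zip(starts, ends)]


def consecutive_events(
    presence: HourlyPresence, min_event_hours: int = DEFAULT_MIN_EVENT_HOURS
) -> pd.DataFrame:
    """Maximal consecutive-hour runs per dyad, length >= ``min_event_hours``.

    A run is a sequence of hour bins each exactly one hour after the
    previous.  Shorter runs are discarded from the event list but still
    contribute to cumulative hours.
    """
    if min_event_hours < 1:
        raise ValueError("min_event_hours must be >= 1")
    t = presence.table
    rows = []
    if not t.empty:
        hour_int = t["hour"].astype("int64") // 3_600_000_000_000
        for (focal, animal), grp in hour_int.groupby(
            [t["focal_id"], t["animal_id"]], observed=True
        ):
            for start, length in _runs(grp.to_numpy()):
                if length >= min_event_hours:
                    rows.append(
                        {
                            "focal_id": focal,
                            "animal_id": animal,
                            "start": pd.Timestamp(start * 3600, unit="s", tz="UTC"),
                            "length": length,
                        }
                    )
    return pd.DataFrame(rows, columns=["focal_id", "animal_id", "start", "length"])


def summarize_dyads(
    presence: HourlyPresence, min_event_hours: int = DEFAULT_MIN_EVENT_HOURS
) -> pd.DataFrame:
    """Per-dyad association summary.

    Columns: cumulative_hours (all bins), n_events / max_event /
    mean_event over retained (>= min_event_hours) runs, plus the target's
    sex and fork length.
    """
    cum = cumulative_hours(presence)
    events = consecutive_events(presence, min_event_hours)
    if events.empty:
        ev = pd.DataFrame(columns=["focal_id", "animal_id", "n_events", "max_event", "mean_event"])
    else:
        ev = (
            events.groupby(["focal_id", "animal_id"], observed=True)["length"]
            .agg(n_events="size", max_event="max", mean_event="mean")
            .reset_index()
        )
    out = cum.merge(ev, on=["focal_id", "animal_id"], how="left")
    out["n_events"] = out["n_events"].fillna(0).astype(int)
    out["max_event"] = out["max_event"].fillna(0).astype(int)
    meta = presence.dyads()
    return out.merge(meta, on=["focal_id", "animal_id"], how="left")


def top_fraction(table: pd.DataFrame, metric: str, fraction: float) -> pd.DataFrame:
    """Select the top ``ceil(fraction * N)`` rows by an association metric.

    ``metric="cumulative"`` ranks dyad summaries by cumulative hours;
    ``metric="max_event"`` ranks individual events by run length.  Ties at
    the cut value are all included, so slightly more than the nominal
    fraction can be returned.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    column = {"cumulative": "cumulative_hours", "max_event": "length"}.get(metric)
    if column is None:
        raise ValueError(f"unknown metric {metric!r}")
    if table.empty:
        return table.copy()
    n_top = math.ceil(fraction * len(table))
    values = table[column].to_numpy()
    cutoff = np.sort(values)[::-1][n_top - 1]
    return (
        table[table[column] >= cutoff]
        .sort_values(column, ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


@dataclass
class CoEncounterSeries:
    """Monthly focal-focal co-encounters and shared-individual proportion.

    ``monthly`` has one row per month: co-encounter hour counts per
    direction and combined, the two focals' unique-individual counts, and
    ``prop_shared = |A & B| / |A | B|`` over their monthly unique sets.
    """

    monthly: pd.DataFrame
    focal_ids: tuple[str, str]


def co_encounters(
    clean, focal_ids: tuple[str, str], species: str | None = None
) -> CoEncounterSeries:
    """Monthly mutual detections between the two focals, plus set overlap.

    Mutual detections are counted as distinct (detector, hour) pairs so a
    burst of pings within an hour counts once per direction.  The
    shared-individual proportion uses the union of the two focals' monthly
    unique sets as denominator, optionally restricted to one species
    (conspecifics).
    """
    fa, fb = focal_ids
    d = clean.detections
    known_focals = set(d["focal_id"].unique()) | set(
        d.loc[d["is_focal"].astype(bool), "animal_id"].unique()
    )
    for f in (fa, fb):
        if f not in known_focals:
            raise KeyError(f"unknown focal id {f!r}")

    d = d.assign(
        month=d["time"].dt.tz_localize(None).dt.to_period("M"),
        hour=d["time"].dt.floor("h"),
    )

    # focal-focal stream: detections whose target is the other focal
    ff = d[d["is_focal"].astype(bool)]
    ff = ff[ff["focal_id"].isin([fa, fb]) & ff["animal_id"].isin([fa, fb])]
    ff = ff.drop_duplicates(subset=["focal_id", "hour"])
    per_dir = (
        ff.groupby(["month", "focal_id"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[fa, fb], fill_value=0)
    )

    # monthly unique non-focal individual sets per focal
    others = d[~d["is_focal"].astype(bool)]
    if species is not None:
        others = others[others["species"] == species]
    months = sorted(set(d["month"]))
    rows = []
    for month in months:
        sub = others[others["month"] == month]
        set_a = set(sub.loc[sub["focal_id"] == fa, "animal_id"])
        set_b = set(sub.loc[sub["focal_id"] == fb, "animal_id"])
        union = set_a | set_b
        prop = len(set_a & set_b) / len(union) if union else np.nan
        ca = int(per_dir.loc[month, fa]) if month in per_dir.index else 0
        cb = int(per_dir.loc[month, fb]) if month in per_dir.index else 0
        rows.append(
            {
                "month": month,
                f"count_{fa}": ca,
                f"count_{fb}": cb,
                "count_total": ca + cb,
                f"n_unique_{fa}": len(set_a),
                f"n_unique_{fb}": len(set_b),
                "prop_shared": prop,
            }
        )
    return CoEncounterSeries(monthly=pd.DataFrame(rows), focal_ids=(fa, fb))
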