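"""Hourly presence and monthly community summaries.

These are the shared substrate for the association and community statistics:
detections collapse to hour bins per (focal, individual) dyad, and to
per-month communities (unique individuals, detection-days, normalised
per-species counts).  Detections of the other transceiver-carrying focal are
routed to a separate co-encounter stream and never counted among "other
individuals" here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["HourlyPresence", "bin_hours", "MonthlyCommunity", "monthly_communities"]


@dataclass
class HourlyPresence:
    """Hour bins with >=1 detection, per (focal, non-focal individual) dyad.

    ``table`` has one row per (focal_id, animal_id, hour) with the hour
    floored to UTC; rows are sorted and unique.  Target metadata (species,
    sex, fork length) rides along for downstream summaries.
    """

    table: pd.DataFrame

    def hours(self, focal_id: str, animal_id: str) -> np.ndarray:
        """Sorted hour bins for one dyad, as integer hours since epoch."""
        t = self.table
        sel = t[(t["focal_id"] == focal_id) & (t["animal_id"] == animal_id)]
        return sel["hour"].astype("int64").to_numpy() // 3_600_000_000_000

    def dyads(self) -> pd.DataFrame:
        """One row per dyad with its metadata."""
        cols = ["focal_id", "animal_id", "species", "sex", "fork_length_cm"]
        return self.table[cols].drop_duplicates().reset_index(drop=True)


def bin_hours(clean) -> HourlyPresence:
    """Collapse clean detections to unique hourly presence bins per dyad.

    The bin is the timestamp truncated to the hour (UTC); several detections
    within one hour collapse to a single bin.  Focal-target rows (the other
    transceiver) are excluded — they feed the co-encounter stream instead.
    """
    d = clean.detections
    d = d[~d["is_focal"].astype(bool)]
    if d.empty:
        table = pd.DataFrame(
            columns=["focal_id", "animal_id", "hour", "species", "sex", "fork_length_cm"]
        )
        return HourlyPresence(table)
    hours = d["time"].dt.floor("h")
    table = (
        d.assign(hour=hours)[
            ["focal_id", "animal_id", "hour", "species", "sex", "fork_length_cm"]
        ]
        .drop_duplicates(subset=["focal_id", "animal_id", "hour"])
        .sort_values(["focal_id", "animal_id", "hour"])
        .reset_index(drop=True)
    )
    return HourlyPresence(table)


@dataclass
class MonthlyCommunity:
    """Per-(focal, calendar month) community summaries.

    ``individuals``: one row per (focal_id, month, animal_id) with the
    individual's detection-days (distinct UTC calendar days with >=1
    detection that month) and metadata.

    ``species``: one row per (focal_id, month, species) with the count of
    unique individuals, the active-tag denominator and the normalised count.
    """

    individuals: pd.DataFrame
    species: pd.DataFrame

    def unique_sets(
        self, focal_id: str, species: str | None = None
    ) -> dict[pd.Period, frozenset]:
        """Month -> set of unique animal_ids encountered by one focal."""
        d = self.individuals[self.individuals["focal_id"] == focal_id]
        if species is not None:
            d = d[d["species"] == species]
        return {
            month: frozenset(grp["animal_id"])
            for month, grp in d.groupby("month", observed=True)
        }

    def detection_day_vectors(
        self, focal_id: str, species: str
    ) -> dict[pd.Period, pd.Series]:
        """Month -> detection-days per individual (Shannon abundance unit)."""
        d = self.individuals
        d = d[(d["focal_id"] == focal_id) & (d["species"] == species)]
        return {
            month: grp.set_index("animal_id")["detection_days"].astype(float)
            for month, grp in d.groupby("month", observed=True)
        }

    def species_vectors(self, focal_id: str) -> dict[pd.Period, pd.Series]:
        """Month -> normalised unique-individual count per species."""
        d = self.species[self.species["focal_id"] == focal_id]
        return {
            month: grp.set_index("species")["normalized"].astype(float)
            for month, grp in d.groupby("month", observed=True)
        }


def monthly_communities(
    clean, active_counts: Mapping[str, int] | pd.Series
) -> MonthlyCommunity:
    """Summarise clean detections into per-month communities per focal.

    Months are UTC calendar months of the detection time; an individual
    detected either side of a month boundary counts in both months.
    ``active_counts`` (species -> active tags) normalises the per-species
    unique-individual counts; a detected species missing from it is an
    error, since the normalisation would silently be wrong.
    """
    active = pd.Series(active_counts, dtype=float)
    d = clean.detections
    d = d[~d["is_focal"].astype(bool)]
    if d.empty:
        empty_ind = pd.DataFrame(
            columns=[
                "focal_id", "month", "animal_id", "species", "sex",
                "fork_length_cm", "detection_days",
            ]
        )
        empty_sp = pd.DataFrame(
            columns=["focal_id", "month", "species", "n_unique", "n_active", "normalized"]
        )
        return MonthlyCommunity(empty_ind, empty_sp)

    detected_species = set(d["species"].unique())
    missing = sorted(detected_species - set(active.index))
    if missing:
        raise KeyError(f"no active-tag count for detected species: {missing}")

    d = d.assign(
        month=d["time"].dt.tz_localize(None).dt.to_period("M"),
        day=d["time"].dt.floor("D"),
    )
    individuals = (
        d.groupby(["focal_id", "month", "animal_id"], observed=True)
        .agg(
            species=("species", "first"),
            sex=("sex", "first"),
            fork_length_cm=("fork_length_cm", "first"),
            detection_days=("day", "nunique"),
        )
        .reset_index()
    )
    species = (
        individuals.groupby(["focal_id", "month", "species"], observed=True)
        .agg(n_unique=("animal_id", "nunique"))
        .reset_index()
    )
    species["n_active"] = species["species"].map(active)
    species["normalized"] = species["n_unique"] / species["n_active"]
    return MonthlyCommunity(individuals, species)
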