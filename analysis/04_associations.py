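#!/usr/bin/env python
"""Dyadic association durations and focal-focal co-encounters.

Cumulative hours per dyad, consecutive-hour events (>= 2 h), the top 10%
of individuals by cumulative hours and top 1% of events by length, and
the monthly shared-individual proportion between the two focals.  Writes
tables under results/04_associations/.
"""

import sys
from pathlib import Path

import pandas as pd

from codetect import associations, encounters, ingest

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "04_associations"
    out.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(
        ROOT / "results" / "03_encounters" / "presence.csv", parse_dates=["hour"]
    )
    presence = encounters.HourlyPresence(table)
    clean_det = pd.read_csv(
        ROOT / "results" / "02_clean" / "clean_detections.csv", parse_dates=["time"]
    )
    clean = ingest.CleanDetectionSet(detections=clean_det, ledger=pd.DataFrame(
        {"rule": [], "n_detections": [], "n_codes": []}))

    dyads = associations.summarize_dyads(presence)
    events = associations.consecutive_events(presence)
    top_dyads = associations.top_fraction(dyads, "cumulative", 0.10)
    top_events = associations.top_fraction(events, "max_event", 0.01)
    registry_focals = sorted(clean_det.loc[clean_det["is_focal"], "animal_id"].unique())
    coenc = associations.co_encounters(clean, tuple(registry_focals)[:2])

    dyads.to_csv(out / "dyads.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    top_dyads.to_csv(out / "top10pct_dyads.csv", index=False)
    top_events.to_csv(out / "top1pct_events.csv", index=False)
    coenc.monthly.to_csv(out / "coencounters.csv", index=False)

    print(f"{len(dyads)} dyads; cumulative hours mean "
          f"{dyads['cumulative_hours'].mean():.1f} "
          f"(range {dyads['cumulative_hours'].min()}-{dyads['cumulative_hours'].max()})")
    print(f"{len(events)} consecutive-hour events >= 2 h; longest "
          f"{events['length'].max()} h")
    print(f"top 10% dyads: {len(top_dyads)} "
          f"(>= {top_dyads['cumulative_hours'].min()} cumulative h)")
    print(f"top 1% events: {len(top_events)} (>= {top_events['length'].min()} h)")
    peak = coenc.monthly.loc[coenc.monthly["count_total"].idxmax()]
    print(f"peak co-encounters in {peak['month']}: {peak['count_total']} "
          f"focal-focal detection hours")


if __name__ == "__main__":
    sys.exit(main())
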