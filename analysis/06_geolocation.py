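#!/usr/bin/env python
"""Attach tiered positions to every detection event.

Primary = focal's same-day fix; secondary = focal's nearest fix within
±7 days; tertiary = detected animal's nearest fix within ±7 days; the
rest stay unlocated.  Writes results/06_geolocation/located_events.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from codetect import geolocate, ingest

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results" / "06_geolocation"
    out.mkdir(parents=True, exist_ok=True)

    clean_det = pd.read_csv(
        ROOT / "results" / "02_clean" / "clean_detections.csv", parse_dates=["time"]
    )
    fixes = ingest.load_fixes(ROOT / "results" / "01_fixture" / "fixes.csv")
    located = geolocate.assign_locations(clean_det, fixes, window_days=7)
    located.to_csv(out / "located_events.csv", index=False)

    counts = located["tier"].value_counts()
    total = len(located)
    print(f"located {total - counts.get('unlocated', 0)} of {total} events:")
    for tier in geolocate.TIERS:
        n = int(counts.get(tier, 0))
        print(f"  {tier}: {n} ({100 * n / total:.1f}%)")


if __name__ == "__main__":
    sys.exit(main())
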