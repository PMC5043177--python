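#!/usr/bin/env python
"""Bin clean detections into hourly presence and monthly communities.

Also reports each focal's coverage of the active tagged conspecific
population — the fraction of potentially detectable conspecifics it
actually heard.  Writes tables under results/03_encounters/.
"""

import sys
from pathlib import Path

import pandas as pd

from codetect import community, encounters, ingest

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    fixture = ROOT / "results" / "01_fixture"
    out = ROOT / "results" / "03_encounters"
    out.mkdir(parents=True, exist_ok=True)

    clean_det = pd.read_csv(
        ROOT / "results" / "02_clean" / "clean_detections.csv", parse_dates=["time"]
    )
    registry = ingest.load_registry(fixture / "registry.csv")
    clean = ingest.CleanDetectionSet(
        detections=clean_det,
        ledger=pd.read_csv(ROOT / "results" / "02_clean" / "exclusion_ledger.csv"),
    )
    span = (clean_det["time"].min().tz_localize(None),
            clean_det["time"].max().tz_localize(None))
    # denominator: non-focal tags (a transceiver cannot detect itself)
    active = ingest.active_tag_counts(registry[~registry["is_focal"]], span)

    presence = encounters.bin_hours(clean)
    monthly = encounters.monthly_communities(clean, active)
    presence.table.to_csv(out / "presence.csv", index=False)
    monthly.individuals.to_csv(out / "monthly_individuals.csv", index=False)
    monthly.species.to_csv(out / "monthly_species.csv", index=False)

    focal_species = registry.loc[registry["is_focal"], "species"].iloc[0]
    consp = monthly.individuals[monthly.individuals["species"] == focal_species]
    print(f"{len(presence.table)} dyad-hours of presence across "
          f"{presence.dyads().shape[0]} dyads")
    for focal, grp in consp.groupby("focal_id"):
        n = grp["animal_id"].nunique()
        cov = community.coverage_percent(n, int(active[focal_species]))
        print(f"  {focal}: {n} unique conspecifics of {active[focal_species]} "
              f"active -> {cov}% coverage")


if __name__ == "__main__":
    sys.exit(main())
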