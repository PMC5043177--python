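#!/usr/bin/env python
"""Match detections against the tag registry and apply the exclusion rules.

Unknown codes, declined-permission owners and suspected-dead tags are
removed in that order; the ledger accounts for every dropped row.  Writes
the clean detections and ledger under results/02_clean/.
"""

import sys
from pathlib import Path

from codetect import ingest

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    fixture = ROOT / "results" / "01_fixture"
    out = ROOT / "results" / "02_clean"
    out.mkdir(parents=True, exist_ok=True)

    load = ingest.load_detections(fixture / "detections.csv")
    registry = ingest.load_registry(fixture / "registry.csv")
    clean = ingest.apply_exclusions(load.records, registry)

    clean.detections.to_csv(out / "clean_detections.csv", index=False)
    clean.ledger.to_csv(out / "exclusion_ledger.csv", index=False)

    print(f"parsed {len(load.records)} detections ({len(load.rejects)} malformed rows)")
    for row in clean.ledger.itertuples(index=False):
        print(f"  rule {row.rule!r}: removed {row.n_detections} detections "
              f"from {row.n_codes} tag codes")
    print(f"retained {len(clean.detections)} detections "
          f"({clean.detections['tag_code'].nunique()} tags, "
          f"{clean.detections['species'].nunique()} species)")


if __name__ == "__main__":
    sys.exit(main())
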