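"""Published regional telemetry-network summary used as pipeline input.

The coastal cooperative telemetry network publishes, per species, the number
of unique transmitters detected by each of the two focal transceivers (ST1,
ST2) over their ~11 months at liberty, together with the number of tags
potentially active in the region during the study.  These printed counts are
inputs to the coverage statistic and to the synthetic population's default
scale; they are not recomputed here.
"""

from __future__ import annotations

import pandas as pd

#: Per-species unique individuals detected by each focal transceiver and the
#: number of potentially active tags in the regional network over the study
#: span (24 Aug 2012 - 27 Jul 2013).
DETECTION_SUMMARY = pd.DataFrame(
    [
        ("Atlantic Sturgeon", "Acipenser oxyrhynchus oxyrhynchus", 120, 57, 1142),
        ("Bull Shark", "Carcharhinus leucas", 1, 0, 31),
        ("Lemon Shark", "Negaprion brevirostris", 2, 0, 173),
        ("Sand Tiger", "Carcharias taurus", 170, 200, 325),
        ("Sandbar Shark", "Carcharhinus plumbeus", 2, 0, 23),
        ("Spiny Dogfish", "Squalus acanthias", 1, 2, 132),
        ("Striped Bass", "Morone saxatilis", 0, 1, 513),
        ("White Shark", "Carcharodon carcharias", 2, 2, 29),
    ],
    columns=["common_name", "species", "detected_st1", "detected_st2", "active_tags"],
)

#: Focal species (the transceiver carriers are mature male sand tigers).
FOCAL_SPECIES = "Carcharias taurus"

#: Study span of the recovered transceiver archives (UTC dates).
STUDY_START = pd.Timestamp("2012-08-24")
STUDY_END = pd.Timestamp("2013-07-27")


def focal_species_row() -> pd.Series:
    """The summary row for the focal (conspecific) species."""
    return DETECTION_SUMMARY.set_index("species").loc[FOCAL_SPECIES]
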