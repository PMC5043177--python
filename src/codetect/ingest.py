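"""Reading detection logs and the tag registry, and the exclusion rules.

A transceiver archive row is (focal transceiver id, UTC timestamp, detected
tag code).  The registry maps tag codes to animals: species, sex, fork
length, the tag's active interval, whether the owner granted permission to
use the detections, and a status flag for tags suspected shed/dead.  Three
exclusion rules are applied in a fixed order — unknown code, permission
declined, suspected dead — and every removal is accounted for in a ledger
so that retained + excluded always reconciles with the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import FormatError

__all__ = [
    "DETECTION_COLUMNS",
    "REGISTRY_COLUMNS",
    "FIX_COLUMNS",
    "LoadResult",
    "load_detections",
    "load_registry",
    "load_fixes",
    "CleanDetectionSet",
    "apply_exclusions",
    "active_tag_counts",
]

TIMESTAMP_COL = "timestamp_iso8601_utc"
DETECTION_COLUMNS = ["focal_id", TIMESTAMP_COL, "tag_code"]
REGISTRY_COLUMNS = [
    "tag_code", "animal_id", "species", "sex", "fork_length_cm",
    "active_from", "active_to", "permission", "status", "is_focal",
]
FIX_COLUMNS = ["animal_id", "date", "lat", "lon", "source"]

EXCLUSION_RULES = ("unknown", "permission", "dead")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")


@dataclass
class LoadResult:
    """Parsed detection records plus the malformed rows that were rejected."""

    records: pd.DataFrame
    rejects: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)


def load_detections(path) -> LoadResult:
    """Parse a detection log CSV into (records, rejects).

    Rows whose timestamp does not parse or whose focal_id / tag_code is
    empty are collected in ``rejects`` with a reason, never silently
    dropped.  Record order follows file order.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, DETECTION_COLUMNS, path)
    time = pd.to_datetime(raw[TIMESTAMP_COL], errors="coerce", utc=True, format="ISO8601")
    bad_time = time.isna()
    bad_focal = raw["focal_id"].str.strip() == ""
    bad_code = raw["tag_code"].str.strip() == ""
    bad = bad_time | bad_focal | bad_code
    reason = pd.Series("", index=raw.index)
    reason[bad_code] = "empty tag_code"
    reason[bad_focal] = "empty focal_id"
    reason[bad_time] = "unparseable timestamp"
    rejects = raw[bad].assign(reason=reason[bad]).reset_index(names="row")
    records = pd.DataFrame(
        {
            "focal_id": raw.loc[~bad, "focal_id"],
            "time": time[~bad],
            "tag_code": raw.loc[~bad, "tag_code"],
        }
    ).reset_index(drop=True)
    return LoadResult(records=records, rejects=rejects)


def load_registry(path) -> pd.DataFrame:
    """Parse the tag registry CSV, validating uniqueness and intervals."""
    reg = pd.read_csv(path, dtype={"tag_code": str, "animal_id": str})
    _require_columns(reg, REGISTRY_COLUMNS, path)
    if reg["tag_code"].duplicated().any():
        dupes = sorted(reg.loc[reg["tag_code"].duplicated(), "tag_code"].unique())
        raise FormatError(f"{path}: duplicate tag_code(s) {dupes[:5]}")
    reg = reg.assign(
        active_from=pd.to_datetime(reg["active_from"]),
        active_to=pd.to_datetime(reg["active_to"]),
        permission=reg["permission"].astype(bool),
        is_focal=reg["is_focal"].astype(bool),
    )
    if (reg["active_from"] >= reg["active_to"]).any():
        raise FormatError(f"{path}: active_from must precede active_to")
    return reg


def load_fixes(path) -> pd.DataFrame:
    """Parse position fixes (animal_id, UTC date, lat, lon, source)."""
    fixes = pd.read_csv(path, dtype={"animal_id": str})
    _require_columns(fixes, FIX_COLUMNS, path)
    fixes = fixes.assign(date=pd.to_datetime(fixes["date"]))
    if ((fixes["lat"].abs() > 90) | (fixes["lon"].abs() > 180)).any():
        raise FormatError(f"{path}: lat/lon out of range")
    return fixes


@dataclass
class CleanDetectionSet:
    """Retained detections with joined metadata plus the exclusion ledger.

    ``detections`` carries focal_id, time, tag_code, animal_id, species,
    sex, fork_length_cm and is_focal (the *target* animal's flag).
    ``ledger`` has one row per exclusion rule with the number of detections
    and distinct tag codes removed; a code removed by an earlier rule is not
    re-counted by a later one.  ``quarantine`` keeps the unknown-code rows
    for audit.
    """

    detections: pd.DataFrame
    ledger: pd.DataFrame
    quarantine: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_input(self) -> int:
        return len(self.detections) + int(self.ledger["n_detections"].sum())


def apply_exclusions(detections: pd.DataFrame, registry: pd.DataFrame) -> CleanDetectionSet:
    """Apply the three exclusion rules in order and join registry metadata.

    Order: (1) tag codes absent from the registry, (2) codes whose owner
    declined permission, (3) codes flagged suspected dead.  Retained rows
    gain the registry's animal metadata.  Conservation holds by
    construction: input rows = retained rows + ledger rows.
    """
    d = detections[["focal_id", "time", "tag_code"]].copy()
    reg = registry.set_index("tag_code")

    ledger_rows = []

    known = d["tag_code"].isin(reg.index)
    quarantine = d[~known].copy()
    ledger_rows.append(
        {"rule": "unknown",
         "n_detections": int((~known).sum()),
         "n_codes": int(d.loc[~known, "tag_code"].nunique())}
    )
    d = d[known]

    denied_codes = set(reg.index[~reg["permission"]])
    denied = d["tag_code"].isin(denied_codes)
    ledger_rows.append(
        {"rule": "permission",
         "n_detections": int(denied.sum()),
         "n_codes": int(d.loc[denied, "tag_code"].nunique())}
    )
    d = d[~denied]

    dead_codes = set(reg.index[reg["status"] == "suspected_dead"])
    dead = d["tag_code"].isin(dead_codes)
    ledger_rows.append(
        {"rule": "dead",
         "n_detections": int(dead.sum()),
         "n_codes": int(d.loc[dead, "tag_code"].nunique())}
    )
    d = d[~dead]

    meta = reg[["animal_id", "species", "sex", "fork_length_cm", "is_focal"]]
    out = d.join(meta, on="tag_code").reset_index(drop=True)
    ledger = pd.DataFrame(ledger_rows, columns=["rule", "n_detections", "n_codes"])
    return CleanDetectionSet(detections=out, ledger=ledger, quarantine=quarantine)


def active_tag_counts(
    registry: pd.DataFrame,
    study_span: tuple[pd.Timestamp, pd.Timestamp],
) -> pd.Series:
    """Per-species count of tags whose active interval overlaps the span.

    Overlap is inclusive of endpoints: a tag active on the first or last
    day of the study counts.  This is the normalisation denominator for
    per-species encounter counts.
    """
    start, end = pd.Timestamp(study_span[0]), pd.Timestamp(study_span[1])
    if start > end:
        raise ValueError("study span start must not exceed end")
    overlap = (registry["active_from"] <= end) & (registry["active_to"] >= start)
    counts = registry[overlap].groupby("species")["tag_code"].nunique()
    return counts.rename("active_tags")
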