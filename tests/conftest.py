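"""Shared fixtures: tiny hand-built inputs and a reduced-scale simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from codetect import config as cfgmod
from codetect import ingest, simulate


def make_registry(rows):
    """Registry DataFrame from compact tuples:
    (tag_code, animal_id, species, sex, fl, active_from, active_to,
     permission, status, is_focal)."""
    df = pd.DataFrame(rows, columns=ingest.REGISTRY_COLUMNS)
    df["active_from"] = pd.to_datetime(df["active_from"])
    df["active_to"] = pd.to_datetime(df["active_to"])
    return df


def make_detections(rows):
    """Detections DataFrame from (focal_id, iso_time, tag_code) tuples."""
    df = pd.DataFrame(rows, columns=["focal_id", "time", "tag_code"])
    df["time"] = pd.to_datetime(df["time"], utc=True)
    return df


@pytest.fixture
def simple_registry():
    """Two focals + three conspecifics + one sturgeon; one code denied,
    one suspected dead."""
    return make_registry(
        [
            ("T-F1", "ST1", "Carcharias taurus", "M", 194.0,
             "2012-08-01", "2014-01-01", True, "alive", True),
            ("T-F2", "ST2", "Carcharias taurus", "M", 198.0,
             "2012-08-01", "2014-01-01", True, "alive", True),
            ("T-01", "CT-1", "Carcharias taurus", "F", 210.0,
             "2012-08-01", "2014-01-01", True, "alive", False),
            ("T-02", "CT-2", "Carcharias taurus", "M", 150.0,
             "2012-08-01", "2014-01-01", True, "alive", False),
            ("T-03", "CT-3", "Carcharias taurus", "M", 180.0,
             "2012-08-01", "2014-01-01", False, "alive", False),
            ("T-04", "AS-1", "Acipenser oxyrhynchus oxyrhynchus", "unknown", 140.0,
             "2012-08-01", "2014-01-01", True, "suspected_dead", False),
        ]
    )


@pytest.fixture(scope="session")
def scaled_sim():
    """One reduced-scale five-mode simulation, shared across tests."""
    cfg = cfgmod.scaled_config()
    return cfg, simulate.simulate(cfg, seed=20160930)


@pytest.fixture(scope="session")
def scaled_clean(scaled_sim):
    cfg, out = scaled_sim
    clean = ingest.apply_exclusions(out.detections, out.registry)
    active = ingest.active_tag_counts(
        out.registry, (cfg.population.study_start, cfg.population.study_end)
    )
    return cfg, out, clean, active


def rng_hours(rng: np.random.Generator, n_max: int = 40, span: int = 120) -> np.ndarray:
    """Random sorted unique integer hour set for fuzzing run finders."""
    n = int(rng.integers(0, n_max))
    return np.unique(rng.integers(0, span, n))
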