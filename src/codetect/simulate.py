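"""Agent-based synthetic telemetry generator.

Animals move on a 1-D coastal corridor (km, negative = south) in hourly
steps.  Conspecifics belong to groups re-drawn at each behavioral-mode
boundary; each hour an animal moves a fraction ``cohesion`` of the way
toward its group centroid (which drifts along the coast at the mode's
rate) plus a Gaussian diffusion step.  During the bottleneck mode all
centroids coincide (fusion); during dispersal cohesion is forced to zero
and positions diffuse apart (fission); during south migration each
conspecific female is displaced offshore — out of detection reach — with
the mode's probability, emulating sexual segregation.  Heterospecifics
hold station around fixed home centres scattered along the corridor.

Detection is range-limited: a focal transceiver hears a co-located active
tag in a given hour with probability ``p_detect * (1-collision_loss)^(k-1)``
(k = co-located non-focal tags), and records a uniformly drawn
minute-within-hour timestamp.  Ground-truth group labels and offshore
flags are kept for every animal-hour, so the fusion/fission schedule is
recoverable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    DetectionModel,
    ModePhase,
    MovementParams,
    PopulationConfig,
    SimulationConfig,
    validate_schedule,
)
from .errors import ConfigError
from . import ingest

__all__ = [
    "generate_population",
    "Tracks",
    "simulate_tracks",
    "simulate_detections",
    "simulate_fixes",
    "SimulationOutput",
    "simulate",
    "write_fixture",
    "read_fixture",
]

HOUR_NS = 3_600_000_000_000

_SPECIES_PREFIX = {
    "Carcharias taurus": "CT",
    "Acipenser oxyrhynchus oxyrhynchus": "AS",
    "Carcharhinus leucas": "BS",
    "Negaprion brevirostris": "LS",
    "Carcharhinus plumbeus": "SB",
    "Squalus acanthias": "SD",
    "Morone saxatilis": "MS",
    "Carcharodon carcharias": "WS",
}


def _prefix(species: str) -> str:
    if species in _SPECIES_PREFIX:
        return _SPECIES_PREFIX[species]
    parts = species.split()
    return "".join(p[0].upper() for p in parts[:2]) or "XX"


def generate_population(
    config: PopulationConfig, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the tagged population as a registry-shaped DataFrame.

    Focal animals (transceiver carriers) are emitted first as mature male
    conspecifics, then exactly ``species_counts[sp]`` non-focal rows per
    species.  Conspecific sexes follow ``male_prob`` and fork lengths a
    clipped normal; heterospecific metadata is drawn but plays no role
    downstream.  Active intervals always overlap the study span.
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    span_days = (config.study_end - config.study_start).days

    def draw_length(n):
        x = rng.normal(config.length_mean_cm, config.length_sd_cm, n)
        return np.clip(x, config.length_min_cm, config.length_max_cm).round(1)

    def active_interval():
        lead = int(rng.integers(0, 100))
        trail = int(rng.integers(0, 300))
        return (
            config.study_start - pd.Timedelta(days=lead),
            config.study_end + pd.Timedelta(days=trail),
        )

    focal_lengths = config.focal_fork_lengths_cm
    for i in range(config.n_focal):
        if focal_lengths is not None and i < len(focal_lengths):
            fl = float(focal_lengths[i])
        else:
            fl = float(draw_length(1)[0])
        a_from, a_to = active_interval()
        rows.append(
            {
                "tag_code": f"A69-9001-{i + 1:04d}",
                "animal_id": f"ST{i + 1}",
                "species": config.focal_species,
                "sex": "M",
                "fork_length_cm": fl,
                "active_from": a_from,
                "active_to": a_to,
                "permission": True,
                "status": "alive",
                "is_focal": True,
            }
        )

    code_serial = 1
    for sp_i, (species, count) in enumerate(sorted(config.species_counts.items())):
        if count < 0:
            raise ConfigError(f"negative count for {species!r}")
        if count == 0:
            continue
        pref = _prefix(species)
        lengths = draw_length(count)
        if species == config.focal_species:
            sexes = np.where(rng.random(count) < config.male_prob, "M", "F")
        else:
            sexes = np.full(count, "unknown", dtype=object)
        for j in range(count):
            a_from, a_to = active_interval()
            rows.append(
                {
                    "tag_code": f"A69-1{sp_i:02d}1-{code_serial:05d}",
                    "animal_id": f"{pref}-{j + 1:04d}",
                    "species": species,
                    "sex": sexes[j],
                    "fork_length_cm": float(lengths[j]),
                    "active_from": a_from,
                    "active_to": a_to,
                    "permission": True,
                    "status": "alive",
                    "is_focal": False,
                }
            )
            code_serial += 1
    pop = pd.DataFrame(rows, columns=ingest.REGISTRY_COLUMNS)
    assert pop["tag_code"].is_unique
    return pop


@dataclass
class Tracks:
    """Hourly positions plus ground truth.

    ``positions``: (n_hours, n_animals) along-coast km.
    ``offshore``: boolean, True when the animal is out of detection reach.
    ``assignments``: one row per (animal, mode phase) with the group label
    and offshore flag — constant within a phase by construction, so this
    is the lossless compact form of the per-hour truth.
    """

    hours: pd.DatetimeIndex
    animal_ids: list[str]
    positions: np.ndarray
    offshore: np.ndarray
    assignments: pd.DataFrame

    def truth_groups_frame(self) -> pd.DataFrame:
        """Expand to one row per (animal, hour): group label + offshore."""
        hours_naive = self.hours.tz_localize(None)
        out = []
        for row in self.assignments.itertuples(index=False):
            mask = (hours_naive >= row.start) & (hours_naive < row.end)
            if not mask.any():
                continue
            out.append(
                pd.DataFrame(
                    {
                        "animal_id": row.animal_id,
                        "hour_iso": self.hours[mask].strftime("%Y-%m-%dT%H:%M:%SZ"),
                        "group_id": row.group_id,
                        "offshore": bool(row.offshore),
                    }
                )
            )
        if not out:
            return pd.DataFrame(columns=["animal_id", "hour_iso", "group_id", "offshore"])
        return pd.concat(out, ignore_index=True)


def simulate_tracks(
    population: pd.DataFrame,
    schedule: list[ModePhase],
    movement: MovementParams | None = None,
    seed: int | np.random.Generator | None = None,
) -> Tracks:
    """Simulate hourly along-coast positions for every animal.

    The schedule must be contiguous; its overall span defines the hourly
    grid.  See the module docstring for the movement model.
    """
    validate_schedule(schedule)
    movement = movement or MovementParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    hours = pd.date_range(
        schedule[0].start, schedule[-1].end, freq="h", inclusive="left", tz="UTC"
    )
    hours_naive = hours.tz_localize(None)
    n_hours, n = len(hours), len(population)
    species = population["species"].to_numpy()
    sex = population["sex"].to_numpy()
    focal_species = population.loc[population["is_focal"], "species"].iloc[0] \
        if population["is_focal"].any() else species[0] if n else ""
    cons = species == focal_species
    het = ~cons

    positions = np.empty((n_hours, n), dtype=np.float64)
    offshore = np.zeros((n_hours, n), dtype=bool)

    cur = np.empty(n)
    cur[cons] = rng.normal(movement.init_center_km, movement.init_spread_km, cons.sum())
    home = rng.uniform(movement.coast_min_km, movement.coast_max_km, int(het.sum()))
    cur[het] = home + rng.normal(0.0, 5.0, int(het.sum()))

    coh = np.empty(n)
    diffusion = np.empty(n)
    coh[het] = movement.het_cohesion
    diffusion[het] = movement.het_diffusion_km_per_hr
    target = np.empty(n)
    target[het] = home

    animal_ids = population["animal_id"].tolist()
    assign_rows = []
    for sp in sorted(set(species[het])):
        for aid in population.loc[het & (species == sp), "animal_id"]:
            assign_rows.append(
                {
                    "animal_id": aid,
                    "mode_index": -1,
                    "mode_name": "resident",
                    "start": schedule[0].start,
                    "end": schedule[-1].end,
                    "group_id": f"het:{_prefix(sp)}",
                    "offshore": False,
                }
            )

    for p_i, phase in enumerate(schedule):
        in_phase = (hours_naive >= phase.start) & (hours_naive < phase.end)
        idx = np.flatnonzero(in_phase)
        # groups re-drawn at each mode boundary
        groups = rng.integers(0, phase.n_groups, int(cons.sum()))
        centroids = np.empty(phase.n_groups)
        for g in range(phase.n_groups):
            members = cur[cons][groups == g]
            centroids[g] = members.mean() if members.size else cur[cons].mean()
        if phase.name == "bottleneck":
            centroids[:] = cur[cons].mean()  # fusion: one shared centroid

        cohesion = 0.0 if phase.name == "dispersal" else min(phase.cohesion, 1.0)
        coh[cons] = cohesion
        diffusion[cons] = phase.diffusion_km_per_hr

        off_mode = np.zeros(n, dtype=bool)
        if phase.female_offshore_prob > 0:
            females = cons & (sex == "F")
            off_mode[females] = rng.random(int(females.sum())) < phase.female_offshore_prob

        for aid, g, off in zip(
            population.loc[cons, "animal_id"], groups, off_mode[cons]
        ):
            assign_rows.append(
                {
                    "animal_id": aid,
                    "mode_index": p_i,
                    "mode_name": phase.name,
                    "start": phase.start,
                    "end": phase.end,
                    "group_id": f"m{p_i}g{g}",
                    "offshore": bool(off),
                }
            )

        drift_per_hr = phase.drift_km_per_day / 24.0
        for h in idx:
            centroids += drift_per_hr
            target[cons] = centroids[groups]
            step = rng.normal(0.0, 1.0, n) * diffusion
            cur = cur + coh * (target - cur) + step
            positions[h] = cur
            offshore[h] = off_mode

    assignments = pd.DataFrame(
        assign_rows,
        columns=["animal_id", "mode_index", "mode_name", "start", "end", "group_id", "offshore"],
    )
    return Tracks(
        hours=hours,
        animal_ids=animal_ids,
        positions=positions,
        offshore=offshore,
        assignments=assignments,
    )


def _active_mask(population: pd.DataFrame, hours: pd.DatetimeIndex) -> np.ndarray:
    """(n_hours, n_animals) True where the tag is active (dates inclusive)."""
    hours_naive = hours.tz_localize(None)
    start = population["active_from"].to_numpy()
    end = (population["active_to"] + pd.Timedelta(days=1)).to_numpy()
    h = hours_naive.to_numpy()[:, None]
    return (h >= start[None, :]) & (h < end[None, :])


def simulate_detections(
    tracks: Tracks,
    population: pd.DataFrame,
    model: DetectionModel | None = None,
    seed: int | np.random.Generator | None = None,
    chunk_hours: int = 512,
) -> pd.DataFrame:
    """Generate detection records from true positions.

    A focal f records tag g at hour t iff |pos_f - pos_g| <= range_km,
    both tags are active and inshore at t, and a Bernoulli draw with
    probability ``p_detect * (1-collision_loss)^(k-1)`` succeeds, where k
    is the number of non-focal tags co-located with f.  No false
    positives exist by construction.
    """
    model = model or DetectionModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = tracks.positions
    n_hours, n = pos.shape
    active = _active_mask(population, tracks.hours)
    usable = active & ~tracks.offshore
    is_focal = population["is_focal"].to_numpy()
    focal_idx = np.flatnonzero(is_focal)
    tag_codes = population["tag_code"].to_numpy()
    focal_ids = population["animal_id"].to_numpy()

    rec_focal: list[np.ndarray] = []
    rec_hour: list[np.ndarray] = []
    rec_tag: list[np.ndarray] = []
    for f in focal_idx:
        for lo in range(0, n_hours, chunk_hours):
            hi = min(lo + chunk_hours, n_hours)
            d = np.abs(pos[lo:hi] - pos[lo:hi, [f]])
            in_range = (d <= model.range_km) & usable[lo:hi]
            in_range &= usable[lo:hi, [f]]
            in_range[:, f] = False
            k = in_range[:, ~is_focal].sum(axis=1)
            p_eff = model.p_detect_per_hour * (1.0 - model.collision_loss) ** np.maximum(
                k - 1, 0
            )
            hit = in_range & (rng.random(in_range.shape) < p_eff[:, None])
            hh, aa = np.nonzero(hit)
            if hh.size:
                rec_focal.append(np.full(hh.size, focal_ids[f]))
                rec_hour.append(hh + lo)
                rec_tag.append(tag_codes[aa])

    if not rec_hour:
        return pd.DataFrame(columns=["focal_id", "time", "tag_code"])
    hour_idx = np.concatenate(rec_hour)
    minutes = rng.integers(0, 60, hour_idx.size)
    times = tracks.hours[hour_idx] + pd.to_timedelta(minutes, unit="m")
    out = pd.DataFrame(
        {
            "focal_id": np.concatenate(rec_focal),
            "time": times,
            "tag_code": np.concatenate(rec_tag),
        }
    )
    return out.sort_values(["focal_id", "time", "tag_code"]).reset_index(drop=True)


def _km_to_latlon(km: np.ndarray, fixes_model) -> tuple[np.ndarray, np.ndarray]:
    lat = fixes_model.base_lat + km / fixes_model.km_per_degree_lat
    lon = np.full_like(lat, fixes_model.base_lon)
    return lat, lon


def simulate_fixes(
    tracks: Tracks,
    population: pd.DataFrame,
    fix_model,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily position fixes from a moored receiver line plus focal pop-ups.

    Each inshore day an animal yields a moored-receiver fix with
    probability ``p_fix_*_per_day``, its noon position snapped to the
    nearest receiver.  Each focal gets one satellite pop-up fix at its
    final active day's true position.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hours_naive = tracks.hours.tz_localize(None)
    days = pd.DatetimeIndex(hours_naive.normalize().unique())
    is_focal = population["is_focal"].to_numpy()
    animal_ids = population["animal_id"].to_numpy()

    day_pos = np.empty((len(days), len(animal_ids)))
    day_off = np.zeros((len(days), len(animal_ids)), dtype=bool)
    day_of_hour = np.searchsorted(days.to_numpy(), hours_naive.normalize().to_numpy())
    for d_i in range(len(days)):
        sel = day_of_hour == d_i
        day_pos[d_i] = tracks.positions[sel].mean(axis=0)
        day_off[d_i] = tracks.offshore[sel].any(axis=0)

    active = _active_mask(population, pd.DatetimeIndex(days, tz="UTC"))
    p_fix = np.where(is_focal, fix_model.p_fix_focal_per_day, fix_model.p_fix_other_per_day)
    hit = (rng.random(day_pos.shape) < p_fix[None, :]) & active & ~day_off

    spacing = fix_model.receiver_spacing_km
    d_i, a_i = np.nonzero(hit)
    snapped = np.round(day_pos[d_i, a_i] / spacing) * spacing
    lat, lon = _km_to_latlon(snapped, fix_model)
    rows = pd.DataFrame(
        {
            "animal_id": animal_ids[a_i],
            "date": days[d_i],
            "lat": np.round(lat, 4),
            "lon": np.round(lon, 4),
            "source": "moored_receiver",
        }
    )

    # pop-up fix at each focal's last simulated day
    pop_rows = []
    for f in np.flatnonzero(is_focal):
        lat_f, lon_f = _km_to_latlon(np.array([day_pos[-1, f]]), fix_model)
        pop_rows.append(
            {
                "animal_id": animal_ids[f],
                "date": days[-1],
                "lat": round(float(lat_f[0]), 4),
                "lon": round(float(lon_f[0]), 4),
                "source": "psat_popup",
            }
        )
    out = pd.concat([rows, pd.DataFrame(pop_rows)], ignore_index=True)
    return out.sort_values(["animal_id", "date"]).reset_index(drop=True)


@dataclass
class SimulationOutput:
    """Everything one simulation run produces, plus its seed."""

    detections: pd.DataFrame
    registry: pd.DataFrame
    fixes: pd.DataFrame
    tracks: Tracks
    rng_seed: int | None

    def truth_groups(self) -> pd.DataFrame:
        return self.tracks.truth_groups_frame()


def simulate(config: SimulationConfig, seed: int | None = None) -> SimulationOutput:
    """Run the full generator: population -> tracks -> detections -> fixes.

    All randomness flows from the single integer seed through spawned
    child generators; the same seed reproduces the output exactly.
    """
    ss = np.random.SeedSequence(seed)
    rng_pop, rng_trk, rng_det, rng_fix = (np.random.default_rng(s) for s in ss.spawn(4))
    population = generate_population(config.population, rng_pop)
    tracks = simulate_tracks(population, config.schedule, config.movement, rng_trk)
    detections = simulate_detections(tracks, population, config.detection, rng_det)
    fixes = simulate_fixes(tracks, population, config.fixes, rng_fix)
    return SimulationOutput(
        detections=detections,
        registry=population,
        fixes=fixes,
        tracks=tracks,
        rng_seed=seed,
    )


def write_fixture(
    output: SimulationOutput, directory, truth: str = "expanded"
) -> dict[str, Path]:
    """Write the three pipeline inputs plus ground truth as CSV.

    Files: detections.csv, registry.csv, fixes.csv, truth_groups.csv.
    Reading them back with :func:`read_fixture` reproduces the in-memory
    records exactly (timestamps at second precision, dates as dates).

    ``truth="expanded"`` writes one row per (animal, hour);
    ``truth="compact"`` writes the per-(animal, mode) assignment table
    instead — lossless, since labels are constant within a mode — which
    keeps study-scale runs to a manageable file size.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    det = output.detections.copy()
    det["time"] = pd.to_datetime(det["time"], utc=True)
    det[ingest.TIMESTAMP_COL] = det["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    det = det[["focal_id", ingest.TIMESTAMP_COL, "tag_code"]]
    paths["detections"] = directory / "detections.csv"
    det.to_csv(paths["detections"], index=False)

    reg = output.registry.copy()
    if len(reg):
        reg["active_from"] = pd.to_datetime(reg["active_from"]).dt.strftime("%Y-%m-%d")
        reg["active_to"] = pd.to_datetime(reg["active_to"]).dt.strftime("%Y-%m-%d")
    paths["registry"] = directory / "registry.csv"
    reg.to_csv(paths["registry"], index=False)

    fx = output.fixes.copy()
    if len(fx):
        fx["date"] = pd.to_datetime(fx["date"]).dt.strftime("%Y-%m-%d")
    paths["fixes"] = directory / "fixes.csv"
    fx.to_csv(paths["fixes"], index=False)

    if truth == "expanded":
        paths["truth_groups"] = directory / "truth_groups.csv"
        output.truth_groups().to_csv(paths["truth_groups"], index=False)
    elif truth == "compact":
        paths["truth_groups"] = directory / "truth_groups_compact.csv"
        output.tracks.assignments.to_csv(paths["truth_groups"], index=False)
    else:
        raise ValueError(f"unknown truth mode {truth!r}")
    return paths


def read_fixture(directory) -> dict[str, pd.DataFrame]:
    """Load a written fixture back into DataFrames (see write_fixture)."""
    directory = Path(directory)
    load = ingest.load_detections(directory / "detections.csv")
    if len(load.rejects):
        raise ValueError(f"fixture contains malformed detection rows: {len(load.rejects)}")
    truth_path = directory / "truth_groups.csv"
    if not truth_path.exists():
        truth_path = directory / "truth_groups_compact.csv"
    return {
        "detections": load.records,
        "registry": ingest.load_registry(directory / "registry.csv"),
        "fixes": ingest.load_fixes(directory / "fixes.csv"),
        "truth_groups": pd.read_csv(truth_path),
    }
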