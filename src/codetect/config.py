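"""Simulation and pipeline configuration.

The synthetic generator emulates the study system: two transceiver-carrying
focal sand tigers inside a tagged population of conspecifics and several
heterospecific tag pools at regional-network scale, moving along a 1-D
coastal corridor (km; negative is south) through a scheduled sequence of
behavioral modes — summering, south migration, community bottleneck,
dispersal, north migration — that drive group fusion and fission and
sexual segregation during the southward leg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import pandas as pd
import yaml

from .errors import ConfigError
from . import reference

MODE_NAMES = (
    "summering",
    "south_migration",
    "bottleneck",
    "dispersal",
    "north_migration",
)


@dataclass
class ModePhase:
    """One scheduled behavioral mode.

    ``cohesion`` is the per-hour attraction fraction toward the group
    centroid (1 snaps members onto it); ``drift_km_per_day`` moves the
    centroids along the coast (negative = south); ``diffusion_km_per_hr``
    is the sd of the hourly random-walk step; ``female_offshore_prob`` is
    the chance a conspecific female is displaced offshore (out of
    detection reach) for the whole phase.
    """

    name: str
    start: pd.Timestamp
    end: pd.Timestamp
    cohesion: float = 0.1
    n_groups: int = 1
    drift_km_per_day: float = 0.0
    female_offshore_prob: float = 0.0
    diffusion_km_per_hr: float = 0.5

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if self.name not in MODE_NAMES:
            raise ConfigError(f"unknown mode {self.name!r}; expected one of {MODE_NAMES}")
        if self.start >= self.end:
            raise ConfigError(f"mode {self.name}: start must precede end")
        if self.cohesion < 0:
            raise ConfigError("cohesion must be non-negative")
        if self.n_groups < 1:
            raise ConfigError("n_groups must be positive")
        if not 0 <= self.female_offshore_prob <= 1:
            raise ConfigError("female_offshore_prob must be in [0, 1]")
        if self.diffusion_km_per_hr < 0:
            raise ConfigError("diffusion must be non-negative")


def validate_schedule(schedule: Sequence[ModePhase]) -> None:
    """Phases must be contiguous and non-overlapping (no gaps)."""
    if not schedule:
        raise ConfigError("schedule is empty")
    for a, b in zip(schedule, schedule[1:]):
        if a.end != b.start:
            raise ConfigError(
                f"schedule gap/overlap between {a.name} (ends {a.end}) "
                f"and {b.name} (starts {b.start})"
            )


@dataclass
class PopulationConfig:
    """Scale and composition of the tagged population.

    ``species_counts`` are non-focal tag counts per species; focal animals
    are additional conspecifics carrying transceivers.  Conspecific fork
    lengths are drawn from a clipped normal; sexes from ``male_prob``.
    """

    study_start: pd.Timestamp
    study_end: pd.Timestamp
    species_counts: dict[str, int] = field(default_factory=dict)
    focal_species: str = reference.FOCAL_SPECIES
    n_focal: int = 2
    focal_fork_lengths_cm: tuple[float, ...] | None = (194.0, 198.0)
    male_prob: float = 0.5
    length_mean_cm: float = 175.0
    length_sd_cm: float = 35.0
    length_min_cm: float = 75.0
    length_max_cm: float = 250.0

    def __post_init__(self):
        self.study_start = pd.Timestamp(self.study_start)
        self.study_end = pd.Timestamp(self.study_end)
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")
        for sp, n in self.species_counts.items():
            if n < 0:
                raise ConfigError(f"species count for {sp!r} must be >= 0")
        if self.n_focal < 1:
            raise ConfigError("need at least one focal animal")
        if not 0 <= self.male_prob <= 1:
            raise ConfigError("male_prob must be in [0, 1]")


@dataclass
class DetectionModel:
    """Range-limited hourly detection with geometric collision thinning.

    A focal hears a co-located tag in a given hour with probability
    ``p_detect_per_hour * (1 - collision_loss)^(k-1)`` where k is the
    number of co-located non-focal tags — crowded water loses codes.
    """

    range_km: float = 0.4
    p_detect_per_hour: float = 0.5
    collision_loss: float = 0.002

    def __post_init__(self):
        if self.range_km <= 0:
            raise ConfigError("range_km must be positive")
        for name in ("p_detect_per_hour", "collision_loss"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")


@dataclass
class MovementParams:
    """Corridor geometry and heterospecific movement.

    Heterospecifics hold station around fixed home centres drawn uniformly
    along the corridor, so only those near the focals' path are ever heard.
    """

    coast_min_km: float = -700.0
    coast_max_km: float = 50.0
    init_center_km: float = 0.0
    init_spread_km: float = 10.0
    het_cohesion: float = 0.02
    het_diffusion_km_per_hr: float = 1.0


@dataclass
class FixModel:
    """Moored receiver line + pop-up tags generating position fixes.

    Receivers sit every ``receiver_spacing_km`` along the coast; a fix
    snaps the animal's daily position to the nearest receiver.  One
    satellite pop-up fix is emitted per focal at the end of its record.
    """

    receiver_spacing_km: float = 25.0
    p_fix_focal_per_day: float = 0.3
    p_fix_other_per_day: float = 0.02
    base_lat: float = 38.9
    base_lon: float = -75.0
    km_per_degree_lat: float = 111.32


@dataclass
class SimulationConfig:
    population: PopulationConfig
    schedule: list[ModePhase]
    detection: DetectionModel = field(default_factory=DetectionModel)
    movement: MovementParams = field(default_factory=MovementParams)
    fixes: FixModel = field(default_factory=FixModel)

    def __post_init__(self):
        validate_schedule(self.schedule)
        if self.schedule[0].start != self.population.study_start or \
                self.schedule[-1].end != self.population.study_end:
            raise ConfigError("schedule must cover exactly the study span")


def _default_schedule(start: str, end: str) -> list[ModePhase]:
    return [
        ModePhase("summering", start, "2012-10-01",
                  cohesion=0.02, n_groups=5, drift_km_per_day=0.0,
                  female_offshore_prob=0.0, diffusion_km_per_hr=0.5),
        ModePhase("south_migration", "2012-10-01", "2012-12-01",
                  cohesion=0.1, n_groups=5, drift_km_per_day=-10.0,
                  female_offshore_prob=0.9, diffusion_km_per_hr=0.5),
        ModePhase("bottleneck", "2012-12-01", "2013-04-01",
                  cohesion=0.05, n_groups=1, drift_km_per_day=0.0,
                  female_offshore_prob=0.0, diffusion_km_per_hr=0.5),
        ModePhase("dispersal", "2013-04-01", "2013-06-01",
                  cohesion=0.0, n_groups=10, drift_km_per_day=0.0,
                  female_offshore_prob=0.0, diffusion_km_per_hr=1.5),
        ModePhase("north_migration", "2013-06-01", end,
                  cohesion=0.1, n_groups=5, drift_km_per_day=11.0,
                  female_offshore_prob=0.0, diffusion_km_per_hr=0.5),
    ]


def default_config() -> SimulationConfig:
    """Study-scale defaults: the regional network's tag pools (per species)
    around two focal transceivers over the ~11-month span, with the five
    behavioral modes laid out along the annual migration."""
    start, end = str(reference.STUDY_START.date()), str(reference.STUDY_END.date())
    counts = dict(
        zip(reference.DETECTION_SUMMARY["species"], reference.DETECTION_SUMMARY["active_tags"])
    )
    pop = PopulationConfig(study_start=start, study_end=end, species_counts=counts)
    return SimulationConfig(population=pop, schedule=_default_schedule(start, end))


def scaled_config(
    n_conspecific: int = 60,
    n_heterospecific: int = 40,
    start: str = "2012-09-01",
) -> SimulationConfig:
    """Reduced-scale configuration: same five-mode structure compressed to
    one month per mode over a smaller population.  Used for fast
    experiments and repeated-seed statistical checks."""
    t0 = pd.Timestamp(start)
    bounds = [t0 + pd.DateOffset(months=k) for k in range(6)]
    b = [str(ts.date()) for ts in bounds]
    schedule = [
        ModePhase("summering", b[0], b[1], cohesion=0.02, n_groups=3,
                  diffusion_km_per_hr=0.5),
        ModePhase("south_migration", b[1], b[2], cohesion=0.1, n_groups=3,
                  drift_km_per_day=-10.0, female_offshore_prob=0.9,
                  diffusion_km_per_hr=0.5),
        ModePhase("bottleneck", b[2], b[3], cohesion=0.05, n_groups=1,
                  diffusion_km_per_hr=0.5),
        ModePhase("dispersal", b[3], b[4], cohesion=0.0, n_groups=6,
                  diffusion_km_per_hr=1.5),
        ModePhase("north_migration", b[4], b[5], cohesion=0.1, n_groups=3,
                  drift_km_per_day=10.0, diffusion_km_per_hr=0.5),
    ]
    pop = PopulationConfig(
        study_start=b[0],
        study_end=b[5],
        species_counts={
            reference.FOCAL_SPECIES: n_conspecific,
            "Acipenser oxyrhynchus oxyrhynchus": n_heterospecific,
        },
    )
    return SimulationConfig(
        population=pop,
        schedule=schedule,
        movement=MovementParams(coast_min_km=-350.0, coast_max_km=50.0),
    )


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["population"]["study_start"] = str(cfg.population.study_start.date())
    d["population"]["study_end"] = str(cfg.population.study_end.date())
    if d["population"]["focal_fork_lengths_cm"] is not None:
        d["population"]["focal_fork_lengths_cm"] = list(
            d["population"]["focal_fork_lengths_cm"]
        )
    for ph, phase in zip(d["schedule"], cfg.schedule):
        ph["start"] = str(phase.start.date())
        ph["end"] = str(phase.end.date())
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    pop = dict(d["population"])
    if pop.get("focal_fork_lengths_cm") is not None:
        pop["focal_fork_lengths_cm"] = tuple(pop["focal_fork_lengths_cm"])
    return SimulationConfig(
        population=PopulationConfig(**pop),
        schedule=[ModePhase(**ph) for ph in d["schedule"]],
        detection=DetectionModel(**d.get("detection", {})),
        movement=MovementParams(**d.get("movement", {})),
        fixes=FixModel(**d.get("fixes", {})),
    )


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
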