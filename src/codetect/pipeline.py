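"""End-to-end pipeline: clean -> summarize -> associate -> community ->
locate -> networks, with every table written as tidy CSV and a manifest
recording the configuration and seed, so a run is reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import associations, community, encounters, geolocate, ingest, networks
from .errors import CodetectError

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    detections_path: str
    registry_path: str
    fixes_path: str
    out_dir: str
    study_start: str | None = None  # default: span of the detection record
    study_end: str | None = None
    focal_ids: tuple[str, str] | None = None  # default: from registry is_focal
    min_event_hours: int = 2
    window_days: int = 7
    n_sim: int = 2000
    n_perm: int = 100
    seed: int = 0
    export_graphs: bool = True

    def __post_init__(self):
        if self.min_event_hours < 1 or self.window_days < 0:
            raise CodetectError("min_event_hours must be >=1 and window_days >=0")
        if self.n_sim < 1 or self.n_perm < 1:
            raise CodetectError("n_sim and n_perm must be positive")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _composition_tests(monthly, registry, focal_species, n_sim, rng):
    """Sex-ratio and size-bin goodness-of-fit per (focal, month) against
    the tagged conspecific population."""
    pop = registry[(registry["species"] == focal_species) & (~registry["is_focal"])]
    sex_counts = pop["sex"].value_counts().reindex(["M", "F"]).dropna()
    sex_props = sex_counts / sex_counts.sum()
    bins = pop["fork_length_cm"].map(community.size_binning)
    bin_order = [b for b in community.size_bin_labels(True) if (bins == b).any()]
    bin_counts = bins.value_counts().reindex(bin_order)
    bin_props = bin_counts / bin_counts.sum()

    rows = []
    ind = monthly.individuals
    consp = ind[ind["species"] == focal_species]
    for (focal, month), grp in consp.groupby(["focal_id", "month"], observed=True):
        sexed = grp[grp["sex"].isin(["M", "F"])]
        if len(sexed):
            obs = sexed["sex"].value_counts().reindex(sex_props.index, fill_value=0)
            res = community.composition_chisq(
                obs, sex_props, n_sim=n_sim, seed=rng
            )
            rows.append(
                {
                    "focal_id": focal, "month": month, "test": "sex_ratio",
                    "n": int(obs.sum()), "statistic": res.statistic, "df": res.df,
                    "p_value": res.p_value, "method": res.method,
                }
            )
        obs_bins = grp["fork_length_cm"].map(community.size_binning)
        obs = obs_bins.value_counts().reindex(bin_props.index, fill_value=0)
        if obs.sum() > 0:
            res = community.composition_chisq(obs, bin_props, n_sim=n_sim, seed=rng)
            rows.append(
                {
                    "focal_id": focal, "month": month, "test": "size_bins",
                    "n": int(obs.sum()), "statistic": res.statistic, "df": res.df,
                    "p_value": res.p_value, "method": res.method,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["focal_id", "month", "test", "n", "statistic", "df", "p_value", "method"],
    )


def _similarity_tables(vectors_by_focal, level):
    mats, consec = [], []
    for focal, vectors in vectors_by_focal.items():
        if len(vectors) < 2:
            continue
        mat = community.similarity_matrix(vectors)
        tidy = mat.stack().rename("similarity").reset_index()
        tidy.columns = ["month_i", "month_j", "similarity"]
        tidy.insert(0, "focal_id", focal)
        tidy.insert(1, "level", level)
        mats.append(tidy)
        series = community.consecutive_similarity(vectors)
        series.insert(0, "focal_id", focal)
        series.insert(1, "level", level)
        consec.append(series)
    empty = pd.DataFrame()
    return (
        pd.concat(mats, ignore_index=True) if mats else empty,
        pd.concat(consec, ignore_index=True) if consec else empty,
    )


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the whole analysis; returns the report directory.

    Any stage failure aborts with the stage name and cause.  Outputs are a
    pure function of (inputs, config, seed).
    """
    for p in (cfg.detections_path, cfg.registry_path, cfg.fixes_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    # -- clean ------------------------------------------------------------
    load = _stage("clean")(ingest.load_detections)(cfg.detections_path)
    registry = _stage("clean")(ingest.load_registry)(cfg.registry_path)
    clean = _stage("clean")(ingest.apply_exclusions)(load.records, registry)
    clean.ledger.to_csv(out / "exclusion_ledger.csv", index=False)
    clean.quarantine.to_csv(out / "quarantine.csv", index=False)
    load.rejects.to_csv(out / "rejects.csv", index=False)

    focal_rows = registry[registry["is_focal"]]
    focal_species = focal_rows["species"].iloc[0] if len(focal_rows) else None
    focal_ids = cfg.focal_ids or tuple(focal_rows["animal_id"])[:2]

    span = (
        pd.Timestamp(cfg.study_start) if cfg.study_start
        else clean.detections["time"].min().tz_localize(None),
        pd.Timestamp(cfg.study_end) if cfg.study_end
        else clean.detections["time"].max().tz_localize(None),
    )
    # non-focal rows only: a transceiver's own tag is not a detectable other
    active = _stage("clean")(ingest.active_tag_counts)(
        registry[~registry["is_focal"]], span
    )

    # -- summarize --------------------------------------------------------
    presence = _stage("summarize")(encounters.bin_hours)(clean)
    monthly = _stage("summarize")(encounters.monthly_communities)(clean, active)
    presence.table.to_csv(out / "presence.csv", index=False)
    monthly.individuals.to_csv(out / "monthly_individuals.csv", index=False)
    monthly.species.to_csv(out / "monthly_species.csv", index=False)

    n_active_consp = int(active.get(focal_species, 0)) if focal_species else 0
    cov_rows = []
    if n_active_consp:
        consp = monthly.individuals[monthly.individuals["species"] == focal_species]
        for focal in focal_ids:
            n_det = consp.loc[consp["focal_id"] == focal, "animal_id"].nunique()
            cov_rows.append(
                {
                    "focal_id": focal,
                    "n_detected": n_det,
                    "n_active": n_active_consp,
                    "coverage_pct": community.coverage_percent(n_det, n_active_consp),
                }
            )
    pd.DataFrame(cov_rows).to_csv(out / "coverage.csv", index=False)

    # -- associate --------------------------------------------------------
    dyads = _stage("associate")(associations.summarize_dyads)(
        presence, cfg.min_event_hours
    )
    events = _stage("associate")(associations.consecutive_events)(
        presence, cfg.min_event_hours
    )
    dyads.to_csv(out / "dyads.csv", index=False)
    events.to_csv(out / "events.csv", index=False)
    coenc = None
    if len(focal_ids) == 2:
        coenc = _stage("associate")(associations.co_encounters)(
            clean, tuple(focal_ids), species=focal_species
        )
        coenc.monthly.to_csv(out / "coencounters.csv", index=False)

    # -- community --------------------------------------------------------
    div_rows, rare_frames = [], []
    for focal in focal_ids:
        vecs = monthly.detection_day_vectors(focal, focal_species)
        for month, v in vecs.items():
            div_rows.append(
                {
                    "focal_id": focal, "month": month,
                    "H": community.shannon_diversity(v), "richness": len(v),
                }
            )
        sets = monthly.unique_sets(focal, species=focal_species)
        if sets:
            months_sorted = sorted(sets)
            curve = community.rarefaction_curve(
                [sets[m] for m in months_sorted], n_perm=cfg.n_perm, seed=rng,
                method="auto",
            )
            curve.insert(0, "focal_id", focal)
            rare_frames.append(curve)
    pd.DataFrame(div_rows).to_csv(out / "diversity.csv", index=False)
    (pd.concat(rare_frames, ignore_index=True) if rare_frames else pd.DataFrame()
     ).to_csv(out / "rarefaction.csv", index=False)

    indiv_vecs = {
        f: monthly.detection_day_vectors(f, focal_species) for f in focal_ids
    }
    sp_vecs = {f: monthly.species_vectors(f) for f in focal_ids}
    mat_i, con_i = _similarity_tables(indiv_vecs, "individual")
    mat_s, con_s = _similarity_tables(sp_vecs, "species")
    pd.concat([mat_i, mat_s], ignore_index=True).to_csv(
        out / "similarity.csv", index=False
    )
    pd.concat([con_i, con_s], ignore_index=True).to_csv(
        out / "similarity_consecutive.csv", index=False
    )
    comptests = _stage("community")(_composition_tests)(
        monthly, registry, focal_species, cfg.n_sim, rng
    )
    comptests.to_csv(out / "comptests.csv", index=False)

    # -- locate -----------------------------------------------------------
    fixes = _stage("locate")(ingest.load_fixes)(cfg.fixes_path)
    located = _stage("locate")(geolocate.assign_locations)(
        clean.detections, fixes, cfg.window_days
    )
    located.to_csv(out / "located_events.csv", index=False)

    # -- networks ---------------------------------------------------------
    nets = _stage("networks")(networks.build_monthly_networks)(
        monthly, coenc, focal_species
    )
    net_rows = []
    if cfg.export_graphs:
        gdir = out / "networks"
        gdir.mkdir(exist_ok=True)
        for net in nets:
            fname = f"{net.month}_{net.stratum}.graphml"
            networks.export_graphml(net, gdir / fname)
            net_rows.append(
                {
                    "month": net.month, "stratum": net.stratum,
                    "n_nodes": net.graph.number_of_nodes(),
                    "n_edges": net.graph.number_of_edges(),
                    "shared_fraction": net.shared_fraction,
                    "file": f"networks/{fname}",
                }
            )
    pd.DataFrame(net_rows).to_csv(out / "network_summary.csv", index=False)

    manifest = {
        "codetect_version": __version__,
        "config": asdict(cfg),
        "seed": cfg.seed,
        "focal_ids": list(focal_ids),
        "focal_species": focal_species,
        "n_detections_in": int(len(load.records)),
        "n_rejected_rows": int(len(load.rejects)),
        "exclusions": clean.ledger.to_dict(orient="records"),
        "n_retained": int(len(clean.detections)),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
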