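"""Synthetic telemetry generator: population, tracks, detections, fixtures."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codetect import config as cfgmod
from codetect import simulate
from codetect.config import DetectionModel, ModePhase, MovementParams, PopulationConfig
from codetect.errors import ConfigError


def small_population(**kw):
    defaults = dict(
        study_start="2012-09-01",
        study_end="2012-09-11",
        species_counts={"Carcharias taurus": 4},
        n_focal=1,
        focal_fork_lengths_cm=None,
    )
    defaults.update(kw)
    return PopulationConfig(**defaults)


def one_phase(name="summering", start="2012-09-01", end="2012-09-11", **kw):
    return [ModePhase(name, start, end, **kw)]


class TestGeneratePopulation:
    def test_study_scale_counts(self):
        cfg = PopulationConfig(
            study_start="2012-08-24",
            study_end="2013-07-27",
            species_counts={
                "Carcharias taurus": 325,
                "Acipenser oxyrhynchus oxyrhynchus": 1142,
            },
        )
        pop = simulate.generate_population(cfg, seed=0)
        assert int((~pop["is_focal"]).sum()) == 1467
        assert int(pop["is_focal"].sum()) == 2
        bysp = pop[~pop["is_focal"]].groupby("species").size()
        assert bysp["Carcharias taurus"] == 325
        assert bysp["Acipenser oxyrhynchus oxyrhynchus"] == 1142

    def test_zero_count_species_absent(self):
        cfg = small_population(species_counts={"Carcharias taurus": 3, "Morone saxatilis": 0})
        pop = simulate.generate_population(cfg, seed=1)
        assert "Morone saxatilis" not in set(pop["species"])

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = small_population()
        a = simulate.generate_population(cfg, seed=7)
        b = simulate.generate_population(cfg, seed=7)
        pd.testing.assert_frame_equal(a, b)
        fa, fb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(fa, index=False)
        b.to_csv(fb, index=False)
        assert fa.read_bytes() == fb.read_bytes()

    def test_negative_count_is_error(self):
        with pytest.raises(ConfigError):
            PopulationConfig(
                study_start="2012-09-01",
                study_end="2012-09-02",
                species_counts={"X": -1},
            )

    def test_tag_codes_unique_and_sexes_follow_ratio(self):
        cfg = small_population(species_counts={"Carcharias taurus": 400}, male_prob=0.5)
        pop = simulate.generate_population(cfg, seed=3)
        assert pop["tag_code"].is_unique
        n_m = int((pop.loc[~pop["is_focal"], "sex"] == "M").sum())
        # binomial(400, .5) central 99.9% interval
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 400, 0.5)
        assert lo <= n_m <= hi


class TestSimulateTracks:
    def test_snap_limit_all_members_on_centroid(self):
        pop = simulate.generate_population(small_population(), seed=0)
        tracks = simulate.simulate_tracks(
            pop,
            one_phase(cohesion=1.0, n_groups=1, diffusion_km_per_hr=0.0),
            seed=0,
        )
        spread = tracks.positions.max(axis=1) - tracks.positions.min(axis=1)
        assert (spread < 1e-9).all()

    def test_centroid_drift_displacement(self):
        pop = simulate.generate_population(small_population(), seed=0)
        d = -8.0
        tracks = simulate.simulate_tracks(
            pop,
            one_phase(name="south_migration", cohesion=1.0, n_groups=1,
                      drift_km_per_day=d, diffusion_km_per_hr=0.0),
            seed=0,
        )
        k_days = 10
        displacement = tracks.positions[-1, 0] - tracks.positions[0, 0]
        expected = d * (k_days * 24 - 1) / 24  # first hour already includes one step
        assert displacement == pytest.approx(expected, abs=1e-6)

    def test_dispersal_mean_pairwise_distance_increases(self):
        """Positions diffuse apart with cohesion off: the mean pairwise
        distance at the end of the mode exceeds the start in every seed."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            pop = simulate.generate_population(small_population(), seed=seed)
            tracks = simulate.simulate_tracks(
                pop,
                one_phase(name="dispersal", cohesion=0.5, n_groups=1,
                          diffusion_km_per_hr=1.0),
                seed=seed,
            )
            def mpd(row):
                diffs = np.abs(row[:, None] - row[None, :])
                return diffs[np.triu_indices(len(row), 1)].mean()
            wins += mpd(tracks.positions[-1]) > mpd(tracks.positions[0])
        assert stats.binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue < 0.01

    def test_dispersal_forces_zero_cohesion(self):
        # with diffusion 0 and cohesion ignored, positions freeze
        pop = simulate.generate_population(small_population(), seed=2)
        tracks = simulate.simulate_tracks(
            pop,
            one_phase(name="dispersal", cohesion=1.0, n_groups=1,
                      diffusion_km_per_hr=0.0),
            seed=2,
        )
        assert np.allclose(tracks.positions[0], tracks.positions[-1])

    def test_schedule_gap_is_error(self):
        pop = simulate.generate_population(small_population(), seed=0)
        gap = [
            ModePhase("summering", "2012-09-01", "2012-09-05"),
            ModePhase("dispersal", "2012-09-06", "2012-09-11"),
        ]
        with pytest.raises(ConfigError, match="gap"):
            simulate.simulate_tracks(pop, gap, seed=0)

    def test_groups_redrawn_at_mode_boundary(self):
        pop = simulate.generate_population(
            small_population(species_counts={"Carcharias taurus": 30}), seed=5
        )
        phases = [
            ModePhase("summering", "2012-09-01", "2012-09-05", n_groups=3),
            ModePhase("dispersal", "2012-09-05", "2012-09-11", n_groups=5),
        ]
        tracks = simulate.simulate_tracks(pop, phases, seed=5)
        a = tracks.assignments
        consp = a[a["mode_index"] >= 0]
        assert set(consp["mode_name"]) == {"summering", "dispersal"}
        per_mode = consp.groupby("mode_name")["group_id"].nunique()
        assert per_mode["summering"] <= 3 and per_mode["dispersal"] <= 5


class TestSimulateDetections:
    def _two_colocated(self, p_detect, seed=0, days=10):
        cfg = small_population(
            study_start="2012-09-01",
            study_end=str(pd.Timestamp("2012-09-01") + pd.Timedelta(days=days)),
            species_counts={"Carcharias taurus": 1},
        )
        pop = simulate.generate_population(cfg, seed=seed)
        phases = one_phase(
            end=str(pd.Timestamp("2012-09-01") + pd.Timedelta(days=days)),
            cohesion=1.0, n_groups=1, diffusion_km_per_hr=0.0,
        )
        tracks = simulate.simulate_tracks(pop, phases, seed=seed)
        det = simulate.simulate_detections(
            tracks, pop,
            DetectionModel(p_detect_per_hour=p_detect, collision_loss=0.0),
            seed=seed,
        )
        return pop, tracks, det

    def test_certain_detection_every_hour(self):
        pop, tracks, det = self._two_colocated(1.0)
        # one focal, one co-located conspecific: one detection per hour
        assert len(det) == len(tracks.hours)
        hours = det["time"].dt.floor("h")
        assert hours.is_unique

    def test_out_of_range_never_detected(self):
        cfg = small_population(species_counts={"Carcharias taurus": 1})
        pop = simulate.generate_population(cfg, seed=1)
        phases = one_phase(cohesion=0.0, diffusion_km_per_hr=0.0)
        tracks = simulate.simulate_tracks(pop, phases, seed=1)
        tracks.positions[:, 1] = tracks.positions[:, 0] + 10.0  # 10 km apart
        det = simulate.simulate_detections(tracks, pop, DetectionModel(), seed=1)
        assert len(det) == 0

    def test_detection_count_in_binomial_interval(self):
        pop, tracks, det = self._two_colocated(0.5, seed=11, days=42)
        n = len(tracks.hours)
        assert n >= 1000
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= len(det) <= hi

    def test_no_false_positives_by_construction(self, scaled_sim):
        cfg, out = scaled_sim
        pop = out.registry
        pos_idx = {a: i for i, a in enumerate(pop["animal_id"])}
        code_to_animal = pop.set_index("tag_code")["animal_id"]
        hour_index = {h: i for i, h in enumerate(out.tracks.hours)}
        sample = out.detections.sample(n=min(500, len(out.detections)), random_state=0)
        for row in sample.itertuples(index=False):
            h = hour_index[row.time.floor("h")]
            f_i = pos_idx[row.focal_id]
            a_i = pos_idx[code_to_animal[row.tag_code]]
            dist = abs(out.tracks.positions[h, f_i] - out.tracks.positions[h, a_i])
            assert dist <= cfg.detection.range_km + 1e-9
            assert not out.tracks.offshore[h, a_i]

    def test_offshore_females_silent_during_south_migration(self):
        cfg = cfgmod.scaled_config(n_conspecific=40, n_heterospecific=0)
        for ph in cfg.schedule:
            if ph.name == "south_migration":
                ph.female_offshore_prob = 1.0
        out = simulate.simulate(cfg, seed=9)
        reg = out.registry.set_index("tag_code")
        d = out.detections.join(reg[["sex"]], on="tag_code")
        south = next(p for p in cfg.schedule if p.name == "south_migration")
        t = d["time"].dt.tz_localize(None)
        window = d[(t >= south.start) & (t < south.end)]
        assert (window["sex"] == "F").sum() == 0
        assert (window["sex"] == "M").sum() > 0  # males still around

    def test_detections_respect_active_intervals(self, scaled_sim):
        _, out = scaled_sim
        reg = out.registry.set_index("tag_code")
        d = out.detections.join(reg[["active_from", "active_to"]], on="tag_code")
        t = d["time"].dt.tz_localize(None)
        assert (t >= d["active_from"]).all()
        assert (t < d["active_to"] + pd.Timedelta(days=1)).all()


class TestFixture:
    def test_round_trip_exact(self, tmp_path, scaled_sim):
        _, out = scaled_sim
        paths = simulate.write_fixture(out, tmp_path / "fx")
        back = simulate.read_fixture(tmp_path / "fx")
        got = back["detections"]
        assert len(got) == len(out.detections)
        expect_t = out.detections["time"].dt.floor("s").reset_index(drop=True)
        pd.testing.assert_series_equal(got["time"], expect_t, check_names=False)
        assert (got["tag_code"].to_numpy() == out.detections["tag_code"].to_numpy()).all()
        reg = back["registry"]
        pd.testing.assert_frame_equal(
            reg, out.registry, check_dtype=False, check_like=True
        )
        assert len(back["fixes"]) == len(out.fixes)

    def test_empty_output_writes_headers_only(self, tmp_path):
        cfg = small_population(species_counts={"Carcharias taurus": 1})
        pop = simulate.generate_population(cfg, seed=0)
        tracks = simulate.simulate_tracks(pop, one_phase(), seed=0)
        empty = simulate.SimulationOutput(
            detections=pd.DataFrame(columns=["focal_id", "time", "tag_code"]),
            registry=pop.iloc[0:0],
            fixes=pd.DataFrame(columns=["animal_id", "date", "lat", "lon", "source"]),
            tracks=tracks,
            rng_seed=0,
        )
        paths = simulate.write_fixture(empty, tmp_path / "fx")
        det = pd.read_csv(paths["detections"])
        assert len(det) == 0
        assert list(det.columns) == ["focal_id", "timestamp_iso8601_utc", "tag_code"]

    def test_fixture_checksums_deterministic(self, tmp_path):
        cfg = cfgmod.scaled_config(n_conspecific=8, n_heterospecific=4)
        sums = []
        for d in ("a", "b"):
            out = simulate.simulate(cfg, seed=77)
            paths = simulate.write_fixture(out, tmp_path / d)
            digest = hashlib.sha256()
            for name in sorted(paths):
                digest.update(paths[name].read_bytes())
            sums.append(digest.hexdigest())
        assert sums[0] == sums[1]

    def test_truth_groups_recover_schedule(self, tmp_path):
        cfg = cfgmod.scaled_config(n_conspecific=10, n_heterospecific=0)
        out = simulate.simulate(cfg, seed=4)
        truth = out.truth_groups()
        truth["hour"] = pd.to_datetime(truth["hour_iso"])
        consp = truth[truth["group_id"].str.startswith("m")]
        # group label constant within each mode, re-drawn across modes
        consp = consp.assign(mode=consp["group_id"].str.extract(r"m(\d+)g")[0].astype(int))
        bounds = consp.groupby("mode")["hour"].agg(["min", "max"])
        for (_, lo, hi), phase in zip(bounds.itertuples(), cfg.schedule):
            assert lo.tz_localize(None) == phase.start
            assert hi.tz_localize(None) == phase.end - pd.Timedelta(hours=1)
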