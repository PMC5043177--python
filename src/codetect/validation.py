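"""Validation experiments: statistical calibration and structure recovery.

These experiments answer two questions about the pipeline itself:

* Is the composition chi-square calibrated — does it reject a true null at
  its nominal rate?
* Do the community / association statistics recover the fission-fusion
  structure that the synthetic generator encodes as ground truth (fusion
  at the bottleneck, fission at dispersal, sexual segregation on the
  southward migration)?
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import associations, community, config as cfgmod, encounters, ingest, networks
from . import simulate

__all__ = [
    "chisq_type1_rates",
    "structure_recovery",
    "run_length_agreement",
]


def chisq_type1_rates(
    n_rep: int = 2000,
    n: int = 200,
    k: int = 5,
    n_sim: int = 999,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> dict[str, float]:
    """Type-I error of the composition test under a true uniform null.

    Draws ``n_rep`` multinomial(n, uniform-k) samples (expected count n/k
    per cell, well above the asymptotic-validity threshold) and reports
    the fraction of p-values <= alpha for the asymptotic and Monte Carlo
    methods.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    props = np.full(k, 1.0 / k)
    obs = rng.multinomial(n, props, size=n_rep)
    rej_asym = rej_mc = 0
    for row in obs:
        res_a = community.composition_chisq(row, props, monte_carlo=False)
        rej_asym += res_a.p_value <= alpha
        res_m = community.composition_chisq(
            row, props, monte_carlo=True, n_sim=n_sim, seed=rng
        )
        rej_mc += res_m.p_value <= alpha
    return {
        "asymptotic": rej_asym / n_rep,
        "monte_carlo": rej_mc / n_rep,
        "n_rep": n_rep,
    }


def _mode_months(cfg: cfgmod.SimulationConfig) -> dict[str, pd.Period]:
    """First calendar month of each scheduled mode."""
    return {ph.name: pd.Period(ph.start, freq="M") for ph in cfg.schedule}


def structure_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    n_sim: int = 2000,
) -> pd.DataFrame:
    """Run the pipeline statistics on ``n_seeds`` independent simulations.

    Uses the reduced-scale five-mode configuration with
    ``female_offshore_prob = 1`` during the south migration (complete
    sexual segregation, the generator's strongest contrast).  Per seed:

    * Shannon H (mean over focals) for the summering / bottleneck /
      dispersal months,
    * shared-node fraction of the conspecific network for bottleneck and
      dispersal months,
    * median dyadic cumulative hours within those months,
    * Monte Carlo chi-square p-value of the south-migration encountered
      sex ratio against the tagged population.
    """
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = cfgmod.scaled_config()
        for ph in cfg.schedule:
            if ph.name == "south_migration":
                ph.female_offshore_prob = 1.0
        out = simulate.simulate(cfg, seed=seed)
        clean = ingest.apply_exclusions(out.detections, out.registry)
        active = ingest.active_tag_counts(
            out.registry[~out.registry["is_focal"]],
            (cfg.population.study_start, cfg.population.study_end),
        )
        monthly = encounters.monthly_communities(clean, active)
        presence = encounters.bin_hours(clean)
        fs = cfg.population.focal_species
        months = _mode_months(cfg)
        focal_ids = tuple(out.registry.loc[out.registry["is_focal"], "animal_id"])

        def mean_shannon(month):
            hs = []
            for f in focal_ids:
                vecs = monthly.detection_day_vectors(f, fs)
                if month in vecs and len(vecs[month]):
                    hs.append(community.shannon_diversity(vecs[month]))
                else:
                    hs.append(0.0)
            return float(np.mean(hs))

        t = presence.table
        t = t[t["species"] == fs]
        t = t.assign(month=t["hour"].dt.tz_localize(None).dt.to_period("M"))

        def median_cum(month):
            sub = t[t["month"] == month].groupby(["focal_id", "animal_id"]).size()
            return float(sub.median()) if len(sub) else 0.0

        coenc = associations.co_encounters(clean, focal_ids, species=fs)
        nets = networks.build_monthly_networks(monthly, coenc, fs)
        shared = {
            n.month: n.shared_fraction for n in nets if n.stratum == "conspecific"
        }

        pop = out.registry[(out.registry["species"] == fs) & (~out.registry["is_focal"])]
        sex_props = pop["sex"].value_counts(normalize=True).reindex(["M", "F"])
        south = months["south_migration"]
        ind = monthly.individuals
        sub = ind[(ind["month"] == south) & (ind["species"] == fs)]
        obs = sub["sex"].value_counts().reindex(["M", "F"], fill_value=0)
        res = community.composition_chisq(
            obs, sex_props, monte_carlo=True, n_sim=n_sim, seed=seed
        )

        rows.append(
            {
                "seed": seed,
                "H_summering": mean_shannon(months["summering"]),
                "H_bottleneck": mean_shannon(months["bottleneck"]),
                "H_dispersal": mean_shannon(months["dispersal"]),
                "shared_bottleneck": shared.get(months["bottleneck"], np.nan),
                "shared_dispersal": shared.get(months["dispersal"], np.nan),
                "cum_bottleneck": median_cum(months["bottleneck"]),
                "cum_dispersal": median_cum(months["dispersal"]),
                "sexratio_p": res.p_value,
                "sexratio_n_female": int(obs["F"]),
            }
        )
    return pd.DataFrame(rows)


def _brute_force_runs(hours: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Quadratic run scanner, independent of the vectorised implementation."""
    s = set(int(h) for h in hours)
    events = []
    for h in sorted(s):
        if h - 1 in s:
            continue
        length = 0
        while h + length in s:
            length += 1
        if length >= min_len:
            events.append((h, length))
    return events


def run_length_agreement(
    n_cases: int = 1000, seed: int | None = None, min_event_hours: int = 2
) -> float:
    """Fraction of fuzzed presence vectors on which the consecutive-event
    finder agrees exactly with the brute-force scanner."""
    from .encounters import HourlyPresence

    rng = np.random.default_rng(seed)
    base = pd.Timestamp("2012-09-01T00:00:00Z")
    agree = 0
    for _ in range(n_cases):
        n = int(rng.integers(0, 40))
        hours = np.unique(rng.integers(0, 120, n))
        table = pd.DataFrame(
            {
                "focal_id": "ST1",
                "animal_id": "A",
                "hour": [base + pd.Timedelta(hours=int(h)) for h in hours],
                "species": "sp",
                "sex": "M",
                "fork_length_cm": 100.0,
            }
        )
        ev = associations.consecutive_events(
            HourlyPresence(table), min_event_hours=min_event_hours
        )
        got = [
            (int((row.start - base) / pd.Timedelta(hours=1)), int(row.length))
            for row in ev.itertuples(index=False)
        ]
        agree += got == _brute_force_runs(hours, min_event_hours)
    return agree / n_cases
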