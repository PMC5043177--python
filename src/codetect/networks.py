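"""Monthly co-detection network graphs and GraphML export.

One bipartite-style star graph per (calendar month, species stratum): the
focal transceiver carriers in the middle, the individuals they encountered
that month around them.  An individual heard by both focals is flagged
``shared`` (it sits in the figure's centre); edge weight is the
individual's detection-days that month, and the focal-focal edge carries
the month's co-encounter count.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .encounters import MonthlyCommunity
from .community import size_binning

__all__ = ["MonthlyNetwork", "build_monthly_networks", "export_graphml"]


@dataclass
class MonthlyNetwork:
    month: pd.Period
    stratum: str  # "conspecific" | "heterospecific"
    graph: nx.Graph

    @property
    def shared_fraction(self) -> float:
        """Fraction of non-focal nodes connected to both focals (NaN if none)."""
        g = self.graph
        animals = [n for n, d in g.nodes(data=True) if d.get("kind") == "animal"]
        if not animals:
            return float("nan")
        shared = sum(1 for n in animals if g.nodes[n].get("shared"))
        return shared / len(animals)


def build_monthly_networks(
    monthly: MonthlyCommunity,
    coencounters=None,
    focal_species: str | None = None,
) -> list[MonthlyNetwork]:
    """Build one network per month per species stratum.

    ``focal_species`` splits individuals into the conspecific stratum and
    everything else; when None a single "all" stratum is built.  The
    focal-focal edge (weight = that month's co-encounter count) is added
    when a :class:`~codetect.associations.CoEncounterSeries` is supplied.
    """
    ind = monthly.individuals
    if ind.empty:
        return []
    focal_ids = sorted(ind["focal_id"].unique())
    coenc_by_month = {}
    if coencounters is not None:
        focal_ids = sorted(set(focal_ids) | set(coencounters.focal_ids))
        coenc_by_month = coencounters.monthly.set_index("month")["count_total"].to_dict()

    nets = []
    for month, month_df in ind.groupby("month", observed=True):
        if focal_species is None:
            strata = {"all": month_df}
        else:
            strata = {
                "conspecific": month_df[month_df["species"] == focal_species],
                "heterospecific": month_df[month_df["species"] != focal_species],
            }
        for stratum, sub in strata.items():
            g = nx.Graph(month=str(month), stratum=stratum)
            for f in focal_ids:
                g.add_node(f, kind="focal", species=focal_species or "", shared=False)
            seen_by: dict[str, set] = {}
            for row in sub.itertuples(index=False):
                seen_by.setdefault(row.animal_id, set()).add(row.focal_id)
                if row.animal_id not in g:
                    try:
                        size_bin = size_binning(row.fork_length_cm)
                    except (ValueError, TypeError):
                        size_bin = ""
                    g.add_node(
                        row.animal_id,
                        kind="animal",
                        species=row.species,
                        sex=row.sex,
                        size_bin=size_bin,
                        shared=False,
                    )
                g.add_edge(row.focal_id, row.animal_id, weight=int(row.detection_days))
            for animal, focals in seen_by.items():
                g.nodes[animal]["shared"] = len(focals) > 1
            if stratum != "heterospecific" and len(focal_ids) == 2:
                w = int(coenc_by_month.get(month, 0))
                if w > 0:
                    g.add_edge(focal_ids[0], focal_ids[1], weight=w)
            nets.append(MonthlyNetwork(month=month, stratum=stratum, graph=g))
    return nets


def export_graphml(network: MonthlyNetwork | nx.Graph, path) -> None:
    """Write a network as GraphML (attributes round-trip exactly).

    GraphML cannot carry None; missing attribute values become "".
    """
    g = network.graph if isinstance(network, MonthlyNetwork) else network
    g = g.copy()
    for _, data in g.nodes(data=True):
        for k, v in data.items():
            if v is None:
                data[k] = ""
    nx.write_graphml(g, path)
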