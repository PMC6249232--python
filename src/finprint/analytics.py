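"""Sighting analytics: dolphin-date graphs, co-sighting depth preference,
sighting frequencies, and the right-tailed Wilcoxon rank-sum test.

Site fidelity is assessed by a "sighting frequency" descriptor: the number of
sightings of each individual within a depth stratum (shallower vs. deeper
than the 800 m isobath), normalised by the stratum's total sightings.  The
per-stratum frequency distributions are compared with a right-tailed
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from itertools import combinations
from math import comb, erfc, sqrt
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .catalogue import Catalogue, ValidationError

DEFAULT_DEPTH_SPLIT_M = 800.0


# --------------------------------------------------------------------------
# Dolphin-date bipartite graph
# --------------------------------------------------------------------------


@dataclass
class SightingGraph:
    """Bipartite undirected graph of dolphins and observation dates."""

    graph: nx.Graph

    @property
    def dolphin_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "dolphin"}

    @property
    def date_nodes(self) -> set[Date]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == "date"}

    @property
    def edges(self) -> set[tuple[str, Date]]:
        out = set()
        for u, v in self.graph.edges():
            if self.graph.nodes[u]["kind"] == "dolphin":
                out.add((u, v))
            else:
                out.add((v, u))
        return out

    def degree(self, node) -> int:
        return self.graph.degree(node)


def build_sighting_graph(catalogue: Catalogue) -> SightingGraph:
    """One node per distinct dolphin and per distinct observation date; an
    edge joins a dolphin to every date on which it was photographed."""
    g = nx.Graph()
    for e in catalogue.entries:
        g.add_node(e.dolphin_name, kind="dolphin")
        g.add_node(e.observation_date, kind="date")
        g.add_edge(e.dolphin_name, e.observation_date)
    return SightingGraph(graph=g)


def connected_components(graph: SightingGraph) -> list[SightingGraph]:
    """Maximal connected sub-graphs, largest first (ties by smallest node
    label representation for determinism)."""
    comps = [graph.graph.subgraph(c).copy() for c in nx.connected_components(graph.graph)]
    comps.sort(key=lambda g: (-g.number_of_nodes(), min(str(n) for n in g.nodes())))
    return [SightingGraph(graph=c) for c in comps]


# --------------------------------------------------------------------------
# Co-sighting / depth-preference graph
# --------------------------------------------------------------------------

DEPTH_SHALLOW_ONLY = "shallow_only"
DEPTH_DEEP_ONLY = "deep_only"
DEPTH_BOTH = "both"


@dataclass
class CoSightingGraph:
    """Dolphin-dolphin graph: edge weight = number of shared sighting dates;
    nodes carry a depth class from the strata of the dolphin's sightings."""

    graph: nx.Graph

    def depth_class(self, dolphin: str) -> str:
        return self.graph.nodes[dolphin]["depth_class"]

    def weight(self, a: str, b: str) -> int:
        return self.graph.edges[a, b]["weight"]

    def style(self, a: str, b: str) -> str:
        """Edge rendering rule: dashed iff the pair shared exactly one date."""
        return "dashed" if self.weight(a, b) == 1 else "solid"


def _stratum(depth_m: float, split: float) -> str:
    # equality goes to the deep stratum
    return "deep" if depth_m >= split else "shallow"


def build_co_sighting_graph(
    catalogue: Catalogue, depth_split_m: float = DEFAULT_DEPTH_SPLIT_M
) -> CoSightingGraph:
    """Build the depth-preference graph from the catalogue's sighting records.

    Two dolphins are linked iff they appear in sightings on at least one
    common date; the edge weight counts the shared dates.  A node's depth
    class is ``shallow_only``/``deep_only``/``both`` according to the strata
    (depth < split vs >= split) of all sightings that include the dolphin.
    """
    if not catalogue.sightings:
        raise ValidationError("catalogue carries no sighting records")
    g = nx.Graph()
    dates_by_dolphin: dict[str, set[Date]] = {}
    strata: dict[str, set[str]] = {}
    for s in catalogue.sightings:
        if s.depth_m is None:
            raise ValidationError(f"sighting {s.date}: missing depth")
        stratum = _stratum(s.depth_m, depth_split_m)
        for name in s.dolphins:
            dates_by_dolphin.setdefault(name, set()).add(s.date)
            strata.setdefault(name, set()).add(stratum)
    for name, seen in strata.items():
        if seen == {"shallow"}:
            cls = DEPTH_SHALLOW_ONLY
        elif seen == {"deep"}:
            cls = DEPTH_DEEP_ONLY
        else:
            cls = DEPTH_BOTH
        g.add_node(name, depth_class=cls)
    for a, b in combinations(sorted(dates_by_dolphin), 2):
        shared = dates_by_dolphin[a] & dates_by_dolphin[b]
        if shared:
            g.add_edge(a, b, weight=len(shared))
    return CoSightingGraph(graph=g)


# --------------------------------------------------------------------------
# Sighting frequency and the rank-sum comparison
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumFrequency:
    """Per-dolphin sighting frequency within one depth stratum."""

    dolphin_name: str
    stratum: str
    n_sightings: int
    frequency: float


def sighting_frequency(
    catalogue: Catalogue,
    stratum: str,
    depth_split_m: float = DEFAULT_DEPTH_SPLIT_M,
) -> list[StratumFrequency]:
    """Sighting frequency per dolphin: sightings of the dolphin in the
    stratum divided by the stratum's total sighting count.

    Only individuals sighted more than once overall (across both strata)
    are reported.  Raises on an empty stratum.
    """
    if stratum not in ("shallow", "deep"):
        raise ValueError("stratum must be 'shallow' or 'deep'")
    if not catalogue.sightings:
        raise ValidationError("catalogue carries no sighting records")
    in_stratum = [s for s in catalogue.sightings
                  if _stratum(s.depth_m, depth_split_m) == stratum]
    if not in_stratum:
        raise ValueError(f"no sightings in the {stratum} stratum")
    total_by_dolphin: dict[str, int] = {}
    for s in catalogue.sightings:
        for name in s.dolphins:
            total_by_dolphin[name] = total_by_dolphin.get(name, 0) + 1
    n_total = len(in_stratum)
    counts: dict[str, int] = {}
    for s in in_stratum:
        for name in s.dolphins:
            counts[name] = counts.get(name, 0) + 1
    return [
        StratumFrequency(dolphin_name=name, stratum=stratum,
                         n_sightings=n, frequency=n / n_total)
        for name, n in sorted(counts.items())
        if total_by_dolphin[name] > 1
    ]


def wilcoxon_rank_sum_right(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Right-tailed Wilcoxon rank-sum (Mann-Whitney) test of H1: values in
    ``x`` tend to be larger than values in ``y``.

    Returns ``(U, p)`` with U the Mann-Whitney statistic of ``x``.  The
    p-value is exact — P(rank sum >= observed) over all C(n_x+n_y, n_x)
    equally likely rank assignments — when the combined sample size is at
    most 12 and there are no ties; otherwise midranks are used with the
    normal approximation, tie-corrected variance and continuity correction.
    A fully tied sample (zero variance) returns p = 0.5 when the statistic
    sits at its null mean.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx_, ny_ = x.size, y.size
    n = nx_ + ny_
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:nx_].sum())
    u = w - nx_ * (nx_ + 1) / 2.0
    has_ties = np.unique(pooled).size < n

    if n <= 12 and not has_ties:
        count = sum(1 for subset in combinations(range(1, n + 1), nx_)
                    if sum(subset) >= w - 1e-9)
        return u, count / comb(n, nx_)

    mu = nx_ * ny_ / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum())) / (n * (n - 1))
    var = nx_ * ny_ / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        if u == mu:
            return u, 0.5
        return u, 0.0 if u > mu else 1.0
    z = (u - mu - 0.5) / sqrt(var)  # continuity-corrected, right tail
    p = 0.5 * erfc(z / sqrt(2.0))
    return u, p


# --------------------------------------------------------------------------
# Summary tables
# --------------------------------------------------------------------------


@dataclass
class SummaryTables:
    """Exact tallies of catalogue entries.

    ``recap``: images per dolphin per date (rows = dolphins, cols = dates);
    ``pie``: images per dolphin; ``dates_per_dolphin`` and
    ``dolphins_per_date``: the two marginals of the distinct (dolphin, date)
    incidence.
    """

    recap: pd.DataFrame
    pie: pd.Series
    dates_per_dolphin: pd.Series
    dolphins_per_date: pd.Series


def summary_statistics(catalogue: Catalogue) -> SummaryTables:
    if not catalogue.entries:
        empty = pd.DataFrame()
        s = pd.Series(dtype=int)
        return SummaryTables(recap=empty, pie=s.copy(),
                             dates_per_dolphin=s.copy(), dolphins_per_date=s.copy())
    df = pd.DataFrame(
        {
            "dolphin": [e.dolphin_name for e in catalogue.entries],
            "date": [e.observation_date for e in catalogue.entries],
        }
    )
    recap = df.pivot_table(index="dolphin", columns="date", aggfunc="size",
                           fill_value=0)
    pie = df.groupby("dolphin").size().sort_index()
    pairs = df.drop_duplicates()
    dates_per_dolphin = pairs.groupby("dolphin").size().sort_index()
    dolphins_per_date = pairs.groupby("date").size().sort_index()
    return SummaryTables(recap=recap, pie=pie,
                         dates_per_dolphin=dates_per_dolphin,
                         dolphins_per_date=dolphins_per_date)


def export_graph(graph: SightingGraph | CoSightingGraph, path, fmt: str = "edgelist") -> None:
    """Write a graph as an edge-list CSV or GraphML file."""
    g = graph.graph
    if fmt == "graphml":
        h = nx.relabel_nodes(g, {n: str(n) for n in g.nodes()})
        nx.write_graphml(h, path)
    elif fmt == "edgelist":
        rows = [{"source": str(u), "target": str(v),
                 **{k: v2 for k, v2 in d.items()}}
                for u, v, d in g.edges(data=True)]
        pd.DataFrame(rows, columns=["source", "target", "weight"]
                     if any("weight" in d for _, _, d in g.edges(data=True))
                     else ["source", "target"]).to_csv(path, index=False)
    else:
        raise ValueError("fmt must be 'edgelist' or 'graphml'")
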