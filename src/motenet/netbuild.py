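"""Per-camp weighted proximity networks from dyad-slot events.

Edge weights are *rates*: dyad-slot contact events divided by the dyadic
daytime co-presence exposure in hours, which corrects for individuals who
arrived late or left early. Nodes are restricted to individuals aged 12
years or older (younger children are neither reliable sensor wearers nor
full participants in the camp economy). For degree only, a sparsified
copy of the network is used in which an edge survives when its weight
strictly exceeds a fraction (default 1%) of the camp network's total
summed edge weight — in small camps almost everyone interacts with
everyone, so unthresholded degree is uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import MissingDataError
from .ingest import DEFAULT_WINDOW, dyad_overlap_hours

logger = logging.getLogger(__name__)

MIN_NODE_AGE = 12.0


@dataclass
class ContactMatrix:
    """Symmetric matrix of time-adjusted interaction rates for one camp."""

    ids: list[str]
    W: np.ndarray          # events per co-presence hour; zero diagonal
    camp_id: str

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.ids)
        assert self.W.shape == (n, n)

    def rate(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.W[i, j])


def build_contact_matrix(dyad_slots: pd.DataFrame, presence: pd.DataFrame,
                         roster: pd.DataFrame, camp: str,
                         window=DEFAULT_WINDOW) -> ContactMatrix:
    """Tally dyad-slot events into a rate matrix for one camp.

    ``W[i, j]`` is the number of contact events for the dyad divided by
    their daytime co-presence hours. Dyads with zero overlap get rate 0;
    if events exist for such a dyad a warning is logged (clock trouble or
    unrecorded presence). Events naming ids absent from the roster raise
    :class:`MissingDataError`.
    """
    members = roster.loc[roster["camp"] == camp, "id"].tolist()
    ids = sorted(members)
    known = set(ids)
    bad = sorted((set(dyad_slots["id_a"]) | set(dyad_slots["id_b"])) - known)
    if bad:
        raise MissingDataError(f"event ids not in roster for camp {camp}: {bad}")

    counts = (dyad_slots.groupby(["id_a", "id_b"]).size()
              if len(dyad_slots) else pd.Series(dtype=int))
    pres_by_id = {i: g for i, g in presence.groupby("individual")}
    empty = presence.iloc[0:0]
    n = len(ids)
    W = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = ids[a], ids[b]
            ev = int(counts.get((ia, ib), 0)) if len(counts) else 0
            hours = dyad_overlap_hours(pres_by_id.get(ia, empty),
                                       pres_by_id.get(ib, empty), window)
            if hours > 0:
                W[a, b] = W[b, a] = ev / hours
            elif ev > 0:
                logger.warning("camp %s dyad (%s, %s): %d events but zero "
                               "co-presence; rate set to 0", camp, ia, ib, ev)
    return ContactMatrix(ids=ids, W=W, camp_id=camp)


def matrix_from_counts(counts: pd.DataFrame, camp: str) -> ContactMatrix:
    """Build a rate matrix from a ``id_a,id_b,events,overlap_hours`` frame.

    Fast-path companion to :func:`build_contact_matrix` for inputs that
    already carry per-dyad totals (e.g. the simulator's sufficient-
    statistic output).
    """
    ids = sorted(set(counts["id_a"]) | set(counts["id_b"]))
    index = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    W = np.zeros((n, n))
    for r in counts.itertuples(index=False):
        if r.overlap_hours > 0:
            i, j = index[r.id_a], index[r.id_b]
            W[i, j] = W[j, i] = r.events / r.overlap_hours
        elif r.events > 0:
            logger.warning("camp %s dyad (%s, %s): events without overlap",
                           camp, r.id_a, r.id_b)
    return ContactMatrix(ids=ids, W=W, camp_id=camp)


def to_network(matrix: ContactMatrix, roster: pd.DataFrame) -> nx.Graph:
    """Turn a rate matrix into the camp's proximity graph.

    Nodes are camp members aged >= 12 (with ``age`` node attributes);
    edges carry strictly positive ``weight``. The graph may be
    disconnected or even edgeless.
    """
    ages = roster.set_index("id")["age"]
    G = nx.Graph(camp=matrix.camp_id)
    keep = [i for i in matrix.ids if ages.get(i, 0.0) >= MIN_NODE_AGE]
    G.add_nodes_from((i, {"age": float(ages[i])}) for i in keep)
    pos = {v: k for k, v in enumerate(matrix.ids)}
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            w = matrix.W[pos[keep[a]], pos[keep[b]]]
            if w > 0:
                G.add_edge(keep[a], keep[b], weight=float(w))
    return G


def threshold_for_degree(network: nx.Graph, fraction: float = 0.01,
                         mode: str = "camp_total") -> nx.Graph:
    """Sparsify a camp network for the degree measure only.

    ``camp_total`` (default): keep edges whose weight strictly exceeds
    ``fraction`` of the total summed edge weight of the camp network.
    ``ego``: keep edges exceeding that fraction of either endpoint's
    strength (an ego-relative reading of the same rule). All nodes are
    retained.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    H = nx.Graph(**network.graph)
    H.add_nodes_from(network.nodes(data=True))
    if mode == "camp_total":
        total = network.size(weight="weight")
        cut = fraction * total
        keep = [(u, v, d) for u, v, d in network.edges(data=True)
                if d["weight"] > cut]
    elif mode == "ego":
        strength = dict(network.degree(weight="weight"))
        keep = [(u, v, d) for u, v, d in network.edges(data=True)
                if d["weight"] > fraction * strength[u]
                or d["weight"] > fraction * strength[v]]
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    H.add_edges_from(keep)
    return H


# ---------------------------------------------------------------------------
# writers


def write_edgelist_csv(network: nx.Graph, path) -> None:
    rows = [{"id_a": min(u, v), "id_b": max(u, v), "weight": d["weight"]}
            for u, v, d in network.edges(data=True)]
    (pd.DataFrame(rows, columns=["id_a", "id_b", "weight"])
       .sort_values(["id_a", "id_b"])
       .to_csv(path, index=False, float_format="%.10g"))


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)


def write_matrix_csv(matrix: ContactMatrix, path) -> None:
    df = pd.DataFrame(matrix.W, index=matrix.ids, columns=matrix.ids)
    df.to_csv(path, float_format="%.10g")


def read_matrix_csv(path, camp: str) -> ContactMatrix:
    df = pd.read_csv(path, index_col=0)
    return ContactMatrix(ids=[str(c) for c in df.columns],
                         W=df.to_numpy(dtype=float), camp_id=camp)
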