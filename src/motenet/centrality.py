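"""Five centrality measures on weighted camp networks, standardized by camp.

Degree and strength are direct measures; eigenvector centrality,
betweenness and closeness are indirect (they depend on ties beyond the
focal node's own). Edge weights are interaction *rates* (affinities), so
geodesic measures convert weight w to a traversal cost d = 1/w: frequent
contact means a short social distance. Conventions:

- degree is computed on the sparsified (thresholded) network only; every
  other measure uses the full weighted network;
- eigenvector centrality is the leading eigenvector of the weighted
  adjacency on the largest connected component, max-normalized to 1,
  zero elsewhere;
- betweenness counts unordered pairs once, excludes endpoints, credits
  tied geodesics fractionally, and is left unnormalized;
- closeness(v) = 1 / sum of geodesic distances from v to the other nodes
  of its component; isolates get 0.

Camp z-standardization (sample SD, divisor n-1) follows, because raw
scores are not comparable across camps of different size and density.
Affine normalizations of the raw scores are therefore irrelevant
downstream.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConvergenceError, DegenerateDataError, MissingDataError
from .netbuild import threshold_for_degree

MEASURES = ("degree", "strength", "ec", "betweenness", "closeness")

_DIST = "_dist"


def _with_distances(network: nx.Graph, weighted: bool = True) -> nx.Graph:
    """Attach traversal costs d = 1/w (or 1 in unweighted mode)."""
    for _, _, d in network.edges(data=True):
        d[_DIST] = 1.0 / d["weight"] if weighted else 1.0
    return network


def degree(thresholded_network: nx.Graph, node) -> int:
    """Number of ties incident to ``node`` in the thresholded network."""
    if node not in thresholded_network:
        raise MissingDataError(f"node {node!r} not in network")
    return int(thresholded_network.degree(node))


def strength(network: nx.Graph, node) -> float:
    """Sum of tie weights incident to ``node`` (0 for isolates)."""
    if node not in network:
        raise MissingDataError(f"node {node!r} not in network")
    return float(network.degree(node, weight="weight"))


def eigenvector_centrality(network: nx.Graph, tol: float = 1e-10,
                           max_iter: int = 2000) -> dict:
    """Leading-eigenvector scores by power iteration, max-normalized.

    Computed on the weighted adjacency of the largest connected component
    (nodes elsewhere score 0); iteration stops when successive normalized
    iterates differ by less than ``tol`` in max-norm.

    Raises
    ------
    ConvergenceError
        If the residual still exceeds ``tol`` after ``max_iter`` sweeps.
    """
    if network.number_of_edges() == 0:
        raise DegenerateDataError("eigenvector centrality needs >= 1 edge")
    comp = max(nx.connected_components(network), key=len)
    nodes = sorted(comp)
    W = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    # positive diagonal shift: same leading eigenvector, but breaks the
    # +/-lambda oscillation of bipartite adjacencies
    shift = W.sum(axis=1).max()
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    residual = np.inf
    for _ in range(max_iter):
        y = W @ x + shift * x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise DegenerateDataError("adjacency annihilated the iterate")
        y /= norm
        residual = np.abs(y - x).max()
        x = y
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"power iteration residual {residual:.3e} > tol after {max_iter} its")
    x = x / x.max()
    scores = {n: 0.0 for n in network}
    scores.update(zip(nodes, x))
    return scores


def betweenness(network: nx.Graph, weighted: bool = True) -> dict:
    """Unnormalized weighted betweenness (geodesic costs d = 1/w)."""
    _with_distances(network, weighted)
    return {n: float(v) for n, v in nx.betweenness_centrality(
        network, weight=_DIST, normalized=False).items()}


def closeness(network: nx.Graph, weighted: bool = True) -> dict:
    """Inverse summed geodesic distance to reachable others; isolates 0."""
    _with_distances(network, weighted)
    out = {}
    for v in network:
        dists = nx.single_source_dijkstra_path_length(network, v, weight=_DIST)
        total = sum(d for u, d in dists.items() if u != v)
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def standardize_by_camp(values: pd.Series, camp_assignment: pd.Series
                        ) -> pd.Series:
    """z-score values within each camp (sample SD, divisor n-1).

    Raises
    ------
    DegenerateDataError
        For a singleton camp or a camp with zero variance, naming it.
    """
    values = values.astype(float)
    out = pd.Series(index=values.index, dtype=float)
    for camp, idx in camp_assignment.groupby(camp_assignment).groups.items():
        x = values.loc[idx]
        if len(x) < 2:
            raise DegenerateDataError(f"camp {camp!r} has a single member")
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateDataError(f"camp {camp!r} has zero variance")
        out.loc[idx] = (x - x.mean()) / sd
    return out


def centrality_table(networks: dict[str, nx.Graph],
                     degree_fraction: float = 0.01,
                     degree_mode: str = "camp_total",
                     weighted_geodesics: bool = True) -> pd.DataFrame:
    """Raw and camp-standardized centrality for every node of every camp.

    ``networks`` maps camp id to its full weighted proximity graph; the
    degree threshold is applied internally. Returns a tidy frame with
    columns ``id, camp, <measure>, z_<measure>`` for the five measures.
    """
    rows = []
    for camp, G in sorted(networks.items()):
        thr = threshold_for_degree(G, fraction=degree_fraction,
                                   mode=degree_mode)
        ec = (eigenvector_centrality(G) if G.number_of_edges()
              else {n: 0.0 for n in G})
        bet = betweenness(G, weighted_geodesics)
        clo = closeness(G, weighted_geodesics)
        for n in sorted(G.nodes):
            rows.append({"id": n, "camp": camp,
                         "degree": degree(thr, n),
                         "strength": strength(G, n),
                         "ec": ec[n], "betweenness": bet[n],
                         "closeness": clo[n]})
    table = pd.DataFrame(rows)
    for m in MEASURES:
        table[f"z_{m}"] = standardize_by_camp(table[m], table["camp"])
    return table


def write_centrality_csv(table: pd.DataFrame, path) -> None:
    """Write the tidy long form ``individual,camp,measure,raw,z``."""
    long = table.melt(id_vars=["id", "camp"], value_vars=list(MEASURES),
                      var_name="measure", value_name="raw")
    zs = table.melt(id_vars=["id", "camp"],
                    value_vars=[f"z_{m}" for m in MEASURES],
                    var_name="zm", value_name="z")
    long["z"] = zs["z"].to_numpy()
    (long.rename(columns={"id": "individual"})
         .sort_values(["camp", "individual", "measure"])
         .to_csv(path, index=False, float_format="%.10g"))
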