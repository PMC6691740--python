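"""Genus co-occurrence networks: construction, topology, keystones, modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from otukit.indicators import benjamini_hochberg
from otukit.normalize import AbundanceTable
from otukit.tables_io import ValidationError


class ParameterError(ValueError):
    pass


def select_network_taxa(
    genus_table: AbundanceTable,
    niches=None,
    scope: str = "overall",
    threshold: float = 0.0005,
) -> list[str]:
    """Genera passing the mean-relative-abundance filter for a network scope.

    ``scope="overall"`` keeps a genus iff its mean relative abundance over
    all samples is strictly above ``threshold``; a niche name restricts the
    mean to that niche's samples.
    """
    if not 0 < threshold < 1:
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold}")
    if genus_table.method != "relative":
        raise ValidationError("select_network_taxa expects a relative-abundance table")
    values = genus_table.values
    if scope == "overall":
        means = values.mean(axis=0)
    else:
        if niches is None:
            raise ValidationError("per-niche scope requires niche labels")
        mask = np.asarray(list(niches)) == scope
        if not mask.any():
            raise ValidationError(f"no samples in niche {scope!r}")
        means = values[mask].mean(axis=0)
    return [t for t, m in zip(genus_table.taxon_ids, means) if m > threshold]


def correlation_matrix(
    genus_table: AbundanceTable, taxa: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Spearman correlations (midranks, t-approximation p).

    Constant genera yield NaN correlations for their pairs; those pairs are
    never turned into edges downstream.
    """
    if taxa is None:
        taxa = list(genus_table.taxon_ids)
    idx = [genus_table.taxon_ids.index(t) for t in taxa]
    x = genus_table.values[:, idx]
    n = x.shape[0]
    if n < 4:
        raise ValidationError("need >= 4 samples for correlation")
    ranks = np.apply_along_axis(stats.rankdata, 0, x)
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (ranks - ranks.mean(axis=0)) / sd
        rho = z.T @ z / n
    rho[np.abs(rho) > 1] = np.sign(rho[np.abs(rho) > 1])
    constant = sd == 0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    return (
        pd.DataFrame(rho, index=taxa, columns=taxa),
        pd.DataFrame(p, index=taxa, columns=taxa),
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    rho_min: float = 0.6,
    p_max: float = 0.01,
    fdr: bool = True,
    absolute: bool = False,
    node_attrs: dict[str, dict] | None = None,
    drop_isolated: bool = True,
) -> nx.Graph:
    """Threshold a correlation matrix into an undirected co-occurrence graph.

    An edge (u, v) exists iff rho(u, v) > rho_min (|rho| with ``absolute``)
    and the (BH-adjusted when ``fdr``) p-value is below ``p_max``. Nodes
    with no surviving edge are dropped by default.
    """
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValidationError("rho and p matrices are not aligned")
    taxa = list(rho.index)
    m = len(taxa)
    iu = np.triu_indices(m, k=1)
    rho_flat = rho.to_numpy()[iu]
    p_flat = p.to_numpy()[iu]
    valid = ~np.isnan(rho_flat)
    q_flat = np.full(m * (m - 1) // 2, np.nan)
    if fdr:
        q_flat[valid] = benjamini_hochberg(p_flat[valid])
    else:
        q_flat[valid] = p_flat[valid]
    strength = np.abs(rho_flat) if absolute else rho_flat
    keep = valid & (strength > rho_min) & (q_flat < p_max)

    g = nx.Graph()
    g.add_nodes_from(taxa)
    for i, j, r, pv, qv in zip(iu[0][keep], iu[1][keep], rho_flat[keep], p_flat[keep],
                               q_flat[keep]):
        g.add_edge(taxa[i], taxa[j], rho=float(r), p=float(pv), q=float(qv))
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    if node_attrs:
        for attr, mapping in node_attrs.items():
            nx.set_node_attributes(g, {n: mapping[n] for n in g.nodes if n in mapping}, attr)
    return g


@dataclass
class NetworkTopology:
    """Whole-graph metrics plus per-node degree/betweenness/module."""

    n_nodes: int
    n_edges: int
    modularity: float
    clustering_coefficient: float
    transitivity: float
    average_path_length: float
    diameter: float
    average_degree: float
    giant_average_path_length: float
    giant_diameter: float
    degree: dict[str, int] = field(repr=False)
    betweenness: dict[str, float] = field(repr=False)
    modules: dict[str, int] = field(repr=False)

    def to_json_dict(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "edges": self.n_edges,
            "MD": self.modularity,
            "CC": self.clustering_coefficient,
            "APL": self.average_path_length,
            "ND": self.diameter,
            "AD": self.average_degree,
        }


def _connected_pair_paths(g: nx.Graph) -> tuple[float, float]:
    """(mean, max) shortest-path length over connected unordered pairs."""
    total = 0.0
    n_pairs = 0
    longest = 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for dist in dists.values():
                if dist > 0:
                    total += dist
                    n_pairs += 1
                    longest = max(longest, dist)
    if n_pairs == 0:
        return float("nan"), float("nan")
    return total / n_pairs, float(longest)


def louvain_partition(g: nx.Graph, seed: int = 0, restarts: int = 10) -> dict[str, int]:
    """Louvain communities, best of ``restarts`` by modularity; deterministic."""
    best_q = -np.inf
    best = None
    for r in range(restarts):
        comms = nx.community.louvain_communities(g, seed=seed + r)
        q = nx.community.modularity(g, comms)
        if q > best_q:
            best_q = q
            best = comms
    assert best is not None
    # stable module ids: order communities by (size desc, smallest label)
    ordered = sorted(best, key=lambda c: (-len(c), min(str(n) for n in c)))
    return {node: i for i, comm in enumerate(ordered) for node in comm}


def modularity_of(g: nx.Graph, partition: dict[str, int]) -> float:
    """Newman modularity Q of a labelled partition."""
    comms: dict[int, set] = {}
    for node, c in partition.items():
        comms.setdefault(c, set()).add(node)
    return float(nx.community.modularity(g, list(comms.values())))


def topology(g: nx.Graph, seed: int = 0) -> NetworkTopology:
    """All topology metrics of a co-occurrence network.

    CC is the mean of local clustering coefficients (degree < 2 counts 0);
    APL and the diameter average/maximize over connected unordered pairs of
    the whole graph, with giant-component-only variants also reported;
    betweenness is Brandes, undirected and unnormalized; modules come from
    Louvain and MD is the modularity of that partition.
    """
    if g.number_of_edges() == 0:
        raise ValidationError("topology undefined for an edgeless graph")
    n = g.number_of_nodes()
    apl, nd = _connected_pair_paths(g)
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    g_apl, g_nd = _connected_pair_paths(giant)
    partition = louvain_partition(g, seed=seed)
    return NetworkTopology(
        n_nodes=n,
        n_edges=g.number_of_edges(),
        modularity=modularity_of(g, partition),
        clustering_coefficient=float(nx.average_clustering(g)),
        transitivity=float(nx.transitivity(g)),
        average_path_length=apl,
        diameter=nd,
        average_degree=2.0 * g.number_of_edges() / n,
        giant_average_path_length=g_apl,
        giant_diameter=g_nd,
        degree=dict(g.degree()),
        betweenness=nx.betweenness_centrality(g, normalized=False),
        modules=partition,
    )


def keystones(topo: NetworkTopology, k: int = 3) -> pd.DataFrame:
    """Nodes ranked by betweenness centrality.

    Ties break by degree descending, then label ascending. Returns the top
    ``k`` rows (all nodes if k exceeds the node count).
    """
    rows = sorted(
        topo.betweenness,
        key=lambda node: (-topo.betweenness[node], -topo.degree[node], str(node)),
    )
    df = pd.DataFrame(
        {
            "genus": rows,
            "betweenness": [topo.betweenness[n] for n in rows],
            "degree": [topo.degree[n] for n in rows],
            "module": [topo.modules[n] for n in rows],
        }
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(k).set_index("genus")


def module_niche_preference(
    topo: NetworkTopology, genus_table: AbundanceTable, niches
) -> pd.DataFrame:
    """Per-module tally of the nodes' preferred niches.

    A node's preferred niche is the argmax over niches of its mean relative
    abundance; the module's majority niche is the most common preference
    (ties broken alphabetically).
    """
    labels = np.asarray(list(niches))
    levels = sorted(set(labels))
    col = {t: i for i, t in enumerate(genus_table.taxon_ids)}
    missing = [n for n in topo.modules if n not in col]
    if missing:
        raise ValidationError(f"nodes missing abundance profiles: {missing[:10]}")
    niche_means = {
        lv: genus_table.values[labels == lv].mean(axis=0) for lv in levels
    }
    records = []
    for node, module in topo.modules.items():
        prefs = {lv: niche_means[lv][col[node]] for lv in levels}
        records.append({"genus": node, "module": module,
                        "preferred_niche": max(sorted(prefs), key=lambda lv: prefs[lv])})
    df = pd.DataFrame(records)
    tallies = (
        df.groupby(["module", "preferred_niche"]).size().unstack(fill_value=0).sort_index()
    )
    tallies["module_size"] = tallies.sum(axis=1)
    tallies["majority_niche"] = tallies.drop(columns="module_size").idxmax(axis=1)
    return tallies
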