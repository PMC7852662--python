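"""Median-joining haplotype networks with a star-likeness summary.

The construction follows the classic scheme: an epsilon-relaxed minimum
spanning network over the variable-site matrix, iterative insertion of
median (Steiner) vectors derived from connected triplets whenever they
reduce connection cost, and a final cleanup that removes median vectors
not lying on any minimal path between observed haplotypes. Characters are
multistate DNA columns; ties are broken lexicographically by haplotype
string so the result is independent of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import networkx as nx
import pandas as pd

from .alignment import HaplotypeSet
from .errors import DegenerateOutputError

_MAX_MEDIAN_ROUNDS = 50


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _diff_sites(a: str, b: str, site_map: list[int]) -> list[int]:
    return [site_map[i] for i, (x, y) in enumerate(zip(a, b)) if x != y]


def _minimum_spanning_network(nodes: list[str], epsilon: int) -> list[tuple[str, str, int]]:
    """Edges (u, v, weight) with weight <= minimax-path distance + epsilon."""
    nodes = sorted(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    dist = {}
    for u, v in combinations(nodes, 2):
        d = _hamming(u, v)
        dist[(u, v)] = d
        g.add_edge(u, v, weight=d)
    mst = nx.minimum_spanning_tree(g, weight="weight")
    # minimax distance: largest edge on the (unique) MST path
    minimax = {}
    for src in nodes:
        seen = {src: 0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nb in mst.neighbors(cur):
                if nb not in seen:
                    seen[nb] = max(seen[cur], mst[cur][nb]["weight"])
                    stack.append(nb)
        for v, mm in seen.items():
            if src < v:
                minimax[(src, v)] = mm
    return [
        (u, v, d)
        for (u, v), d in sorted(dist.items())
        if d <= minimax[(u, v)] + epsilon
    ]


def _median(u: str, v: str, w: str) -> str:
    """Per-site majority consensus of a triplet; pivot (first argument)
    resolves three-way ties."""
    out = []
    for a, b, c in zip(u, v, w):
        if b == c:
            out.append(b)
        else:
            out.append(a)  # a==b, a==c, or all three distinct -> pivot state
    return "".join(out)


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # nodes keyed by full haplotype string
    epsilon: int
    variable_sites: list[int]  # original 0-based column indices

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["observed"]]


def build_mj_network(
    h: HaplotypeSet,
    epsilon: int = 0,
    groups: Mapping[str, str] | None = None,
) -> HaplotypeNetwork:
    """Median-joining network over the haplotypes of `h`.

    `groups` optionally maps sample ids to labels, recorded per node.
    """
    if h.H < 2:
        raise DegenerateOutputError("network needs at least 2 distinct haplotypes")
    if epsilon < 0 or int(epsilon) != epsilon:
        raise ValueError("epsilon must be a non-negative integer")
    L = len(h.haplotypes[0])
    var_sites = [
        j for j in range(L) if len({s[j] for s in h.haplotypes}) > 1
    ]
    reduced = {s[:]: "".join(s[j] for j in var_sites) for s in h.haplotypes}
    observed = sorted(reduced.values())
    nodes = list(observed)
    for _ in range(_MAX_MEDIAN_ROUNDS):
        edges = _minimum_spanning_network(nodes, epsilon)
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        for u, v, _d in edges:
            adj[u].add(v)
            adj[v].add(u)
        candidates: dict[str, int] = {}
        node_set = set(nodes)
        for u in sorted(adj):
            for v, w in combinations(sorted(adj[u]), 2):
                m = _median(u, v, w)
                if m in node_set:
                    continue
                cost = _hamming(m, u) + _hamming(m, v) + _hamming(m, w)
                if m not in candidates or cost < candidates[m]:
                    candidates[m] = cost
        if not candidates:
            break
        lam = min(candidates.values())
        new = sorted(m for m, c in candidates.items() if c <= lam + epsilon)
        nodes.extend(new)
    observed_set = set(observed)
    # cleanup: drop medians off every minimal observed-observed path, and
    # medians of degree < 3; rebuild until stable
    while True:
        edges = _minimum_spanning_network(nodes, epsilon)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from(edges)
        keep = set(observed)
        for s, t in combinations(sorted(observed_set), 2):
            for path in nx.all_shortest_paths(g, s, t, weight="weight"):
                keep.update(path)
        removable = [
            n
            for n in nodes
            if n not in observed_set and (n not in keep or g.degree(n) < 3)
        ]
        if not removable:
            break
        nodes = [n for n in nodes if n not in set(removable)]

    back = {red: full for full, red in reduced.items()}
    fill = h.haplotypes[0]

    def expand(red: str) -> str:
        if red in back:
            return back[red]
        full = list(fill)
        for i, j in enumerate(var_sites):
            full[j] = red[i]
        return "".join(full)

    mult = dict(zip(h.haplotypes, h.multiplicities))
    members = dict(zip(h.haplotypes, h.members))
    out = nx.Graph()
    for node in nodes:
        full = expand(node)
        is_obs = node in observed_set
        attrs = {
            "observed": is_obs,
            "multiplicity": mult.get(full, 0),
            "samples": ",".join(members.get(full, ())),
        }
        if groups is not None and is_obs:
            labels = sorted({groups[s] for s in members.get(full, ()) if s in groups})
            attrs["groups"] = ",".join(labels)
        out.add_node(full, **attrs)
    final_edges = _minimum_spanning_network(nodes, epsilon)
    for u, v, d in final_edges:
        sites = _diff_sites(u, v, var_sites)
        out.add_edge(expand(u), expand(v), weight=d,
                     sites=",".join(str(s + 1) for s in sites))
    return HaplotypeNetwork(graph=out, epsilon=int(epsilon), variable_sites=var_sites)


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_medians: int
    max_degree: int
    star_likeness: float
    modal_adjacency: float
    reticulations: int
    modal_haplotype: str
    hub_haplotype: str


def network_summary(net: HaplotypeNetwork) -> NetworkSummary:
    """Node/edge/median counts, max degree, star-likeness and reticulations.

    Star-likeness is the fraction of observed haplotypes at distance 1 from
    the star center, the node (observed or inferred median) with the most
    observed neighbours; in a rapid expansion the center is frequently an
    inferred ancestral vector rather than a sampled haplotype.
    `modal_adjacency` is the narrower score anchored on the modal (most
    frequent, ties lexicographic) observed haplotype itself.
    """
    g = net.graph
    obs = net.observed_nodes
    modal = min(obs, key=lambda n: (-g.nodes[n]["multiplicity"], n))
    others = [n for n in obs if n != modal]
    if others:
        modal_adj = sum(1 for n in others if g.has_edge(modal, n)) / len(others)
    else:
        modal_adj = 1.0

    def obs_neighbours(v: str) -> int:
        return sum(1 for nb in g.neighbors(v) if g.nodes[nb]["observed"])

    hub = min(sorted(g.nodes), key=lambda v: (-obs_neighbours(v), v))
    denom = len(obs) - (1 if g.nodes[hub]["observed"] else 0)
    star = obs_neighbours(hub) / denom if denom > 0 else 1.0
    return NetworkSummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_medians=len(net.median_nodes),
        max_degree=max(dict(g.degree).values()),
        star_likeness=star,
        modal_adjacency=modal_adj,
        reticulations=g.number_of_edges() - g.number_of_nodes()
        + nx.number_connected_components(g),
        modal_haplotype=modal,
        hub_haplotype=hub,
    )


def total_cost(net: HaplotypeNetwork) -> int:
    """Weight of a minimum spanning tree of the network (Steiner cost)."""
    mst = nx.minimum_spanning_tree(net.graph, weight="weight")
    return int(sum(d["weight"] for _u, _v, d in mst.edges(data=True)))


def write_graphml(net: HaplotypeNetwork, path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_edge_tsv(net: HaplotypeNetwork, path) -> None:
    rows = [
        {"from": u, "to": v, "mutations": d["weight"], "sites_1based": d["sites"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_nexus(net: HaplotypeNetwork, path) -> None:
    """NEXUS file with Taxa and a Network block (vertices + edges)."""
    g = net.graph
    names = {}
    obs_i = med_i = 0
    for node in sorted(g.nodes):
        if g.nodes[node]["observed"]:
            obs_i += 1
            names[node] = f"H{obs_i}"
        else:
            med_i += 1
            names[node] = f"mv{med_i}"
    lines = ["#NEXUS", "", "BEGIN Taxa;"]
    observed = [n for n in sorted(g.nodes) if g.nodes[n]["observed"]]
    lines.append(f"DIMENSIONS ntax={len(observed)};")
    lines.append("TAXLABELS")
    lines += [f"  {names[n]}" for n in observed]
    lines += [";", "END;", "", "BEGIN Network;"]
    lines.append(
        f"DIMENSIONS nvertices={g.number_of_nodes()} nedges={g.number_of_edges()};"
    )
    lines.append("VERTICES")
    for i, node in enumerate(sorted(g.nodes), start=1):
        d = g.nodes[node]
        kind = "observed" if d["observed"] else "median"
        lines.append(f"  {i} {names[node]} [kind={kind} frequency={d['multiplicity']}]")
    lines.append(";")
    index = {node: i for i, node in enumerate(sorted(g.nodes), start=1)}
    lines.append("EDGES")
    for j, (u, v, d) in enumerate(sorted(g.edges(data=True)), start=1):
        lines.append(f"  {j} {index[u]} {index[v]} [weight={d['weight']}]")
    lines += [";", "END;", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
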