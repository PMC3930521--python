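"""Median-joining haplotype networks and haplogroup detection.

The construction follows the Bandelt-Forster-Roehl procedure: an
epsilon-relaxed minimum spanning network over Hamming distances between
haplotypes (restricted to their variable sites), iteratively augmented with
quasi-median (Steiner) vectors for triplets of linked nodes whenever the
added vector shortens the network, with obsolete inferred vectors pruned at
each round. With epsilon = 0 and tree-like data the result collapses to the
minimum spanning tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import networkx as nx
import numpy as np

from benguela.mtdna_diversity import HaplotypeTable


@dataclass
class HaplotypeNetwork:
    """Graph over observed haplotypes and inferred median vectors.

    Nodes carry ``sequence``, ``observed`` (bool), ``frequency`` and, for
    observed haplotypes, per-site counts; edges carry ``steps`` (Hamming
    distance over the variable sites used for construction).
    """

    graph: nx.Graph
    epsilon: int
    variable_positions: tuple[int, ...]

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["observed"]]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["observed"]]

    def total_length(self) -> int:
        return int(sum(d["steps"] for _, _, d in self.graph.edges(data=True)))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _variable_positions(seqs: list[str]) -> list[int]:
    L = len(seqs[0])
    return [j for j in range(L) if len({s[j] for s in seqs}) > 1]


def _msn_edges(seqs: dict[str, str], epsilon: int) -> list[tuple[str, str, int]]:
    """Epsilon-relaxed minimum spanning network.

    An edge (a, b) belongs to the network iff its weight is within epsilon of
    the minimax (bottleneck) path weight between a and b, which for
    epsilon = 0 yields the union of all minimum spanning trees. MST ties are
    broken lexicographically for determinism.
    """
    names = sorted(seqs)
    g = nx.Graph()
    for a, b in combinations(names, 2):
        g.add_edge(a, b, weight=_hamming(seqs[a], seqs[b]))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    kept = []
    for a, b in combinations(names, 2):
        w = g[a][b]["weight"]
        path = nx.shortest_path(mst, a, b)
        bottleneck = max(
            mst[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
        )
        if w <= bottleneck + epsilon:
            kept.append((a, b, w))
    return kept


def _quasi_medians(u: str, v: str, w: str) -> list[str]:
    """Per-site majority consensus; sites with three distinct states expand
    into all three alternatives (quasi-median set)."""
    options = []
    for a, b, c in zip(u, v, w):
        states = [a, b, c]
        best = max(set(states), key=states.count)
        if states.count(best) >= 2:
            options.append((best,))
        else:
            options.append(tuple(sorted(set(states))))
    if int(np.prod([len(o) for o in options])) > 729:  # cap combinatorial blowup
        options = [(o[0],) for o in options]
    return ["".join(combo) for combo in product(*options)]


def mj_network(ht: HaplotypeTable, epsilon: int = 0, max_rounds: int = 20) -> HaplotypeNetwork:
    """Median-joining network over the observed haplotypes.

    Monomorphic columns are dropped before construction. Each round builds
    the epsilon-relaxed minimum spanning network, proposes quasi-medians for
    triplets with at least two linked pairs, adds the best
    (connection-cost-minimising) new vector only if it strictly shortens the
    network, and prunes inferred vectors that no longer help; rounds repeat
    to a fixed point.
    """
    if ht.n_haplotypes < 2:
        raise ValueError("network needs >= 2 haplotypes")
    positions = _variable_positions(list(ht.haplotypes))
    seqs = {hid: "".join(full[j] for j in positions) for hid, full in zip(ht.ids, ht.haplotypes)}
    freq = {hid: int(ht.counts.loc[hid].sum()) for hid in ht.ids}
    observed = set(ht.ids)
    median_count = 0

    def network_length(node_seqs: dict) -> int:
        return sum(w for _, _, w in _msn_edges(node_seqs, epsilon))

    current = dict(seqs)
    for _ in range(max_rounds):
        edges = _msn_edges(current, epsilon)
        adj: dict[str, set] = {n: set() for n in current}
        for a, b, _ in edges:
            adj[a].add(b)
            adj[b].add(a)
        base_len = sum(w for _, _, w in edges)
        existing = set(current.values())
        best: tuple[int, int, str] | None = None  # (new_length, cost, seq)
        for u, v, w in combinations(sorted(current), 3):
            linked = sum(1 for x, y in [(u, v), (u, w), (v, w)] if y in adj[x])
            if linked < 2:
                continue
            for med in _quasi_medians(current[u], current[v], current[w]):
                if med in existing:
                    continue
                cost = (
                    _hamming(med, current[u])
                    + _hamming(med, current[v])
                    + _hamming(med, current[w])
                )
                trial = dict(current)
                trial[f"__cand__"] = med
                new_len = network_length(trial)
                if new_len < base_len and (best is None or (new_len, cost, med) < best):
                    best = (new_len, cost, med)
        if best is None:
            break
        median_count += 1
        current[f"mv{median_count}"] = best[2]
        # prune medians that no longer shorten the network
        pruned = True
        while pruned:
            pruned = False
            cur_len = network_length(current)
            for name in [n for n in current if n not in observed]:
                without = {k: v for k, v in current.items() if k != name}
                if len(without) >= 2 and network_length(without) <= cur_len:
                    current = without
                    pruned = True
                    break

    edges = _msn_edges(current, epsilon)
    g = nx.Graph()
    for name, seq in current.items():
        g.add_node(
            name,
            sequence=seq,
            observed=name in observed,
            frequency=freq.get(name, 0),
        )
    for a, b, w in edges:
        g.add_edge(a, b, steps=w)
    return HaplotypeNetwork(g, epsilon, tuple(positions))


def haplogroups(net: HaplotypeNetwork, min_steps: int) -> tuple[list[set], int]:
    """Partition observed haplotypes by cutting long branches.

    Edges of ``min_steps`` or more are removed and the remaining connected
    components define the haplogroups (restricted to observed haplotypes).
    Also returns the largest removed bridge length between the resulting
    clusters (0 when nothing was cut).
    """
    if min_steps < 1:
        raise ValueError("min_steps must be >= 1")
    g = net.graph.copy()
    removed = [(a, b, d["steps"]) for a, b, d in g.edges(data=True) if d["steps"] >= min_steps]
    g.remove_edges_from([(a, b) for a, b, _ in removed])
    comps = []
    for comp in nx.connected_components(g):
        obs = {n for n in comp if net.graph.nodes[n]["observed"]}
        if obs:
            comps.append(obs)
    bridge = max((w for _, _, w in removed), default=0)
    return comps, int(bridge)


def min_intergroup_distance(ht: HaplotypeTable, group_a: list[str], group_b: list[str]) -> int:
    """Minimum Hamming distance between haplotypes of two sets (by id)."""
    idx = {hid: i for i, hid in enumerate(ht.ids)}
    return min(
        _hamming(ht.haplotypes[idx[a]], ht.haplotypes[idx[b]])
        for a in group_a
        for b in group_b
    )


def edge_list(net: HaplotypeNetwork) -> list[tuple[str, str, int]]:
    return [(a, b, d["steps"]) for a, b, d in net.graph.edges(data=True)]
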