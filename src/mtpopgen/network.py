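"""Median-joining haplotype networks.

Haplotypes are compared over the union of their segregating positions; the
distance between two haplotypes is the number of positions at which their
alleles differ. The minimum spanning network (MSN) is the union of all
minimum spanning trees — an edge (u, v) belongs to the MSN exactly when its
weight equals the minimax (bottleneck) path weight between u and v. The
median-joining construction of Bandelt et al. then repeatedly proposes, for
connected triplets of the MSN, the per-position majority (median) haplotype,
keeps medians that reduce the total network cost (within a tolerance
``epsilon``), and prunes median vectors that no longer help, until a
fixpoint is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .core import PopulationDataset, VariantProfile, collapse_haplotypes

MAX_HAPLOTYPES = 5000

Haplotype = frozenset  # of (position, base) pairs


def _distance(a: Haplotype, b: Haplotype) -> int:
    alle_a, alle_b = dict(a), dict(b)
    return sum(
        1 for pos in alle_a.keys() | alle_b.keys()
        if alle_a.get(pos) != alle_b.get(pos)
    )


def _hap_key(h: Haplotype) -> str:
    return "/".join(f"{p}{b}" for p, b in sorted(h)) or "."


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # nodes: haplotype keys; edge attr "weight" = mutations
    haplotypes: dict[str, Haplotype]
    counts: pd.DataFrame  # observed haplotypes x populations; medians absent
    median_nodes: set[str] = field(default_factory=set)

    @property
    def total_cost(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def is_median(self, key: str) -> bool:
        return key in self.median_nodes

    def node_table(self) -> pd.DataFrame:
        rows = []
        for key in self.graph.nodes:
            row = {"id": key, "type": "median" if key in self.median_nodes else "observed"}
            if key in self.counts.index:
                row.update(self.counts.loc[key].to_dict())
            else:
                row.update({c: 0 for c in self.counts.columns})
            rows.append(row)
        return pd.DataFrame(rows).set_index("id")

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"u": u, "v": v, "mutations": d["weight"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["u", "v", "mutations"])


def _msn_graph(haps: Mapping[str, Haplotype]) -> nx.Graph:
    """Union of all minimum spanning trees over the complete distance graph."""
    keys = sorted(haps)
    complete = nx.Graph()
    complete.add_nodes_from(keys)
    for u, v in combinations(keys, 2):
        complete.add_edge(u, v, weight=_distance(haps[u], haps[v]))
    if len(keys) == 1:
        return complete
    mst = nx.minimum_spanning_tree(complete, weight="weight")
    # bottleneck (minimax) weight between two nodes = max edge on their MST path
    msn = nx.Graph()
    msn.add_nodes_from(keys)
    for u, v, d in complete.edges(data=True):
        path = nx.shortest_path(mst, u, v)
        bottleneck = max(
            mst[a][b]["weight"] for a, b in zip(path, path[1:])
        )
        if d["weight"] == bottleneck:
            msn.add_edge(u, v, weight=d["weight"])
    return msn


def minimum_spanning_network(
    haplotypes: Mapping[str, Haplotype] | Sequence[Haplotype],
    counts: pd.DataFrame | None = None,
) -> HaplotypeNetwork:
    haps = _as_mapping(haplotypes)
    graph = _msn_graph(haps)
    if counts is None:
        counts = pd.DataFrame(
            {"all": {k: 1 for k in haps}}, dtype=int
        )
    return HaplotypeNetwork(graph, dict(haps), counts)


def _as_mapping(
    haplotypes: Mapping[str, Haplotype] | Sequence[Haplotype]
) -> dict[str, Haplotype]:
    if isinstance(haplotypes, Mapping):
        return {k: frozenset(v) for k, v in haplotypes.items()}
    out: dict[str, Haplotype] = {}
    for h in haplotypes:
        h = frozenset(h)
        out[_hap_key(h)] = h  # duplicates collapse on the key
    return out


def _median_vector(a: Haplotype, b: Haplotype, c: Haplotype) -> Haplotype:
    """Per-position majority over three haplotypes; a position's allele is
    the base carried by at least two of them, ties (three distinct derived
    bases) keep the ancestral/reference base."""
    da, db, dc = dict(a), dict(b), dict(c)
    median = set()
    for pos in da.keys() | db.keys() | dc.keys():
        alleles = [da.get(pos), db.get(pos), dc.get(pos)]
        for base in set(alleles):
            if base is not None and alleles.count(base) >= 2:
                median.add((pos, base))
                break
    return frozenset(median)


def _mst_cost(haps: Mapping[str, Haplotype]) -> float:
    keys = sorted(haps)
    if len(keys) < 2:
        return 0.0
    g = nx.Graph()
    for u, v in combinations(keys, 2):
        g.add_edge(u, v, weight=_distance(haps[u], haps[v]))
    return sum(
        d["weight"]
        for _, _, d in nx.minimum_spanning_edges(g, weight="weight", data=True)
    )


def median_joining(
    haplotypes: Mapping[str, Haplotype] | Sequence[Haplotype],
    counts: pd.DataFrame | None = None,
    epsilon: int = 0,
) -> HaplotypeNetwork:
    """Bandelt median-joining network.

    Iterates: build the MSN over the current haplotype set; for every
    connected triplet (two MSN edges sharing a node) propose the median
    vector; greedily add proposals that reduce the minimum-spanning cost
    (a cost increase up to ``epsilon`` is tolerated for proposals tied with
    the best); prune median vectors whose removal does not increase the
    cost; stop at a fixpoint. Deterministic: candidates are examined in
    lexicographic key order.
    """
    observed = _as_mapping(haplotypes)
    if len(observed) > MAX_HAPLOTYPES:
        raise ValueError(f"refusing to build a network over {len(observed)} haplotypes")
    current = dict(observed)
    medians: set[str] = set()
    for _ in range(200):  # fixpoint guard
        changed = False
        msn = _msn_graph(current)
        base_cost = _mst_cost(current)
        proposals: dict[str, Haplotype] = {}
        for v in sorted(msn.nodes):
            neigh = sorted(msn.neighbors(v))
            for u, w in combinations(neigh, 2):
                med = _median_vector(current[u], current[v], current[w])
                key = _hap_key(med)
                if key not in current:
                    proposals[key] = med
        for key in sorted(proposals):
            trial = dict(current)
            trial[key] = proposals[key]
            if _mst_cost(trial) <= base_cost - 1 + epsilon:
                current = trial
                medians.add(key)
                base_cost = _mst_cost(current)
                changed = True
        # prune medians that no longer reduce the cost
        for key in sorted(medians):
            trial = {k: v for k, v in current.items() if k != key}
            if _mst_cost(trial) <= _mst_cost(current):
                current = trial
                medians.discard(key)
                changed = True
        if not changed:
            break
    graph = _msn_graph(current)
    if counts is None:
        counts = pd.DataFrame({"all": {k: 1 for k in observed}}, dtype=int)
    return HaplotypeNetwork(graph, current, counts, medians)


def network_from_dataset(
    ds: PopulationDataset, epsilon: int = 0
) -> HaplotypeNetwork:
    """Median-joining network of a dataset's collapsed haplotypes with
    per-population counts."""
    counts = collapse_haplotypes(ds)
    haps: dict[str, Haplotype] = {}
    for prof in ds.profiles:
        haps.setdefault(prof.key(), frozenset(prof.variants))
    return median_joining(haps, counts=counts)


def write_gml(net: HaplotypeNetwork, path: str) -> None:
    g = net.graph.copy()
    for node in g.nodes:
        g.nodes[node]["kind"] = "median" if node in net.median_nodes else "observed"
    nx.write_gml(g, path)
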