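"""Bipartite bird-resource networks and node-importance statistics.

Three network kinds are supported: ``diet_animal`` (birds x animal prey
taxa, COI reads), ``diet_plant`` (birds x dietary plant genera, rbcL
reads) and ``nest_plant`` (birds x nest substrate species, nest counts).
Node importance is measured by degree and by the abundance-weighted mean
degree (wMD),

    wMD = (sum_i b * s_i) / (sum_i b),    i = 1..n incident edges,

where b is the focal node's absolute abundance (total reads, or total
nests for the nesting network) and s_i the abundance of link i. With b
constant across the sum the expression reduces algebraically to the mean
incident edge weight; it is nevertheless evaluated term by term so the
``partner_weighted`` variant — which substitutes the partner node's
abundance b_i for b — differs by a single symbol.
"""

from __future__ import annotations

import importlib.resources
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

from .ingest import (
    ARTIFICIAL,
    UNASSIGNED,
    UNIDENTIFIED,
    Lineage,
    NestRecord,
    OtuTable,
    SampleMeta,
)

logger = logging.getLogger(__name__)

NETWORK_KINDS = ("diet_animal", "diet_plant", "nest_plant")


@dataclass
class BipartiteNetwork:
    """Weighted bipartite graph between bird species and resource taxa.

    Node abundances are totals over all observations; edges carry the
    post-filter link abundances, so a node's abundance may exceed the sum
    of its incident edge weights.
    """

    kind: str
    bird_nodes: dict[str, float] = field(default_factory=dict)
    resource_nodes: dict[str, float] = field(default_factory=dict)
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise ValueError(f"unknown network kind {self.kind!r}")
        seen: set[tuple[str, str]] = set()
        for bird, resource, weight in self.edges:
            if bird not in self.bird_nodes:
                raise ValueError(f"edge endpoint {bird!r} not a bird node")
            if resource not in self.resource_nodes:
                raise ValueError(f"edge endpoint {resource!r} not a resource node")
            if weight <= 0:
                raise ValueError(f"edge ({bird}, {resource}) has non-positive weight")
            if (bird, resource) in seen:
                raise ValueError(f"duplicate edge ({bird}, {resource})")
            seen.add((bird, resource))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def incident(self, node: str) -> list[tuple[str, float]]:
        """(partner, weight) pairs for the edges touching ``node``."""
        if node in self.bird_nodes:
            return [(r, w) for b, r, w in self.edges if b == node]
        if node in self.resource_nodes:
            return [(b, w) for b, r, w in self.edges if r == node]
        raise KeyError(f"unknown node {node!r}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for name, abundance in self.bird_nodes.items():
            g.add_node(name, partition="bird", abundance=float(abundance))
        for name, abundance in self.resource_nodes.items():
            g.add_node(name, partition="resource", abundance=float(abundance))
        for bird, resource, weight in self.edges:
            g.add_edge(bird, resource, weight=float(weight))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, kind: str) -> "BipartiteNetwork":
        birds = {n: d["abundance"] for n, d in g.nodes(data=True) if d["partition"] == "bird"}
        resources = {
            n: d["abundance"] for n, d in g.nodes(data=True) if d["partition"] == "resource"
        }
        edges = []
        for u, v, d in g.edges(data=True):
            bird, resource = (u, v) if u in birds else (v, u)
            edges.append((bird, resource, float(d["weight"])))
        edges.sort()
        return cls(kind=kind, bird_nodes=birds, resource_nodes=resources, edges=edges)


@dataclass(frozen=True)
class NodeImportance:
    node: str
    degree: int
    wmd: float


class AnimalAggregation:
    """Maps an animal OTU lineage onto a resource-node label.

    The default scheme names the five dominant insect orders, keeps a few
    ecologically salient classes/phyla (Aves, Annelida, Arachnida, ...)
    and buckets the rest as "other ..." groups.
    """

    def __init__(self, config: Mapping) -> None:
        self._class_splits = config.get("class_splits", {})
        self._groups = list(config.get("groups", []))
        self._fallbacks = list(config.get("fallbacks", []))
        self._default = config.get("default", "other")

    @classmethod
    def default(cls) -> "AnimalAggregation":
        ref = importlib.resources.files("keystonenet.data") / "animal_aggregation.yml"
        return cls(yaml.safe_load(ref.read_text()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnimalAggregation":
        return cls(yaml.safe_load(Path(path).read_text()))

    def label(self, lineage: Lineage) -> str:
        cls_label = lineage.at("class")
        if cls_label in self._class_splits:
            split = self._class_splits[cls_label]
            order = lineage.at("order")
            return order if order in split.get("orders", []) else split["other"]
        for rule in self._groups + self._fallbacks:
            if lineage.at(rule["rank"]) == rule["name"]:
                return rule["label"]
        return self._default


def build_network(
    kind: str,
    samples: Sequence[SampleMeta] | None = None,
    otu: OtuTable | None = None,
    nests: Sequence[NestRecord] | None = None,
    resource_rank: str | None = None,
    edge_min: int | None = None,
    aggregation: AnimalAggregation | None = None,
    exclude_families: Sequence[str] = ("Hominidae",),
) -> BipartiteNetwork:
    """Accumulate and filter a bird-resource network.

    Diet kinds require host-assigned ``samples`` plus the matching marker
    ``otu`` table; edge weight is the sum of reads over all samples of a host
    species assigned to a resource taxon, and edges whose weight does not
    exceed ``edge_min`` (default 100) are removed. The nest kind counts nests
    per (bird, substrate) pair; nest counts live on a ~100-nest scale where a
    read-abundance threshold is meaningless, so its ``edge_min`` defaults
    to 0. Isolated nodes are dropped.
    """
    if kind not in NETWORK_KINDS:
        raise ValueError(f"unknown network kind {kind!r}")
    if kind == "nest_plant":
        if nests is None:
            raise ValueError("nest_plant networks require nest records")
        return _build_nest_network(nests, 0 if edge_min is None else edge_min)
    if samples is None or otu is None:
        raise ValueError(f"{kind} networks require samples and an OTU table")
    edge_min = 100 if edge_min is None else edge_min
    if resource_rank is None:
        resource_rank = "higher" if kind == "diet_animal" else "genus"

    assigned = [s for s in samples if s.host_species != UNASSIGNED]
    if not assigned:
        logger.warning("no host-assigned samples: returning an empty %s network", kind)
        return BipartiteNetwork(kind=kind)

    if resource_rank == "higher":
        agg = aggregation or AnimalAggregation.default()
        label_of = {o: agg.label(otu.lineages[o]) for o in otu.counts.index}
    elif resource_rank in ("genus", "species"):
        label_of = {o: otu.lineages[o].label_at(resource_rank) for o in otu.counts.index}
    else:
        raise ValueError(f"unknown resource rank {resource_rank!r}")

    excluded = set(exclude_families)
    keep_otus = [
        o
        for o in otu.counts.index
        if label_of[o] and otu.lineages[o].at("family") not in excluded
    ]
    host_of = {s.sample_id: s.host_species for s in assigned if s.sample_id in otu.counts.columns}
    if not keep_otus or not host_of:
        return BipartiteNetwork(kind=kind)
    counts = otu.counts.loc[keep_otus, list(host_of)]
    by_label = counts.groupby(pd.Index([label_of[o] for o in keep_otus])).sum()
    # label x host matrix: sum each host species' sample columns
    by_host = by_label.T.groupby(pd.Index([host_of[s] for s in by_label.columns])).sum().T

    bird_ab = {h: float(t) for h, t in by_host.sum(axis=0).items() if t > 0}
    resource_ab = {r: float(t) for r, t in by_host.sum(axis=1).items() if t > 0}
    edges = sorted(
        (str(host), str(label), float(w))
        for label, row in by_host.iterrows()
        for host, w in row.items()
        if w > edge_min
    )
    return _assemble(kind, bird_ab, resource_ab, edges)


def _build_nest_network(nests: Sequence[NestRecord], edge_min: int) -> BipartiteNetwork:
    counts: dict[tuple[str, str], float] = defaultdict(float)
    bird_ab: dict[str, float] = defaultdict(float)
    resource_ab: dict[str, float] = defaultdict(float)
    for n in nests:
        if n.bird_species == UNIDENTIFIED or n.substrate == ARTIFICIAL:
            continue
        counts[(n.bird_species, n.substrate)] += 1
        bird_ab[n.bird_species] += 1
        resource_ab[n.substrate] += 1
    edges = sorted((b, r, w) for (b, r), w in counts.items() if w > edge_min)
    return _assemble("nest_plant", dict(bird_ab), dict(resource_ab), edges)


def _assemble(kind, bird_ab, resource_ab, edges) -> BipartiteNetwork:
    connected_birds = {b for b, _, _ in edges}
    connected_resources = {r for _, r, _ in edges}
    dropped = (set(bird_ab) - connected_birds) | (set(resource_ab) - connected_resources)
    if dropped:
        logger.info("%s network: dropping %d isolated node(s)", kind, len(dropped))
    return BipartiteNetwork(
        kind=kind,
        bird_nodes={b: a for b, a in bird_ab.items() if b in connected_birds},
        resource_nodes={r: a for r, a in resource_ab.items() if r in connected_resources},
        edges=edges,
    )


def node_degree(net: BipartiteNetwork, node: str) -> int:
    """Number of post-filter edges incident to ``node``."""
    return len(net.incident(node))


def node_wmd(net: BipartiteNetwork, node: str, variant: str = "literal") -> float:
    """Abundance-weighted mean degree of ``node``.

    ``literal`` uses the focal node's own abundance b in every term of both
    sums; ``partner_weighted`` uses the partner node's abundance b_i instead.
    A degree-0 node yields 0 with a warning.
    """
    incident = net.incident(node)
    if not incident:
        logger.warning("wMD of isolated node %s defined as 0", node)
        return 0.0
    if variant == "literal":
        b = (net.bird_nodes.get(node) if node in net.bird_nodes else net.resource_nodes[node])
        numer = sum(b * s for _, s in incident)
        denom = sum(b for _ in incident)
    elif variant == "partner_weighted":
        all_nodes = {**net.bird_nodes, **net.resource_nodes}
        numer = sum(all_nodes[partner] * s for partner, s in incident)
        denom = sum(all_nodes[partner] for partner, _ in incident)
    else:
        raise ValueError(f"unknown wMD variant {variant!r}")
    return numer / denom


def node_importance(net: BipartiteNetwork, variant: str = "literal") -> list[NodeImportance]:
    """Degree and wMD for every resource node (unsorted)."""
    return [
        NodeImportance(node=r, degree=node_degree(net, r), wmd=node_wmd(net, r, variant))
        for r in net.resource_nodes
    ]


def rank_keystones(
    net: BipartiteNetwork,
    by: str = "wmd",
    variant: str = "literal",
    top_k: int = 10,
) -> list[NodeImportance]:
    """Rank resource nodes by importance.

    ``by="degree"`` / ``by="wmd"`` sort descending by that statistic, ties
    broken by the other statistic and then alphabetically; ``by="both"``
    returns the intersection of the top-``top_k`` sets of the two rankings,
    ordered by wMD rank.
    """
    if not net.resource_nodes:
        raise ValueError("cannot rank keystones of an empty network")
    stats = node_importance(net, variant=variant)
    by_degree = sorted(stats, key=lambda s: (-s.degree, -s.wmd, s.node))
    by_wmd = sorted(stats, key=lambda s: (-s.wmd, -s.degree, s.node))
    if by == "degree":
        return by_degree
    if by == "wmd":
        return by_wmd
    if by == "both":
        top_d = {s.node for s in by_degree[:top_k]}
        return [s for s in by_wmd[:top_k] if s.node in top_d]
    raise ValueError(f"unknown ranking statistic {by!r}")


def export_graph(net: BipartiteNetwork, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML (node partition/abundance, edge weight)
    or as a three-column weighted edge list TSV."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif format == "edge_tsv":
        with path.open("w") as fh:
            fh.write("bird\tresource\tweight\n")
            for bird, resource, weight in net.edges:
                fh.write(f"{bird}\t{resource}\t{weight:g}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_graphml(path: str | Path, kind: str) -> BipartiteNetwork:
    return BipartiteNetwork.from_networkx(nx.read_graphml(Path(path)), kind=kind)
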