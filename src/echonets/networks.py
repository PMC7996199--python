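"""User-level and community-level interaction networks.

For each topic and mechanism (retweet / comment) the user network has a
directed edge i -> j whenever user i retweeted (commented on) a post of
user j, weighted by the number of such interactions; self-interactions are
dropped.  Node attitudes come from the majority-vote aggregation of that
user's posts *in that mechanism*; users present only as targets are coded
agree if they authored an original rebuttal in the topic, unknown
otherwise.

Communities are detected by seeded Louvain modularity maximization on the
symmetrized weighted graph — topology only, blind to attitudes.  The
community network keeps only inter-community interactions, aggregated by
community pair.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .coding import aggregate_user_attitude
from .data_model import Attitude, Dataset, Kind
from .echo_metrics import community_attitude_score, heterogeneity

__all__ = [
    "InteractionNetwork",
    "CommunityStats",
    "CommunityPartition",
    "CommunityNetwork",
    "TopologyMetrics",
    "build_user_network",
    "detect_communities",
    "build_community_network",
    "topology_metrics",
]


@dataclass
class InteractionNetwork:
    """Directed weighted user graph for one topic x mechanism."""

    mechanism: Kind
    topic: str
    graph: nx.DiGraph  # node attr "attitude" (str), edge attr "weight" (int)


@dataclass
class CommunityStats:
    size: int
    counts: Counter  # Attitude -> member count
    attitude_score: Optional[float]
    heterogeneity: Optional[float]


@dataclass
class CommunityPartition:
    assignment: dict[str, int]  # user -> community id
    communities: dict[int, CommunityStats]

    def members(self, cid: int) -> list[str]:
        return [u for u, c in self.assignment.items() if c == cid]


@dataclass
class CommunityNetwork:
    """Inter-community interactions; nodes carry attitude_score and size."""

    mechanism: Kind
    topic: str
    graph: nx.DiGraph


@dataclass
class TopologyMetrics:
    """Standard summary metrics; None marks a metric undefined on the graph."""

    density: Optional[float]
    modularity: Optional[float]
    transitivity: Optional[float]
    reciprocity: Optional[float]

    def as_dict(self) -> dict:
        return {
            "density": self.density,
            "modularity": self.modularity,
            "transitivity": self.transitivity,
            "reciprocity": self.reciprocity,
        }


def build_user_network(
    dataset: Dataset, mechanism: Kind, topic: str
) -> InteractionNetwork:
    """Build the directed weighted interaction network for one topic."""
    mechanism = Kind(mechanism)
    if mechanism is Kind.ORIGINAL:
        raise ValueError("mechanism must be 'retweet' or 'comment'")
    available = dataset.topics
    if topic not in available:
        raise ValueError(
            f"topic {topic!r} not in dataset; available topics: {available}"
        )
    by_id = dataset.by_id
    posts_by_author: dict[str, list] = defaultdict(list)
    edges: Counter[tuple[str, str]] = Counter()
    original_authors: set[str] = set()
    for p in dataset.posts:
        if p.topic != topic:
            continue
        if p.kind is Kind.ORIGINAL:
            original_authors.add(p.author_id)
            continue
        if p.kind is not mechanism:
            continue
        posts_by_author[p.author_id].append(p)
        target = by_id[p.parent_post_id].author_id
        if target != p.author_id:  # self-interactions are dropped
            edges[(p.author_id, target)] += 1

    graph = nx.DiGraph(mechanism=mechanism.value, topic=topic)
    nodes = set(posts_by_author)
    for (u, v) in edges:
        nodes.add(u)
        nodes.add(v)
    for user in sorted(nodes):
        if user in posts_by_author:
            att = aggregate_user_attitude(posts_by_author[user]).attitude
        elif user in original_authors:
            att = Attitude.AGREE  # original rebuttal posters endorse their post
        else:
            att = Attitude.UNKNOWN
        graph.add_node(user, attitude=att.value)
    for (u, v), w in sorted(edges.items()):
        graph.add_edge(u, v, weight=int(w))
    return InteractionNetwork(mechanism=mechanism, topic=topic, graph=graph)


def _symmetrize(graph: nx.DiGraph) -> nx.Graph:
    und = nx.Graph()
    und.add_nodes_from(graph.nodes(data=True))
    for u, v, data in graph.edges(data=True):
        w = data.get("weight", 1)
        if und.has_edge(u, v):
            und[u][v]["weight"] += w
        else:
            und.add_edge(u, v, weight=w)
    return und


def detect_communities(
    network: InteractionNetwork,
    seed: int = 0,
    resolution: float = 1.0,
    score_denominator: str = "all",
) -> CommunityPartition:
    """Seeded Louvain partition on the symmetrized weighted graph.

    Topology-only: node attitudes play no part.  Community ids are
    assigned deterministically (decreasing size, then smallest member).
    """
    graph = network.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect communities in an empty network")
    und = _symmetrize(graph)
    comms = nx.community.louvain_communities(
        und, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    assignment: dict[str, int] = {}
    communities: dict[int, CommunityStats] = {}
    for cid, members in enumerate(comms):
        counts: Counter = Counter(
            {a: 0 for a in (Attitude.AGREE, Attitude.DISAGREE, Attitude.QUERY,
                            Attitude.UNKNOWN)}
        )
        for user in members:
            assignment[user] = cid
            counts[Attitude(graph.nodes[user]["attitude"])] += 1
        A, D = counts[Attitude.AGREE], counts[Attitude.DISAGREE]
        Q, U = counts[Attitude.QUERY], counts[Attitude.UNKNOWN]
        communities[cid] = CommunityStats(
            size=len(members),
            counts=counts,
            attitude_score=community_attitude_score(
                A, D, Q, U, denominator=score_denominator
            ),
            heterogeneity=heterogeneity(A, D),
        )
    return CommunityPartition(assignment=assignment, communities=communities)


def build_community_network(
    network: InteractionNetwork,
    partition: CommunityPartition,
    score_denominator: str = "all",
) -> CommunityNetwork:
    """Contract the user network to communities, dropping intra-community edges."""
    graph = network.graph
    missing = [u for u in graph.nodes if u not in partition.assignment]
    if missing:
        raise ValueError(
            "nodes without a community assignment: " + ", ".join(sorted(missing))
        )
    cgraph = nx.DiGraph(
        mechanism=network.mechanism.value, topic=network.topic
    )
    for cid, stats in partition.communities.items():
        A = stats.counts[Attitude.AGREE]
        D = stats.counts[Attitude.DISAGREE]
        Q = stats.counts[Attitude.QUERY]
        U = stats.counts[Attitude.UNKNOWN]
        score = community_attitude_score(A, D, Q, U, denominator=score_denominator)
        cgraph.add_node(
            cid,
            attitude_score=float(score) if score is not None else 0.0,
            size=stats.size,
        )
    for u, v, data in graph.edges(data=True):
        cu, cv = partition.assignment[u], partition.assignment[v]
        if cu == cv:
            continue
        w = data.get("weight", 1)
        if cgraph.has_edge(cu, cv):
            cgraph[cu][cv]["weight"] += w
        else:
            cgraph.add_edge(cu, cv, weight=w)
    return CommunityNetwork(
        mechanism=network.mechanism, topic=network.topic, graph=cgraph
    )


def topology_metrics(network, partition: Optional[CommunityPartition] = None) -> TopologyMetrics:
    """Density, modularity (needs a partition), transitivity, reciprocity.

    Degenerate cases are flagged as undefined (None), never reported as 0:
    density needs >= 2 nodes, reciprocity needs >= 1 edge, transitivity
    needs >= 1 connected triple, modularity needs a partition and edges.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    n = graph.number_of_nodes()
    m = graph.number_of_edges()

    density = nx.density(graph) if n >= 2 else None
    reciprocity = nx.overall_reciprocity(graph) if m >= 1 else None

    und_simple = nx.Graph(graph)  # unweighted projection for triple counting
    triples = sum(d * (d - 1) / 2 for _, d in und_simple.degree())
    transitivity = nx.transitivity(und_simple) if triples > 0 else None

    modularity = None
    if partition is not None and m >= 1:
        und = _symmetrize(graph)
        groups = defaultdict(set)
        for node, cid in partition.assignment.items():
            if node in und:
                groups[cid].add(node)
        modularity = nx.community.modularity(
            und, list(groups.values()), weight="weight"
        )
    return TopologyMetrics(
        density=density,
        modularity=modularity,
        transitivity=transitivity,
        reciprocity=reciprocity,
    )
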