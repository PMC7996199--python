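"""Echo-chamber quantification: edge homophily, heterogeneity, assortativity.

An interaction edge is *like-minded* when both endpoints hold the same
clear attitude (agree-agree or disagree-disagree), *cross-cutting* when
one end agrees and the other disagrees, and *unclear* when either end is
query or unknown.  Within a community holding A agree and D disagree
members, the heterogeneity index

    H = 1 - |A - D| / (A + D)

ranges linearly from 0 (one-sided) to 1 (perfectly balanced).  A community
with A agree, D disagree and Q + U unclear members has attitude score
(A - D) / (A + D + Q + U) in [-1, 1].  Inter-community homophily is
summarized by the assortativity coefficient r: the weighted Pearson
correlation of the attitude scores at the two ends of each directed
inter-community edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import Attitude, Dataset, Kind

if TYPE_CHECKING:  # pragma: no cover
    from .networks import CommunityNetwork, InteractionNetwork

__all__ = [
    "EDGE_TYPES",
    "classify_edge",
    "EdgeTypeSummary",
    "homophily_summary",
    "community_attitude_score",
    "heterogeneity",
    "attribute_assortativity",
    "EchoReport",
    "echo_report",
    "report_frame",
]

LIKE_MINDED = "like_minded"
CROSS_CUTTING = "cross_cutting"
UNCLEAR = "unclear"
EDGE_TYPES = (LIKE_MINDED, CROSS_CUTTING, UNCLEAR)

_CLEAR = {Attitude.AGREE, Attitude.DISAGREE}


def classify_edge(att_i: Attitude, att_j: Attitude) -> str:
    """Classify an interaction by the attitudes at its two ends (symmetric)."""
    a, b = Attitude(att_i), Attitude(att_j)
    if a not in _CLEAR or b not in _CLEAR:
        return UNCLEAR
    return LIKE_MINDED if a is b else CROSS_CUTTING


@dataclass(frozen=True)
class EdgeTypeSummary:
    """Edge weight accumulated per homophily class, with proportions."""

    weights: dict[str, float]
    total: float

    @property
    def defined(self) -> bool:
        return self.total > 0

    @property
    def proportions(self) -> Optional[dict[str, float]]:
        if not self.defined:
            return None
        return {k: w / self.total for k, w in self.weights.items()}

    def proportion(self, edge_type: str) -> Optional[float]:
        props = self.proportions
        return None if props is None else props[edge_type]


def homophily_summary(network: "InteractionNetwork") -> EdgeTypeSummary:
    """Accumulate each edge's weight into its homophily class."""
    graph = network.graph
    weights = {k: 0.0 for k in EDGE_TYPES}
    for u, v, data in graph.edges(data=True):
        et = classify_edge(graph.nodes[u]["attitude"], graph.nodes[v]["attitude"])
        weights[et] += data.get("weight", 1)
    return EdgeTypeSummary(weights=weights, total=sum(weights.values()))


def community_attitude_score(
    A: int, D: int, Q: int = 0, U: int = 0, denominator: str = "all"
) -> Optional[float]:
    """Mean member attitude score (A - D) / total, in [-1, 1].

    ``denominator="all"`` averages over every member (query/unknown score 0);
    ``"clear_only"`` uses (A - D)/(A + D) and is undefined (None) when no
    member holds a clear attitude.
    """
    for name, v in (("A", A), ("D", D), ("Q", Q), ("U", U)):
        if v < 0:
            raise ValueError(f"count {name} must be >= 0, got {v}")
    if denominator == "all":
        total = A + D + Q + U
        if total == 0:
            raise ValueError("empty community has no attitude score")
        return (A - D) / total
    if denominator == "clear_only":
        return None if A + D == 0 else (A - D) / (A + D)
    raise ValueError(f"denominator must be 'all' or 'clear_only', got {denominator!r}")


def heterogeneity(A: int, D: int) -> Optional[float]:
    """Balance of agree vs disagree members: H = 1 - |A - D|/(A + D).

    Undefined (None) when the community has no clear-attitude member.
    """
    if A < 0 or D < 0:
        raise ValueError(f"counts must be >= 0, got A={A}, D={D}")
    if A + D == 0:
        return None
    return 1.0 - abs(A - D) / (A + D)


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> Optional[float]:
    w = w / w.sum()
    mx, my = float(w @ x), float(w @ y)
    cov = float(w @ ((x - mx) * (y - my)))
    vx = float(w @ ((x - mx) ** 2))
    vy = float(w @ ((y - my) ** 2))
    if vx <= 0.0 or vy <= 0.0:
        return None
    return cov / np.sqrt(vx * vy)


def attribute_assortativity(
    network: "CommunityNetwork", mode: str = "directed"
) -> Optional[float]:
    """Assortativity r of node attitude scores over (weighted) edges.

    Weighted Pearson correlation of (source score, target score) across
    directed edges, each counted with its weight.  ``mode="undirected"``
    symmetrizes by also counting every edge reversed.  Undefined (None)
    when there are no edges or an endpoint-score sequence has zero
    variance.
    """
    if mode not in ("directed", "undirected"):
        raise ValueError(f"mode must be 'directed' or 'undirected', got {mode!r}")
    graph = network if isinstance(network, nx.Graph) else network.graph
    rows = [
        (
            graph.nodes[u]["attitude_score"],
            graph.nodes[v]["attitude_score"],
            data.get("weight", 1),
        )
        for u, v, data in graph.edges(data=True)
    ]
    if not rows:
        return None
    x = np.array([r[0] for r in rows], dtype=float)
    y = np.array([r[1] for r in rows], dtype=float)
    w = np.array([r[2] for r in rows], dtype=float)
    if mode == "undirected":
        x, y = np.concatenate([x, y]), np.concatenate([y, x])
        w = np.concatenate([w, w])
    return _weighted_pearson(x, y, w)


@dataclass
class EchoReport:
    """Full echo-chamber readout for one topic x mechanism network."""

    topic: str
    mechanism: Kind
    edge_summary: EdgeTypeSummary
    communities: pd.DataFrame  # columns: community, size, A, D, Q, U, score, H
    assortativity: Optional[float]
    user_topology: dict
    community_topology: dict
    n_posts: int

    @property
    def mean_heterogeneity(self) -> Optional[float]:
        vals = self.communities["H"].dropna()
        return None if vals.empty else float(vals.mean())


def echo_report(
    dataset: Dataset,
    mechanisms: tuple[Kind, ...] = (Kind.RETWEET, Kind.COMMENT),
    topics: Optional[list[str]] = None,
    seed: int = 0,
    resolution: float = 1.0,
    score_denominator: str = "all",
    assortativity_mode: str = "directed",
    export_dir: Optional[Path] = None,
) -> list[EchoReport]:
    """Run the full measurement chain for every topic x mechanism.

    Builds the user network, detects communities, contracts to the
    community network, and computes homophily, heterogeneity,
    assortativity and topology metrics.  Optionally exports GraphML.
    """
    from . import networks as _networks
    from .data_model import export_graphml

    if topics is None:
        topics = dataset.topics
    reports: list[EchoReport] = []
    for topic in topics:
        for mechanism in mechanisms:
            mechanism = Kind(mechanism)
            n_posts = sum(
                1
                for p in dataset.posts
                if p.topic == topic and p.kind is mechanism
            )
            net = _networks.build_user_network(dataset, mechanism, topic)
            if net.graph.number_of_nodes() == 0:
                continue
            partition = _networks.detect_communities(
                net, seed=seed, resolution=resolution
            )
            cnet = _networks.build_community_network(
                net, partition, score_denominator=score_denominator
            )
            rows = []
            for cid, stats in sorted(partition.communities.items()):
                rows.append(
                    {
                        "community": cid,
                        "size": stats.size,
                        "A": stats.counts[Attitude.AGREE],
                        "D": stats.counts[Attitude.DISAGREE],
                        "Q": stats.counts[Attitude.QUERY],
                        "U": stats.counts[Attitude.UNKNOWN],
                        "score": stats.attitude_score,
                        "H": stats.heterogeneity,
                    }
                )
            communities = pd.DataFrame(
                rows,
                columns=["community", "size", "A", "D", "Q", "U", "score", "H"],
            )
            report = EchoReport(
                topic=topic,
                mechanism=mechanism,
                edge_summary=homophily_summary(net),
                communities=communities,
                assortativity=attribute_assortativity(
                    cnet, mode=assortativity_mode
                ),
                user_topology=_networks.topology_metrics(
                    net, partition=partition
                ).as_dict(),
                community_topology=_networks.topology_metrics(cnet).as_dict(),
                n_posts=n_posts,
            )
            reports.append(report)
            if export_dir is not None:
                export_dir = Path(export_dir)
                export_dir.mkdir(parents=True, exist_ok=True)
                stem = f"{topic}_{mechanism.value}"
                export_graphml(net, export_dir / f"{stem}_users.graphml")
                if cnet.graph.number_of_nodes() > 0:
                    export_graphml(
                        cnet, export_dir / f"{stem}_communities.graphml"
                    )
    return reports


def _round(value: Optional[float], digits: int) -> Optional[float]:
    return None if value is None else round(value, digits)


def report_frame(reports: list[EchoReport], rounded: bool = True) -> pd.DataFrame:
    """Tabulate reports; display rounding is 1 d.p. on percentages, 3 on r/H."""
    rows = []
    for r in reports:
        props = r.edge_summary.proportions or {}
        row = {
            "topic": r.topic,
            "mechanism": r.mechanism.value,
            "n_posts": r.n_posts,
            "total_weight": r.edge_summary.total,
            "like_minded_weight": r.edge_summary.weights[LIKE_MINDED],
            "cross_cutting_weight": r.edge_summary.weights[CROSS_CUTTING],
            "unclear_weight": r.edge_summary.weights[UNCLEAR],
            "like_minded_pct": props.get(LIKE_MINDED, np.nan) * 100,
            "cross_cutting_pct": props.get(CROSS_CUTTING, np.nan) * 100,
            "unclear_pct": props.get(UNCLEAR, np.nan) * 100,
            "n_communities": len(r.communities),
            "mean_H": r.mean_heterogeneity,
            "assortativity": r.assortativity,
            "density": r.user_topology.get("density"),
            "modularity": r.user_topology.get("modularity"),
            "transitivity": r.user_topology.get("transitivity"),
            "reciprocity": r.user_topology.get("reciprocity"),
        }
        if rounded:
            for k in ("like_minded_pct", "cross_cutting_pct", "unclear_pct"):
                if not np.isnan(row[k]):
                    row[k] = round(row[k], 1)
            for k in ("mean_H", "assortativity", "modularity", "transitivity",
                      "reciprocity", "density"):
                row[k] = _round(row[k], 3)
        rows.append(row)
    return pd.DataFrame(rows)
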