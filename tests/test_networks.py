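import itertools

import networkx as nx
import numpy as np
import pytest

from echonets.data_model import Attitude, Dataset, Kind
from echonets.networks import (
    CommunityPartition,
    InteractionNetwork,
    build_community_network,
    build_user_network,
    detect_communities,
    topology_metrics,
)

from conftest import make_original, make_post


@pytest.fixture
def retweet_dataset():
    posts = [make_original(post_id="o1", author="op")]
    # i retweets op twice (via the original), j retweets i's retweet
    posts.append(make_post(post_id="r1", author="i", parent="o1"))
    posts.append(make_post(post_id="r2", author="i", parent="o1"))
    posts.append(make_post(post_id="r3", author="j", parent="r1",
                           attitude="disagree"))
    return Dataset(posts=posts)


class TestBuildUserNetwork:
    def test_repeat_interaction_accumulates_weight(self, retweet_dataset):
        net = build_user_network(retweet_dataset, Kind.RETWEET, "virus")
        assert net.graph["i"]["op"]["weight"] == 2
        assert net.graph["j"]["i"]["weight"] == 1

    def test_node_attitudes_aggregated_per_mechanism(self, retweet_dataset):
        net = build_user_network(retweet_dataset, Kind.RETWEET, "virus")
        assert net.graph.nodes["i"]["attitude"] == "agree"
        assert net.graph.nodes["j"]["attitude"] == "disagree"
        assert net.graph.nodes["op"]["attitude"] == "agree"  # original poster

    def test_reciprocal_comment_edges(self):
        posts = [
            make_original(post_id="o1", author="a"),
            make_post(post_id="c1", author="b", kind=Kind.COMMENT, parent="o1"),
            make_post(post_id="c2", author="a", kind=Kind.COMMENT, parent="c1"),
        ]
        net = build_user_network(Dataset(posts=posts), Kind.COMMENT, "virus")
        assert net.graph.has_edge("b", "a") and net.graph.has_edge("a", "b")

    def test_self_interactions_dropped(self):
        posts = [
            make_original(post_id="o1", author="a"),
            make_post(post_id="r1", author="a", parent="o1"),
        ]
        net = build_user_network(Dataset(posts=posts), Kind.RETWEET, "virus")
        assert net.graph.number_of_edges() == 0

    def test_edge_weight_conservation(self):
        """Total weight equals the number of mechanism posts with
        in-network, non-self targets."""
        rng = np.random.default_rng(3)
        posts = [make_original(post_id="o1", author="op")]
        ids = ["o1"]
        for i in range(60):
            parent = ids[int(rng.integers(len(ids)))]
            pid = f"r{i}"
            posts.append(make_post(post_id=pid, author=f"u{int(rng.integers(12))}",
                                   parent=parent))
            ids.append(pid)
        ds = Dataset(posts=posts)
        by_id = ds.by_id
        expected = sum(
            1 for p in ds.posts
            if p.kind is Kind.RETWEET
            and by_id[p.parent_post_id].author_id != p.author_id
        )
        net = build_user_network(ds, Kind.RETWEET, "virus")
        total = sum(w for _, _, w in net.graph.edges(data="weight"))
        assert total == expected

    def test_unknown_topic_lists_available(self, retweet_dataset):
        with pytest.raises(ValueError, match="virus"):
            build_user_network(retweet_dataset, Kind.RETWEET, "nope")


def _two_cliques_network():
    g = nx.DiGraph()
    for block, nodes in enumerate((list("abcde"), list("vwxyz"))):
        for u, v in itertools.permutations(nodes, 2):
            g.add_edge(u, v, weight=1)
    g.add_edge("a", "v", weight=1)  # single bridge
    for n in g.nodes:
        g.nodes[n]["attitude"] = "agree"
    return InteractionNetwork(Kind.RETWEET, "virus", g)


def _brute_force_best_bipartition(graph):
    """Max-modularity 2-partition by exhaustive enumeration."""
    und = nx.Graph()
    und.add_nodes_from(graph.nodes)
    for u, v, w in graph.edges(data="weight"):
        und.add_edge(u, v, weight=und.get_edge_data(u, v, {"weight": 0})["weight"] + w)
    nodes = sorted(und.nodes)
    best, best_q = None, -np.inf
    for mask in range(1, 2 ** (len(nodes) - 1)):
        part_a = {nodes[i] for i in range(len(nodes)) if mask >> i & 1}
        part_b = set(nodes) - part_a
        q = nx.community.modularity(und, [part_a, part_b], weight="weight")
        if q > best_q:
            best, best_q = (part_a, part_b), q
    return best, best_q


class TestDetectCommunities:
    def test_two_cliques_separate(self):
        net = _two_cliques_network()
        (part_a, part_b), _ = _brute_force_best_bipartition(net.graph)
        partition = detect_communities(net, seed=0)
        groups = {}
        for user, cid in partition.assignment.items():
            groups.setdefault(cid, set()).add(user)
        assert sorted(map(sorted, groups.values())) == sorted(
            map(sorted, (part_a, part_b))
        )

    def test_single_edge_graph_no_crash(self):
        g = nx.DiGraph()
        g.add_edge("a", "b", weight=1)
        g.nodes["a"]["attitude"] = "agree"
        g.nodes["b"]["attitude"] = "disagree"
        partition = detect_communities(InteractionNetwork(Kind.RETWEET, "t", g))
        assert set(partition.assignment) == {"a", "b"}

    def test_partition_blind_to_attitudes(self):
        net = _two_cliques_network()
        base = detect_communities(net, seed=5).assignment
        relabeled = _two_cliques_network()
        for i, n in enumerate(sorted(relabeled.graph.nodes)):
            relabeled.graph.nodes[n]["attitude"] = ["agree", "disagree", "query"][i % 3]
        assert detect_communities(relabeled, seed=5).assignment == base

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        g = nx.gnp_random_graph(40, 0.15, seed=4, directed=True)
        for n in g.nodes:
            g.nodes[n]["attitude"] = "agree"
        for u, v in g.edges:
            g[u][v]["weight"] = int(rng.integers(1, 4))
        net = InteractionNetwork(Kind.RETWEET, "t", g)
        a = detect_communities(net, seed=42)
        b = detect_communities(net, seed=42)
        assert a.assignment == b.assignment

    def test_beats_singleton_partition(self):
        net = _two_cliques_network()
        und = nx.Graph(net.graph)
        partition = detect_communities(net, seed=0)
        groups = {}
        for user, cid in partition.assignment.items():
            groups.setdefault(cid, set()).add(user)
        q = nx.community.modularity(und, list(groups.values()))
        q_singletons = nx.community.modularity(und, [{n} for n in und.nodes])
        assert q >= q_singletons

    def test_empty_network_is_an_error(self):
        net = InteractionNetwork(Kind.RETWEET, "t", nx.DiGraph())
        with pytest.raises(ValueError, match="empty"):
            detect_communities(net)


class TestCommunityNetwork:
    def test_single_community_yields_one_node_no_edges(self):
        g = nx.DiGraph()
        g.add_edge("a", "b", weight=2)
        for n, att in (("a", "agree"), ("b", "disagree")):
            g.nodes[n]["attitude"] = att
        net = InteractionNetwork(Kind.RETWEET, "t", g)
        part = CommunityPartition(
            assignment={"a": 0, "b": 0},
            communities=detect_communities(net).communities,
        )
        # force both into one community
        part = detect_communities(net, resolution=0.01)
        if len(part.communities) == 1:
            cnet = build_community_network(net, part)
            assert cnet.graph.number_of_nodes() == 1
            assert cnet.graph.number_of_edges() == 0

    def test_weight_conservation(self):
        net = _two_cliques_network()
        part = detect_communities(net, seed=0)
        cnet = build_community_network(net, part)
        user_total = sum(w for *_, w in net.graph.edges(data="weight"))
        intra = sum(
            w for u, v, w in net.graph.edges(data="weight")
            if part.assignment[u] == part.assignment[v]
        )
        cnet_total = sum(w for *_, w in cnet.graph.edges(data="weight"))
        assert cnet_total == user_total - intra

    def test_community_score_is_mean_member_score(self):
        g = nx.DiGraph()
        atts = {"a": "agree", "b": "agree", "c": "disagree", "d": "query"}
        for n, att in atts.items():
            g.add_node(n, attitude=att)
        g.add_edge("a", "b", weight=1)
        g.add_edge("c", "d", weight=1)
        net = InteractionNetwork(Kind.RETWEET, "t", g)
        part = detect_communities(net, seed=0)
        cnet = build_community_network(net, part)
        from echonets.coding import ATTITUDE_SCORES

        for cid, data in cnet.graph.nodes(data=True):
            members = [u for u, c in part.assignment.items() if c == cid]
            mean = np.mean(
                [ATTITUDE_SCORES[Attitude(atts[m])] for m in members]
            )
            assert data["attitude_score"] == pytest.approx(mean)

    def test_missing_assignment_is_an_error(self):
        g = nx.DiGraph()
        g.add_node("a", attitude="agree")
        g.add_node("b", attitude="agree")
        g.add_edge("a", "b", weight=1)
        net = InteractionNetwork(Kind.RETWEET, "t", g)
        part = detect_communities(net)
        part.assignment.pop("b")
        with pytest.raises(ValueError, match="b"):
            build_community_network(net, part)


def _oracle_topology(g: nx.DiGraph):
    n, m = g.number_of_nodes(), g.number_of_edges()
    density = m / (n * (n - 1)) if n >= 2 else None
    reciprocity = (
        sum(1 for u, v in g.edges if g.has_edge(v, u)) / m if m else None
    )
    und = nx.Graph(g)
    nodes = sorted(und.nodes)
    triangles = sum(
        1
        for a, b, c in itertools.combinations(nodes, 3)
        if und.has_edge(a, b) and und.has_edge(b, c) and und.has_edge(a, c)
    )
    triples = sum(
        1
        for a, b, c in itertools.permutations(nodes, 3)
        if a < c and und.has_edge(b, a) and und.has_edge(b, c)
    )
    transitivity = 3 * triangles / triples if triples else None
    return density, reciprocity, transitivity


class TestTopologyMetrics:
    def test_complete_triangle_digraph(self):
        g = nx.complete_graph(3, create_using=nx.DiGraph)
        m = topology_metrics(g)
        assert m.transitivity == pytest.approx(1.0)
        assert m.reciprocity == pytest.approx(1.0)
        assert m.density == pytest.approx(1.0)

    def test_inward_star_has_zero_reciprocity(self):
        g = nx.DiGraph()
        for leaf in "bcd":
            g.add_edge(leaf, "a", weight=1)
        assert topology_metrics(g).reciprocity == 0.0

    def test_degenerate_graphs_flagged_undefined(self):
        g = nx.DiGraph()
        g.add_nodes_from("ab")
        m = topology_metrics(g)
        assert m.reciprocity is None  # no edges
        assert m.transitivity is None  # no connected triples
        single = nx.DiGraph()
        single.add_node("a")
        assert topology_metrics(single).density is None

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_graphs_match_enumeration_oracle(self, seed):
        g = nx.gnp_random_graph(20, 0.15, seed=seed, directed=True)
        m = topology_metrics(g)
        density, reciprocity, transitivity = _oracle_topology(g)
        assert m.density == pytest.approx(density)
        assert m.reciprocity == pytest.approx(reciprocity)
        if transitivity is None:
            assert m.transitivity is None
        else:
            assert m.transitivity == pytest.approx(transitivity)

    def test_modularity_matches_hand_formula(self):
        net = _two_cliques_network()
        part = detect_communities(net, seed=0)
        m = topology_metrics(net, partition=part)
        # hand formula: Q = sum_c (in_c/2m - (tot_c/2m)^2) on symmetrized graph
        und = nx.Graph()
        for u, v, w in net.graph.edges(data="weight"):
            und.add_edge(u, v, weight=und.get_edge_data(u, v, {"weight": 0})["weight"] + w)
        two_m = sum(d for _, d in und.degree(weight="weight"))
        q = 0.0
        for cid in set(part.assignment.values()):
            members = {u for u, c in part.assignment.items() if c == cid}
            in_w = sum(
                w for u, v, w in und.edges(data="weight")
                if u in members and v in members
            )
            tot = sum(d for n, d in und.degree(weight="weight") if n in members)
            q += 2 * in_w / two_m - (tot / two_m) ** 2
        assert m.modularity == pytest.approx(q)
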