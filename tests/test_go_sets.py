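import io as stdio
import itertools
import math

import networkx as nx
import numpy as np
import pytest
from networkx.algorithms.community import modularity

import cactophil as cp
from cactophil import io as cio
from cactophil.go_sets import (
    GoGraph,
    GoSetPartition,
    edge_weights,
    enrich_sets,
    information_content,
    label_partition,
    louvain_partition,
    representation_metrics,
)
from cactophil.simulate import SimulationConfig, simulate_go_annotations


def toy_graph():
    """Root with two branches; 10 genes, 5 of them on term B."""
    dag = nx.DiGraph()
    for t, name in [("R", "root"), ("A", "alpha"), ("B", "beta"), ("B1", "beta-leaf")]:
        dag.add_node(t, name=name)
    dag.add_edge("A", "R")
    dag.add_edge("B", "R")
    dag.add_edge("B1", "B")
    ann = {}
    for i in range(10):
        terms = {"R"}
        if i < 5:
            terms |= {"B", "B1"}
        else:
            terms |= {"A"}
        ann[f"g{i}"] = terms
    return GoGraph(dag=dag, annotations=ann, root="R")


# ---------------------------------------------------------------------------
# information content & weights
# ---------------------------------------------------------------------------

def test_root_ic_is_zero():
    g = toy_graph()
    assert information_content(g, "R") == 0.0


def test_term_covering_half_the_genes_has_ic_ln2():
    g = toy_graph()
    assert information_content(g, "B") == pytest.approx(math.log(2))


def test_unknown_term_rejected():
    with pytest.raises(KeyError):
        information_content(toy_graph(), "nope")


def test_lin_weights():
    g = toy_graph()
    w = edge_weights(g)
    # root edge: IC(parent)=0 -> weight 0
    assert w["B"]["R"]["weight"] == 0.0
    # equal-IC parent and child -> weight 1
    assert w["B1"]["B"]["weight"] == pytest.approx(1.0)


def test_lin_weight_formula():
    # IC 1 and 3 -> 2*1/(1+3) = 0.5, on a constructed two-term chain
    dag = nx.DiGraph()
    dag.add_edge("c", "p")
    dag.add_edge("p", "r")
    ann = {f"g{i}": {"r"} for i in range(100)}
    for i in range(math.ceil(100 / math.e)):
        ann[f"g{i}"] |= {"p"}          # IC(p) ~ 1
    for i in range(math.ceil(100 / math.e**3)):
        ann[f"g{i}"] |= {"c"}          # IC(c) ~ 3
    g = GoGraph(dag=dag, annotations=ann, root="r")
    w = edge_weights(g)
    icp = information_content(g, "p")
    icc = information_content(g, "c")
    assert w["c"]["p"]["weight"] == pytest.approx(2 * icp / (icp + icc))


def test_cyclic_ontology_rejected():
    dag = nx.DiGraph([("a", "b"), ("b", "a")])
    with pytest.raises(ValueError, match="cycle"):
        GoGraph(dag=dag, annotations={}, root="a")


# ---------------------------------------------------------------------------
# Louvain partitions
# ---------------------------------------------------------------------------

def _clique_graph(sizes, bridges=()):
    g = nx.Graph()
    offset = 0
    blocks = []
    for s in sizes:
        nodes = [f"n{offset + i}" for i in range(s)]
        for a, b in itertools.combinations(nodes, 2):
            g.add_edge(a, b, weight=1.0)
        blocks.append(nodes)
        offset += s
    for a, b in bridges:
        g.add_edge(a, b, weight=1.0)
    return g, blocks


def test_two_disconnected_cliques_give_two_sets():
    g, blocks = _clique_graph([4, 4])
    part = louvain_partition(g, seed=0, subsets=False)
    assert sorted(map(sorted, part.sets.values())) == sorted(map(sorted, blocks))


def test_partition_beats_singletons_and_matches_exhaustive_optimum():
    """On an 8-node two-clique graph the seeded Louvain run attains the
    global modularity optimum found by exhaustive partition search."""
    g, blocks = _clique_graph([4, 4], bridges=[("n0", "n4")])
    part = louvain_partition(g, seed=0, subsets=False)
    got = modularity(g, [set(s) for s in part.sets.values()], weight="weight")

    nodes = sorted(g.nodes)
    best = -1.0
    # enumerate all set partitions of 8 nodes (Bell(8) = 4140)
    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for smaller in partitions(rest):
            for i in range(len(smaller)):
                yield smaller[:i] + [smaller[i] | {head}] + smaller[i + 1:]
            yield smaller + [{head}]

    for p in partitions(nodes):
        q = modularity(g, p, weight="weight")
        if q > best:
            best = q
    assert got == pytest.approx(best, abs=1e-12)
    singletons = modularity(g, [{n} for n in nodes], weight="weight")
    assert got >= singletons


def test_planted_two_block_graph_recovered():
    rng = np.random.default_rng(3)
    g = nx.Graph()
    nodes = [f"n{i}" for i in range(30)]
    for i, j in itertools.combinations(range(30), 2):
        same = (i < 15) == (j < 15)
        p = 0.9 if same else 0.05
        if rng.random() < p:
            g.add_edge(nodes[i], nodes[j], weight=1.0)
    part = louvain_partition(g, seed=0, subsets=False)
    assert len(part.sets) == 2
    found = {frozenset(s) for s in part.sets.values()}
    assert found == {frozenset(nodes[:15]), frozenset(nodes[15:])}


def test_louvain_deterministic_under_seed():
    g, _ = _clique_graph([5, 5, 5], bridges=[("n0", "n5"), ("n5", "n10")])
    p1 = louvain_partition(g, seed=42)
    p2 = louvain_partition(g, seed=42)
    assert p1.sets == p2.sets and p1.subsets == p2.subsets


def test_empty_graph_rejected():
    with pytest.raises(ValueError, match="empty"):
        louvain_partition(nx.Graph())


def test_partition_validation_catches_overlap():
    part = GoSetPartition(sets={"s1": ["a", "b"], "s2": ["b"]})
    with pytest.raises(AssertionError, match="multiple sets"):
        part.validate(["a", "b"])


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def test_labels_use_dominant_term_and_tie_rule():
    g = toy_graph()
    part = GoSetPartition(sets={"s1": ["A", "B", "B1"]})
    label_partition(part, g)
    # A and B both cover 5 genes: tie broken to the smaller id, "A"
    assert part.set_labels["s1"] == "alpha"
    part2 = GoSetPartition(sets={"s1": ["B1"]})
    label_partition(part2, g)
    assert part2.set_labels["s1"] == "beta-leaf"


def test_label_empty_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        label_partition(GoSetPartition(sets={"s1": []}), toy_graph())


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def oracle_hypergeom_tail(k, N, K, n):
    """Direct summation of the hypergeometric upper tail P(X >= k)."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += (
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        )
    return total


def test_enrichment_p_matches_direct_summation():
    dag = nx.DiGraph([("t", "r")])
    ann = {f"g{i}": ({"r", "t"} if i < 20 else {"r"}) for i in range(100)}
    g = GoGraph(dag=dag, annotations=ann, root="r")
    part = GoSetPartition(sets={"s1": ["t"]})
    study = [f"g{i}" for i in range(8)] + ["g50", "g51"]  # k=8 of n=10
    res = enrich_sets(study, list(ann), part, g)
    assert res.iloc[0]["p"] == pytest.approx(
        oracle_hypergeom_tail(8, 100, 20, 10), rel=1e-12
    )


def test_study_equal_background_gives_p_one():
    dag = nx.DiGraph([("t", "r")])
    ann = {f"g{i}": {"r", "t"} for i in range(10)}
    g = GoGraph(dag=dag, annotations=ann, root="r")
    part = GoSetPartition(sets={"s1": ["t"], "s2": ["r"]})
    res = enrich_sets(list(ann), list(ann), part, g)
    assert (res["p"] == 1.0).all()


def test_enrichment_requires_study_subset():
    g = toy_graph()
    part = GoSetPartition(sets={"s1": ["B"]})
    with pytest.raises(ValueError, match="subset"):
        enrich_sets(["zz"], ["g0"], part, g)
    with pytest.raises(ValueError, match="empty"):
        enrich_sets([], ["g0"], part, g)


def test_planted_enrichment_is_top_hit():
    """The set holding the planted GO block is the most significant
    enrichment for the planted study list."""
    cfg = SimulationConfig(seed=17)
    obo, ann, truth = simulate_go_annotations(cfg)
    graph = cio.read_obo(stdio.StringIO(obo))
    g = GoGraph.from_obonet(graph, ann.groupby("gene_id")["go_id"].agg(set).to_dict())
    w = edge_weights(g)
    part = label_partition(louvain_partition(w, seed=0), g)
    part.validate(w.nodes)
    res = enrich_sets(truth["study_genes"], list(g.annotations), part, g)
    top = res.sort_values("p").iloc[0]
    planted = set(truth["planted_terms"])
    overlap = {
        sid: len(set(part.sets[sid]) & planted) / len(part.sets[sid])
        for sid in part.sets
    }
    assert overlap[top["set"]] > 0.9
    assert top["q"] < 0.05


def test_annotation_closure_counts_ancestors():
    cfg = SimulationConfig(seed=17)
    obo, ann, truth = simulate_go_annotations(cfg)
    graph = cio.read_obo(stdio.StringIO(obo))
    g = GoGraph.from_obonet(graph, ann.groupby("gene_id")["go_id"].agg(set).to_dict())
    # every annotated gene is counted at the root
    assert g.n_annotated(truth["root"]) == len(g.annotations)
    # and counts never increase towards the leaves
    for child, parent in g.dag.edges:
        assert g.n_annotated(child) <= g.n_annotated(parent)
        assert information_content(g, child) >= information_content(g, parent) - 1e-12


def test_single_term_ontology_gives_single_set():
    cfg = SimulationConfig(seed=17)
    cfg.go.n_terms = 1
    obo, ann, truth = simulate_go_annotations(cfg)
    graph = cio.read_obo(stdio.StringIO(obo))
    g = GoGraph.from_obonet(graph, ann.groupby("gene_id")["go_id"].agg(set).to_dict())
    part = louvain_partition(edge_weights(g), seed=0)
    assert len(part.sets) == 1


# ---------------------------------------------------------------------------
# representation metrics
# ---------------------------------------------------------------------------

def test_representation_filters_and_flags():
    subsets = {
        "small": {f"g{i}" for i in range(10)},           # exactly 10: excluded
        "mid": {f"g{i}" for i in range(100)},            # 6% involvement
        "big": {f"g{i}" for i in range(40)},
    }
    events = {"ev": {f"g{i}" for i in range(6)} | {"x"}}
    df = representation_metrics(subsets, events).set_index("subset")
    assert not df.loc["small", "analysed"]
    assert df.loc["mid", "pct_ev"] == pytest.approx(6.0)
    assert df.loc["mid", "display_percent"]
    assert not df.loc["mid", "display_absolute"]  # 6 <= 10 genes
    # events == subset -> 100%
    df2 = representation_metrics(
        {"s": {"a", "b"} | {f"g{i}" for i in range(20)}},
        {"ev": {"a", "b"} | {f"g{i}" for i in range(20)}},
    )
    assert df2.iloc[0]["pct_ev"] == pytest.approx(100.0)
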