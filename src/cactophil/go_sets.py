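"""GO-term set construction by Louvain clustering and set-level enrichment.

The ontology's is_a graph is weighted with semantic similarity between
parent and child (Lin similarity on annotation-based information content)
and partitioned into mutually exclusive sets by seeded Louvain community
detection; re-running Louvain inside each set yields nested subsets.  Sets
and subsets are labelled after their dominant (most broadly annotated)
member term.  Gene-list enrichment is hypergeometric per set with
Benjamini-Hochberg control across sets, and representation metrics report
how strongly each subset participates in an event gene list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from networkx.algorithms.community import louvain_communities
from scipy import stats

__all__ = [
    "GoGraph",
    "GoSetPartition",
    "information_content",
    "edge_weights",
    "louvain_partition",
    "label_partition",
    "enrich_sets",
    "representation_metrics",
]


@dataclass
class GoGraph:
    """Ontology DAG with ancestor-closed gene annotations.

    ``dag`` is a directed graph with child -> parent is_a edges; node
    attributes carry ``name`` and ``namespace``.
    """

    dag: nx.DiGraph
    annotations: dict[str, set[str]]       # gene -> closed term set
    root: str
    pseudo_count: float = 0.5

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("ontology graph contains a cycle")
        self._n_annotated = self._count_annotations()

    @classmethod
    def from_obonet(
        cls,
        graph: nx.MultiDiGraph,
        annotations: Mapping[str, Iterable[str]],
        namespace: str | None = None,
    ) -> "GoGraph":
        """Build from an ``obonet``-style graph (child -> parent edges with
        is_a keys) plus raw gene -> term annotations, which are closed over
        ancestors here."""
        dag = nx.DiGraph()
        for node, data in graph.nodes(data=True):
            ns = data.get("namespace")
            if namespace is not None and ns != namespace:
                continue
            dag.add_node(node, name=data.get("name", node), namespace=ns)
        for child, parent, key in graph.edges(keys=True):
            if key != "is_a":
                continue
            if child in dag and parent in dag:
                dag.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("ontology graph contains a cycle")
        roots = [n for n in dag if dag.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected a single root, found {roots}")
        closed = {}
        for gene, terms in annotations.items():
            full: set[str] = set()
            for t in terms:
                if t not in dag:
                    continue
                full.add(t)
                full.update(nx.descendants(dag, t))  # ancestors (edges point up)
            if full:
                closed[gene] = full
        return cls(dag=dag, annotations=closed, root=roots[0])

    def _count_annotations(self) -> dict[str, int]:
        counts = {t: 0 for t in self.dag}
        for terms in self.annotations.values():
            for t in terms:
                if t in counts:
                    counts[t] += 1
        return counts

    def n_annotated(self, term: str) -> int:
        """Genes annotated to the term or any descendant (annotations are
        ancestor-closed, so this is the term's own closed count)."""
        if term not in self.dag:
            raise KeyError(f"unknown term {term!r}")
        return self._n_annotated[term]

    def genes_of_terms(self, terms: Iterable[str]) -> set[str]:
        terms = set(terms)
        return {g for g, ts in self.annotations.items() if ts & terms}


def information_content(graph: GoGraph, term: str) -> float:
    """IC = -ln(n(term)/n(root)); zero-annotation terms use the configured
    pseudo-count."""
    n_root = graph.n_annotated(graph.root)
    if n_root == 0:
        return 0.0
    n = graph.n_annotated(term)
    if n == 0:
        n = graph.pseudo_count
    return max(0.0, -math.log(n / n_root))


def edge_weights(graph: GoGraph, measure: str = "lin") -> nx.Graph:
    """Undirected is_a graph with semantic-similarity edge weights.

    ``lin``: 2*IC(parent)/(IC(parent)+IC(child)) — the parent is the most
    informative common ancestor of a parent-child pair.  ``jaccard``:
    Jaccard index of the two terms' ancestor sets (incl. self).
    """
    g = nx.Graph()
    g.add_nodes_from(graph.dag.nodes)
    if measure == "lin":
        ic = {t: information_content(graph, t) for t in graph.dag}
        for child, parent in graph.dag.edges:
            denom = ic[parent] + ic[child]
            w = 2.0 * ic[parent] / denom if denom > 0 else 1.0
            g.add_edge(child, parent, weight=max(0.0, min(1.0, w)))
    elif measure == "jaccard":
        anc = {
            t: nx.descendants(graph.dag, t) | {t} for t in graph.dag
        }
        for child, parent in graph.dag.edges:
            inter = len(anc[child] & anc[parent])
            union = len(anc[child] | anc[parent])
            g.add_edge(child, parent, weight=inter / union if union else 0.0)
    else:
        raise ValueError(f"unknown similarity measure {measure!r}")
    return g


@dataclass
class GoSetPartition:
    """Mutually exclusive term sets with nested subsets and dominant-term
    labels."""

    sets: dict[str, list[str]]
    subsets: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    set_labels: dict[str, str] = field(default_factory=dict)
    subset_labels: dict[tuple[str, str], str] = field(default_factory=dict)

    def membership(self) -> dict[str, tuple[str, str | None]]:
        out: dict[str, tuple[str, str | None]] = {}
        for sid, terms in self.sets.items():
            subs = self.subsets.get(sid, {})
            sub_of = {t: ssid for ssid, ts in subs.items() for t in ts}
            for t in terms:
                out[t] = (sid, sub_of.get(t))
        return out

    def validate(self, universe: Iterable[str]) -> None:
        """Assert mutual exclusivity and coverage of the clustered terms."""
        seen: set[str] = set()
        for terms in self.sets.values():
            dup = seen & set(terms)
            if dup:
                raise AssertionError(f"terms in multiple sets: {sorted(dup)[:5]}")
            seen.update(terms)
        missing = set(universe) - seen
        if missing:
            raise AssertionError(f"terms not covered: {sorted(missing)[:5]}")
        for sid, subs in self.subsets.items():
            sub_seen: set[str] = set()
            for terms in subs.values():
                dup = sub_seen & set(terms)
                if dup:
                    raise AssertionError(f"terms in multiple subsets of {sid}")
                sub_seen.update(terms)
            if sub_seen != set(self.sets[sid]):
                raise AssertionError(f"subsets of {sid} do not cover the set")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term, (sid, ssid) in sorted(self.membership().items()):
            rows.append(
                {
                    "term": term,
                    "set": sid,
                    "subset": ssid,
                    "set_label": self.set_labels.get(sid),
                    "subset_label": self.subset_labels.get((sid, ssid)),
                }
            )
        return pd.DataFrame(rows)


def _communities(g: nx.Graph, resolution: float, seed: int) -> list[list[str]]:
    comms = louvain_communities(g, weight="weight", resolution=resolution, seed=seed)
    return sorted((sorted(c) for c in comms), key=lambda c: c[0])


def louvain_partition(
    weighted: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    subsets: bool = True,
) -> GoSetPartition:
    """Seeded Louvain partition of the weighted term graph into mutually
    exclusive sets; Louvain re-applied within each set gives its subsets."""
    if weighted.number_of_nodes() == 0:
        raise ValueError("empty term graph")
    sets = {
        f"set{idx:03d}": terms
        for idx, terms in enumerate(_communities(weighted, resolution, seed))
    }
    part = GoSetPartition(sets=sets)
    if subsets:
        for sid, terms in sets.items():
            sub = weighted.subgraph(terms)
            part.subsets[sid] = {
                f"{sid}.{j:03d}": ts
                for j, ts in enumerate(_communities(sub, resolution, seed))
            }
    return part


def label_partition(partition: GoSetPartition, graph: GoGraph) -> GoSetPartition:
    """Label every set and subset after its dominant term: the member with
    the greatest (closed) annotation count, ties to the smallest id."""

    def dominant(terms: Sequence[str]) -> str:
        if not terms:
            raise ValueError("cannot label an empty set")
        best = min(terms, key=lambda t: (-graph.n_annotated(t), t))
        return graph.dag.nodes[best].get("name", best)

    for sid, terms in partition.sets.items():
        partition.set_labels[sid] = dominant(terms)
    for sid, subs in partition.subsets.items():
        for ssid, terms in subs.items():
            partition.subset_labels[(sid, ssid)] = dominant(terms)
    return partition


def enrich_sets(
    study: Iterable[str],
    background: Iterable[str],
    partition: GoSetPartition,
    graph: GoGraph,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric set-level enrichment with BH control across sets.

    A gene counts towards a set when any of its (ancestor-closed) terms
    lies in the set.  Returns per set: k (study hits), K (background
    hits), n (study size), N (background size), p, q and significance at
    q < alpha.
    """
    study = set(study)
    background = set(background)
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        raise ValueError("study genes must be a subset of the background")
    N, n = len(background), len(study)
    rows = []
    for sid in sorted(partition.sets):
        genes = graph.genes_of_terms(partition.sets[sid])
        K = len(genes & background)
        k = len(genes & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"set": sid, "label": partition.set_labels.get(sid),
             "k": k, "K": K, "n": n, "N": N, "p": min(1.0, p)}
        )
    df = pd.DataFrame(rows)
    df["q"] = stats.false_discovery_control(df["p"], method="bh")
    df["significant"] = df["q"] < alpha
    return df


def representation_metrics(
    subset_genes: Mapping[str, set[str]],
    event_lists: Mapping[str, set[str]],
    min_subset_size: int = 10,
    display_n: int = 10,
    display_pct: float = 5.0,
) -> pd.DataFrame:
    """Absolute and percentage representation of each subset in each event
    gene list.

    Subsets of ``min_subset_size`` or fewer genes are excluded from the
    analysis (strictly more than the threshold are kept).  A subset is
    display-flagged when, in any analysis column, more than ``display_n``
    genes or more than ``display_pct`` percent of the subset are involved.
    """
    rows = []
    for ssid, genes in sorted(subset_genes.items()):
        size = len(genes)
        analysed = size > min_subset_size
        rec: dict = {"subset": ssid, "subset_size": size, "analysed": analysed}
        any_display_n = any_display_pct = False
        for name, events in sorted(event_lists.items()):
            nhit = len(genes & events)
            pct = 100.0 * nhit / size if size else 0.0
            rec[f"n_{name}"] = nhit
            rec[f"pct_{name}"] = pct
            any_display_n |= nhit > display_n
            any_display_pct |= pct > display_pct
        rec["display_absolute"] = analysed and any_display_n
        rec["display_percent"] = analysed and any_display_pct
        rows.append(rec)
    return pd.DataFrame(rows)
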