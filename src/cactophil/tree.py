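"""Species tree with named branches and silent-site branch lengths.

The tree is rooted; every branch is identified by the name of the node it
leads to (the species name for a terminal branch, the internal-node label
for an internal branch).  Branch lengths are silent-site divergences in
substitutions per 4-fold degenerate site.

The default topology is the cactophilic *Drosophila repleta* group study
system: five repleta-group species plus two outgroups placed as a basal
trichotomy, so that the stem branch of the repleta clade (the "ancestral
repleta" branch) is identifiable from pairwise distances.
"""

from __future__ import annotations

import io
import warnings
from typing import Iterable, Sequence

import dendropy

__all__ = ["SpeciesTree", "DEFAULT_TREE_NEWICK", "ROOT_BRANCH"]

#: Stem label returned for orthogroups spanning the whole tree.
ROOT_BRANCH = "root"

#: Default repleta-group study topology with silent-site branch lengths
#: (substitutions / 4-fold site).
DEFAULT_TREE_NEWICK = (
    "(D_melanogaster:0.35,D_virilis:0.30,"
    "(D_repleta:0.22,"
    "(D_hydei:0.20,"
    "(D_buzzatii:0.16,"
    "(D_aldrichi:0.10,D_mojavensis:0.12)mulleri_complex:0.05"
    ")cactus_specialisation:0.08"
    ")cactus_use:0.12"
    ")ancestral_repleta:0.25"
    ")root;"
)

#: Terminal branches of the repleta in-group (the species with inparalogue
#: and selection analyses in the study design).
REPLETA_SPECIES = (
    "D_repleta",
    "D_hydei",
    "D_buzzatii",
    "D_aldrichi",
    "D_mojavensis",
)


class SpeciesTree:
    """Rooted species tree with named internal branches.

    Thin wrapper around a :class:`dendropy.Tree` providing the branch-name
    bookkeeping the pipeline needs: branch -> silent length, branch ->
    descendant species, smallest-clade origin mapping, and leaf-to-leaf
    branch paths for least-squares branch-length fitting.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self._tree = tree
        self._name_nodes()
        self._nodes = {self.branch_name(n): n for n in tree.preorder_node_iter()}

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls(tree)

    @classmethod
    def default(cls) -> "SpeciesTree":
        return cls.from_newick(DEFAULT_TREE_NEWICK)

    def _name_nodes(self) -> None:
        # Unnamed internal nodes get deterministic preorder names.
        for i, node in enumerate(self._tree.preorder_node_iter()):
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("leaf without a name in species tree")
            elif not node.label:
                auto = ROOT_BRANCH if node.parent_node is None else f"node{i}"
                warnings.warn(
                    f"unnamed internal node auto-named {auto!r} (preorder index {i})"
                )
                node.label = auto

    # -- naming ---------------------------------------------------------
    @staticmethod
    def branch_name(node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    # -- basic queries ---------------------------------------------------
    @property
    def species(self) -> list[str]:
        return [t.label for t in self._tree.taxon_namespace]

    @property
    def root_name(self) -> str:
        return self.branch_name(self._tree.seed_node)

    @property
    def branch_lengths(self) -> dict[str, float]:
        """Branch name -> silent length for every non-root branch."""
        out: dict[str, float] = {}
        for name, node in self._nodes.items():
            if node.parent_node is not None:
                out[name] = float(node.edge.length or 0.0)
        return out

    @property
    def internal_branches(self) -> list[str]:
        return [
            n for n, node in self._nodes.items()
            if not node.is_leaf() and node.parent_node is not None
        ]

    @property
    def terminal_branches(self) -> list[str]:
        return [n for n, node in self._nodes.items() if node.is_leaf()]

    def descendant_species(self, branch: str) -> frozenset[str]:
        node = self._node(branch)
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def _node(self, branch: str) -> dendropy.Node:
        try:
            return self._nodes[branch]
        except KeyError:
            raise KeyError(f"unknown branch {branch!r}") from None

    # -- origin mapping --------------------------------------------------
    def origin_branch(self, species: Iterable[str]) -> str:
        """Stem branch of the smallest clade containing all given species.

        Single-origin (Dollo) rule: an orthogroup is assigned to the branch
        subtending the MRCA of its member species; a group spanning the
        whole tree maps to the root stem.
        """
        labels = sorted(set(species))
        known = set(self.species)
        unknown = set(labels) - known
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        if len(labels) == 1:
            return labels[0]
        mrca = self._tree.mrca(taxon_labels=labels)
        return self.branch_name(mrca)

    def branches_from_root(self, species: str) -> list[str]:
        """Branch names on the root-to-tip path (rootmost first)."""
        node = self._node(species)
        path = []
        while node.parent_node is not None:
            path.append(self.branch_name(node))
            node = node.parent_node
        return path[::-1]

    def path_branches(self, a: str, b: str) -> list[str]:
        """Branch names on the path between two leaves."""
        pa, pb = self.branches_from_root(a), self.branches_from_root(b)
        shared = 0
        while shared < min(len(pa), len(pb)) and pa[shared] == pb[shared]:
            shared += 1
        return pa[shared:] + pb[shared:]

    def with_branch_lengths(self, lengths: dict[str, float]) -> "SpeciesTree":
        """Copy of this tree with branch lengths replaced."""
        clone = SpeciesTree.from_newick(self.newick())
        for name, node in clone._nodes.items():
            if node.parent_node is not None:
                node.edge.length = float(lengths.get(name, 0.0))
        return clone

    # -- IO --------------------------------------------------------------
    def newick(self) -> str:
        buf = io.StringIO()
        self._tree.write(
            file=buf, schema="newick", unquoted_underscores=True,
            suppress_rooting=True,
        )
        return buf.getvalue().strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree({len(self.species)} species, root={self.root_name!r})"
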