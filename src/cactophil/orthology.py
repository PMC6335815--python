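"""Three-criterion orthologue / inparalogue / gene-birth classification.

A cross-species gene pair is accepted as orthologous when it is (1) a
reciprocal best-scoring hit, (2) supported by conserved synteny (a
neighbour of one gene has its own partner near the other gene), and, where
a species carries several candidate copies, (3) the copy whose distance
pattern to the other species mirrors its partner's (a symmetric sister
relationship read off the score table rather than a full gene tree).
Genes meeting only some applicable criteria are inparalogues (template =
best-scoring same-species orthogroup member); genes meeting none are gene
births.  Orthogroups are connected components of accepted pairs and are
mapped to their origin branch by the single-origin (Dollo) rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .tree import SpeciesTree

__all__ = [
    "OrthologyMap",
    "classify_orthology",
    "assign_origin_branch",
    "pairwise_event_overlap",
    "similarity_from_sequences",
]


@dataclass
class OrthologyMap:
    """Partition of all genes into orthogroup members, inparalogues and
    gene births (complete: the three categories cover every input gene)."""

    orthogroups: dict[str, dict[str, list[str]]]      # og_id -> species -> genes
    origin_branch: dict[str, str]                     # og_id -> branch
    inparalogues: dict[str, tuple[str, str | None]]   # gene -> (species, template)
    gene_births: list[str]
    orthologue_pairs: pd.DataFrame                    # gene_a, gene_b, score

    def category_of(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for og, by_sp in self.orthogroups.items():
            for genes in by_sp.values():
                for g in genes:
                    out[g] = "orthologue"
        for g in self.inparalogues:
            out[g] = "inparalogue"
        for g in self.gene_births:
            out[g] = "gene_birth"
        return out

    def orthogroup_of(self) -> dict[str, str]:
        out = {}
        for og, by_sp in self.orthogroups.items():
            for genes in by_sp.values():
                for g in genes:
                    out[g] = og
        return out

    def to_frame(self, species_of: dict[str, str]) -> pd.DataFrame:
        cat = self.category_of()
        og_of = self.orthogroup_of()
        template_og = {}
        rows = []
        for g, c in cat.items():
            og = og_of.get(g)
            template = self.inparalogues.get(g, (None, None))[1]
            rows.append(
                {
                    "gene_id": g,
                    "species": species_of.get(g),
                    "category": c,
                    "orthogroup_id": og if og else (og_of.get(template) if template else None),
                    "origin_branch": self.origin_branch.get(og) if og else None,
                    "template_id": template,
                }
            )
        return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)

    def counts_by_species(self, species_of: dict[str, str]) -> pd.DataFrame:
        """Per-species totals in the three categories (summary-table form)."""
        cat = self.category_of()
        rows: dict[str, dict[str, int]] = {}
        for g, c in cat.items():
            sp = species_of.get(g, "?")
            rows.setdefault(sp, {"orthologue": 0, "inparalogue": 0, "gene_birth": 0})
            rows[sp][c] += 1
        df = pd.DataFrame(rows).T.sort_index()
        df["total"] = df.sum(axis=1)
        return df


def similarity_from_sequences(seqs: dict[str, str]) -> pd.DataFrame:
    """Symmetric similarity edges (score = negative p-distance) for a set of
    equal-length sequences; a stand-in for BLAST-like scores on real data."""
    ids = sorted(seqs)
    arr = np.array([list(seqs[g]) for g in ids])
    rows = []
    for i, j in combinations(range(len(ids)), 2):
        p = float(np.mean(arr[i] != arr[j]))
        rows.append({"gene_a": ids[i], "gene_b": ids[j], "score": -p})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def _neighbours(order: dict[tuple[str, int], str], scaffold: str, idx: int,
                w: int) -> list[str]:
    out = []
    for d in range(1, w + 1):
        for j in (idx - d, idx + d):
            g = order.get((scaffold, j))
            if g is not None:
                out.append(g)
    return out


def classify_orthology(
    genes: pd.DataFrame,
    similarity: pd.DataFrame,
    tree: SpeciesTree,
    synteny_window: int = 5,
    min_synteny_support: int = 1,
    tie_margin: float = 0.0,
) -> OrthologyMap:
    """Classify every gene by the three-criterion rule.

    Parameters
    ----------
    genes
        Columns gene_id, species, scaffold, order_index.
    similarity
        Columns gene_a, gene_b, score (symmetric; higher = more similar).
    synteny_window
        w: neighbours examined on each side, and the positional window
        around the partner within which a neighbour's partner must fall.
    min_synteny_support
        How many of the <= 2w neighbours must have a partner in window.
    tie_margin
        Scores within this margin of the best count as tied candidates and
        trigger the symmetric-sister test (criterion 3).
    """
    species_of = dict(zip(genes["gene_id"], genes["species"]))
    coords = {
        g: (s, int(i))
        for g, s, i in zip(genes["gene_id"], genes["scaffold"], genes["order_index"])
    }
    at_coord = {(s, i): g for g, (s, i) in coords.items()}
    all_genes = list(genes["gene_id"])

    if similarity.empty:
        warnings.warn("empty similarity graph: all genes classified as births")
        return OrthologyMap({}, {}, {}, sorted(all_genes),
                            pd.DataFrame(columns=["gene_a", "gene_b", "score"]))

    # symmetric score lookup
    score: dict[str, dict[str, float]] = {}
    for a, b, s in zip(similarity["gene_a"], similarity["gene_b"], similarity["score"]):
        score.setdefault(a, {})[b] = float(s)
        score.setdefault(b, {})[a] = float(s)

    # best hit per gene per other species
    best_hit: dict[tuple[str, str], tuple[str, float]] = {}
    for g, hits in score.items():
        per_sp: dict[str, tuple[str, float]] = {}
        for h, s in hits.items():
            sp = species_of.get(h)
            if sp is None or sp == species_of.get(g):
                continue
            cur = per_sp.get(sp)
            if cur is None or s > cur[1] or (s == cur[1] and h < cur[0]):
                per_sp[sp] = (h, s)
        for sp, hit in per_sp.items():
            best_hit[(g, sp)] = hit

    def rbh(a: str, b: str) -> bool:
        ha = best_hit.get((a, species_of[b]))
        hb = best_hit.get((b, species_of[a]))
        return ha is not None and hb is not None and ha[0] == b and hb[0] == a

    rbh_pairs: set[tuple[str, str]] = set()
    for (g, sp), (h, s) in best_hit.items():
        if g < h and rbh(g, h):
            rbh_pairs.add((g, h))

    partner_in: dict[tuple[str, str], str] = {}
    for a, b in rbh_pairs:
        partner_in[(a, species_of[b])] = b
        partner_in[(b, species_of[a])] = a

    def synteny_ok(a: str, b: str) -> bool:
        support = 0
        for x, y in ((a, b), (b, a)):
            sx, ix = coords[x]
            sy, iy = coords[y]
            for nb in _neighbours(at_coord, sx, ix, synteny_window):
                p = partner_in.get((nb, species_of[y]))
                if p is None:
                    continue
                ps, pi = coords[p]
                if ps == sy and abs(pi - iy) <= synteny_window:
                    support += 1
                    if support >= min_synteny_support:
                        return True
        return support >= min_synteny_support

    def sister_symmetric(a: str, b: str) -> bool:
        """Criterion 3: among same-species candidates tied with `a` for
        partner `b`, `a` must have the distance pattern to third species
        that best mirrors b's (ties broken towards `a` by score then id)."""
        sp_a, sp_b = species_of[a], species_of[b]
        s_best = score[b].get(a, -np.inf)
        cands = [
            g for g, s in score[b].items()
            if species_of.get(g) == sp_a and s >= s_best - tie_margin
        ]
        if len(cands) <= 1:
            return True
        others = [sp for sp in set(species_of.values()) if sp not in (sp_a, sp_b)]

        def asymmetry(c: str) -> float:
            diffs = []
            for sp in others:
                hb = best_hit.get((b, sp))
                if hb is None:
                    continue
                o = hb[0]
                d_c = -score.get(c, {}).get(o, -np.inf)
                d_b = -score.get(b, {}).get(o, -np.inf)
                if np.isfinite(d_c) and np.isfinite(d_b):
                    diffs.append(abs(d_c - d_b))
            return float(np.mean(diffs)) if diffs else 0.0

        ranked = sorted(cands, key=lambda c: (asymmetry(c), -score[b].get(c, -np.inf), c))
        return ranked[0] == a

    accepted: list[tuple[str, str, float]] = []
    for a, b in sorted(rbh_pairs):
        if not synteny_ok(a, b):
            continue
        if not (sister_symmetric(a, b) and sister_symmetric(b, a)):
            continue
        accepted.append((a, b, score[a][b]))

    # connected components of accepted pairs = orthogroups
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for a, b, _ in accepted:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        union(a, b)

    comps: dict[str, list[str]] = {}
    for g in parent:
        comps.setdefault(find(g), []).append(g)

    # resolve components with multiple copies of one species: keep the
    # best-supported copy, demote the rest to inparalogues
    member_of: dict[str, str] = {}
    demoted: dict[str, tuple[str, str | None]] = {}
    orthogroups: dict[str, dict[str, list[str]]] = {}
    pair_score: dict[str, float] = {}
    for a, b, s in accepted:
        pair_score[a] = pair_score.get(a, 0.0) + s
        pair_score[b] = pair_score.get(b, 0.0) + s

    for n, root in enumerate(sorted(comps)):
        og_id = f"OG{n:05d}"
        members = sorted(comps[root])
        by_sp: dict[str, list[str]] = {}
        for g in members:
            by_sp.setdefault(species_of[g], []).append(g)
        kept: dict[str, list[str]] = {}
        for sp, gs in by_sp.items():
            if len(gs) == 1:
                kept[sp] = gs
            else:
                ranked = sorted(gs, key=lambda g: (-pair_score.get(g, 0.0), g))
                kept[sp] = [ranked[0]]
                for g in ranked[1:]:
                    demoted[g] = (sp, ranked[0])
        if len(kept) >= 2:
            orthogroups[og_id] = kept
            for sp, gs in kept.items():
                for g in gs:
                    member_of[g] = og_id
        else:
            # single-species remnant: everything becomes inparalogue/birth
            for sp, gs in kept.items():
                for g in gs:
                    demoted[g] = (sp, None)

    # remaining genes: inparalogue if a same-species orthogroup member is
    # their best same-species hit; otherwise gene birth
    inparalogues: dict[str, tuple[str, str | None]] = {}
    births: list[str] = []
    for g in all_genes:
        if g in member_of:
            continue
        sp = species_of[g]
        template = None
        best = -np.inf
        for h, s in score.get(g, {}).items():
            if species_of.get(h) == sp and h in member_of and s > best:
                best, template = s, h
        pre = demoted.get(g)
        if pre is not None and pre[1] is not None:
            inparalogues[g] = pre
        elif template is not None:
            inparalogues[g] = (sp, template)
        elif score.get(g):
            # similar to something, but no resolvable template
            inparalogues[g] = (sp, None)
        else:
            births.append(g)

    origin = {
        og: assign_origin_branch(by_sp, tree) for og, by_sp in orthogroups.items()
    }
    pairs = pd.DataFrame(
        [(a, b, s) for a, b, s in accepted
         if a in member_of and b in member_of and member_of[a] == member_of[b]],
        columns=["gene_a", "gene_b", "score"],
    )
    return OrthologyMap(orthogroups, origin, inparalogues, sorted(births), pairs)


def assign_origin_branch(
    orthogroup: dict[str, list[str]] | set[str], tree: SpeciesTree
) -> str:
    """Origin branch of an orthogroup: stem of the smallest clade containing
    every member species (single-origin rule)."""
    species = set(orthogroup) if not isinstance(orthogroup, dict) else set(orthogroup.keys())
    if len(species) < 2:
        raise ValueError("orthogroup must span at least two species")
    return tree.origin_branch(species)


def pairwise_event_overlap(
    event_sets: dict[str, set[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared-orthogroup counts and Jaccard indices between branch-wise
    event sets.  Diagonals carry the set sizes (counts) and 1.0 (Jaccard)."""
    keys = sorted(event_sets)
    n = len(keys)
    counts = np.zeros((n, n), dtype=int)
    jac = np.zeros((n, n))
    for i, a in enumerate(keys):
        counts[i, i] = len(event_sets[a])
        jac[i, i] = 1.0
        for j in range(i + 1, n):
            b = keys[j]
            inter = len(event_sets[a] & event_sets[b])
            uni = len(event_sets[a] | event_sets[b])
            counts[i, j] = counts[j, i] = inter
            jac[i, j] = jac[j, i] = inter / uni if uni else 0.0
    return (
        pd.DataFrame(counts, index=keys, columns=keys),
        pd.DataFrame(jac, index=keys, columns=keys),
    )
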