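"""Codon-level molecular-evolution statistics.

Silent divergence is measured on 4-fold degenerate third positions
(presumptively neutral sites), corrected for multiple hits with the
Jukes-Cantor formula, and branch lengths are fitted to the pairwise silent
distances by non-negative least squares on the fixed species topology.
Ka/Ks follows Nei & Gojobori (1986) with substitution pathways averaged and
pathways through stop codons excluded.  A 4-criterion orthogroup filter
selects slowly evolving single-copy groups for supermatrix phylogenomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import log
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy.optimize import nnls

from .tree import SpeciesTree

__all__ = [
    "CodonAlignment",
    "fourfold_degenerate_columns",
    "jc_silent_distance",
    "jc_correct",
    "ls_branch_lengths",
    "ng86_kaks",
    "filter_orthogroups_for_phylogeny",
    "export_supermatrix",
]

BASES = "ACGT"
_CODON_TABLE = standard_dna_table.forward_table
_STOPS = set(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, or None for a stop."""
    return _CODON_TABLE.get(codon)


def _fourfold_codons() -> frozenset[str]:
    """Codons whose third position is 4-fold degenerate (standard code)."""
    out = set()
    for c1 in BASES:
        for c2 in BASES:
            aas = {_CODON_TABLE.get(c1 + c2 + c3) for c3 in BASES}
            if None not in aas and len(aas) == 1:
                out.update(c1 + c2 + c3 for c3 in BASES)
    return frozenset(out)


FOURFOLD_CODONS = _fourfold_codons()


@dataclass
class CodonAlignment:
    """Gap-free equal-length codon alignment, one sequence per species."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("sequences differ in length")
        (length,) = lengths or {0}
        if length % 3:
            raise ValueError("alignment length not divisible by 3")
        for name, seq in self.sequences.items():
            bad = set(seq) - set(BASES)
            if bad:
                raise ValueError(f"{name}: non-ACGT characters {sorted(bad)}")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    def codon(self, name: str, i: int) -> str:
        return self.sequences[name][3 * i : 3 * i + 3]


def fourfold_degenerate_columns(aln: CodonAlignment) -> list[int]:
    """Third-position column indices that are 4-fold degenerate in *every*
    sequence (strict intersection across species).

    Raises on internal stop codons, naming the offending sequence and codon.
    """
    n = aln.n_codons
    cols: list[int] = []
    for i in range(n):
        fourfold = True
        for name in aln.sequences:
            codon = aln.codon(name, i)
            if codon in _STOPS and i < n - 1:
                raise ValueError(f"internal stop codon in {name} at codon {i}")
            if codon not in FOURFOLD_CODONS:
                fourfold = False
        if fourfold:
            cols.append(3 * i + 2)
    return cols


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a proportion of differences."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def jc_silent_distance(
    aln: CodonAlignment, columns: Sequence[int] | None = None
) -> pd.DataFrame:
    """Pairwise JC-corrected distances over 4-fold degenerate columns.

    Saturated pairs (p >= 3/4) get NaN and should be excluded from fitting.
    """
    if columns is None:
        columns = fourfold_degenerate_columns(aln)
    if len(columns) == 0:
        raise ValueError("no 4-fold degenerate columns usable for distances")
    names = aln.species
    mat = np.array(
        [[aln.sequences[n][c] for c in columns] for n in names], dtype="U1"
    )
    k = len(names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            p = float(np.mean(mat[i] != mat[j]))
            d[i, j] = d[j, i] = jc_correct(p)
    return pd.DataFrame(d, index=names, columns=names)


def ls_branch_lengths(
    tree: SpeciesTree, distances: pd.DataFrame, weighting: str = "fm"
) -> tuple[dict[str, float], float]:
    """Non-negative least-squares branch lengths on the fixed topology.

    ``weighting='fm'`` (default) applies Fitch-Margoliash 1/d^2 weights so
    that noisy long distances do not dominate the short internal edges;
    ``weighting='ols'`` fits unweighted.  Returns (branch -> length,
    unweighted residual norm).  Saturated (NaN) pairs are dropped from the
    fit.  Requires >= 3 taxa.
    """
    if weighting not in ("fm", "ols"):
        raise ValueError(f"unknown weighting {weighting!r}")
    taxa = [t for t in distances.index if t in set(tree.species)]
    if len(taxa) < 3:
        raise ValueError("branch-length fit needs at least 3 taxa")
    branches = sorted(
        b for b in tree.branch_lengths
        if tree.descendant_species(b) & set(taxa)
    )
    col = {b: i for i, b in enumerate(branches)}
    rows, y = [], []
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            dij = distances.loc[a, b]
            if not np.isfinite(dij):
                continue
            row = np.zeros(len(branches))
            for br in tree.path_branches(a, b):
                row[col[br]] = 1.0
            rows.append(row)
            y.append(dij)
    A = np.asarray(rows)
    y = np.asarray(y)
    if A.shape[0] < len(branches):
        raise ValueError("underdetermined branch-length system")
    if weighting == "fm":
        w = 1.0 / np.maximum(y, 1e-6) ** 2
        x, _ = nnls(A * np.sqrt(w)[:, None], y * np.sqrt(w))
    else:
        x, _ = nnls(A, y)
    rnorm = float(np.linalg.norm(A @ x - y))
    return {b: float(x[col[b]]) for b in branches}, rnorm


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    """
    aa = translate_codon(codon)
    if aa is None:
        raise ValueError(f"internal stop codon {codon}")
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if translate_codon(alt) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all minimal substitution pathways; pathways through stops excluded
    (all pathways used if every one passes through a stop)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    tallies: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in permutations(diff):
        cur = c1
        syn = non = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            a1, a2 = translate_codon(cur), translate_codon(nxt)
            if a2 is None or a1 is None:
                through_stop = True
            if a1 is not None and a1 == a2:
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        (fallback if through_stop else tallies).append((syn, non))
    use = tallies or fallback
    return (
        sum(t[0] for t in use) / len(use),
        sum(t[1] for t in use) / len(use),
    )


def ng86_kaks(seq1: str, seq2: str) -> tuple[float, float, float | None]:
    """Nei-Gojobori (1986) Ka, Ks and their ratio for a gap-free CDS pair.

    Synonymous/nonsynonymous site counts are averaged over the two
    sequences; differences are averaged over minimal substitution pathways;
    proportions are Jukes-Cantor corrected.  The ratio is None when Ks = 0.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequence length mismatch")
    if len(seq1) % 3:
        raise ValueError("length not divisible by 3")
    S = N = Sd = Nd = 0.0
    for i in range(len(seq1) // 3):
        c1, c2 = seq1[3 * i : 3 * i + 3], seq2[3 * i : 3 * i + 3]
        s1, n1 = _codon_site_counts(c1)
        s2, n2 = _codon_site_counts(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = jc_correct(pS)
    ka = jc_correct(pN)
    ratio = None if ks == 0 or not np.isfinite(ks) else ka / ks
    return ka, ks, ratio


# ---------------------------------------------------------------------------
# Orthogroup filter for phylogenomics
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    retained: list[str]
    rejections: pd.DataFrame  # orthogroup_id, criterion, reason


def filter_orthogroups_for_phylogeny(
    alignments: Mapping[str, CodonAlignment],
    protein_lengths: Mapping[str, Sequence[int]],
    has_inparalogue: Mapping[str, bool],
    reference_species: str | None = None,
    kaks_threshold: float = 1.0,
    min_length_aa: int = 200,
    length_window_aa: int = 5,
    mad_factor: float = 1.5,
) -> FilterResult:
    """Apply the 4-criterion orthogroup filter, in order:

    1. no species has traceable duplications (no inparalogues);
    2. slowly evolving: no member pair against the reference species member
       has Ka/Ks > 1;
    3. members > ``min_length_aa`` amino acids, unless all members are
       within ``length_window_aa`` residues of each other;
    4. every member within ``mad_factor`` median absolute deviations of the
       median member length.

    Returns retained ids plus a per-orthogroup rejection log naming the
    first criterion that failed.
    """
    retained: list[str] = []
    rows: list[dict] = []

    def reject(og: str, criterion: int, reason: str) -> None:
        rows.append({"orthogroup_id": og, "criterion": criterion, "reason": reason})

    for og in sorted(alignments):
        aln = alignments[og]
        lengths = np.asarray(protein_lengths[og], dtype=float)

        if has_inparalogue.get(og, False):
            reject(og, 1, "traceable duplication (inparalogue) present")
            continue

        ref = reference_species if reference_species in aln.sequences else aln.species[0]
        exceeded = False
        for name in aln.species:
            if name == ref:
                continue
            _, _, ratio = ng86_kaks(aln.sequences[ref], aln.sequences[name])
            if ratio is not None and ratio > kaks_threshold:
                exceeded = True
                break
        if exceeded:
            reject(og, 2, f"Ka/Ks > {kaks_threshold} vs {ref}")
            continue

        within_window = lengths.max() - lengths.min() <= length_window_aa
        if lengths.min() <= min_length_aa and not within_window:
            reject(og, 3, f"member <= {min_length_aa} aa and lengths not within "
                          f"{length_window_aa} residues")
            continue

        med = float(np.median(lengths))
        # floor the MAD at one residue so near-identical lengths (MAD 0)
        # do not spuriously reject an orthogroup
        mad = max(float(np.median(np.abs(lengths - med))), 1.0)
        if np.any(np.abs(lengths - med) > mad_factor * mad):
            reject(og, 4, f"member beyond {mad_factor} MAD of median length")
            continue

        retained.append(og)

    rejections = pd.DataFrame(rows, columns=["orthogroup_id", "criterion", "reason"])
    return FilterResult(retained=retained, rejections=rejections)


def export_supermatrix(
    alignments: Mapping[str, CodonAlignment]
) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate retained alignments into a supermatrix.

    Returns (species -> concatenated sequence, partition table with 1-based
    inclusive coordinates).  Orthogroups are concatenated in sorted-id
    order; every retained group must contain every taxon.
    """
    ids = sorted(alignments)
    if not ids:
        raise ValueError("no retained orthogroups to concatenate")
    taxa = sorted(alignments[ids[0]].sequences)
    parts = {t: [] for t in taxa}
    rows = []
    start = 1
    for og in ids:
        aln = alignments[og]
        missing = set(taxa) ^ set(aln.sequences)
        if missing:
            raise ValueError(f"orthogroup {og}: taxon set mismatch {sorted(missing)}")
        length = 3 * aln.n_codons
        for t in taxa:
            parts[t].append(aln.sequences[t])
        rows.append({"orthogroup_id": og, "start": start, "end": start + length - 1})
        start += length
    matrix = {t: "".join(parts[t]) for t in taxa}
    return matrix, pd.DataFrame(rows)


def write_partition_file(partitions: pd.DataFrame, path) -> None:
    """RAxML-style partition table: ``DNA, <id> = <start>-<end>``."""
    with open(path, "w") as fh:
        for row in partitions.itertuples():
            fh.write(f"DNA, {row.orthogroup_id} = {row.start}-{row.end}\n")
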