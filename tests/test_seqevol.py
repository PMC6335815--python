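import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cactophil as cp
from cactophil.seqevol import (
    CodonAlignment,
    FOURFOLD_CODONS,
    export_supermatrix,
    filter_orthogroups_for_phylogeny,
    fourfold_degenerate_columns,
    jc_correct,
    jc_silent_distance,
    ls_branch_lengths,
    ng86_kaks,
    translate_codon,
    write_partition_file,
)

BASES = "ACGT"
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
SENSE = [c for c in CODONS if translate_codon(c) is not None]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_fourfold(codon: str) -> bool:
    """Degeneracy-table scan: third position is 4-fold iff all four third
    bases give the same amino acid."""
    aas = {translate_codon(codon[:2] + b) for b in BASES}
    return None not in aas and len(aas) == 1


def oracle_ng86_pair(c1: str, c2: str):
    """Brute-force NG86 for one codon pair: enumerate every ordering of the
    differing positions explicitly."""
    def site_counts(codon):
        syn = 0.0
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if translate_codon(alt) == translate_codon(codon):
                    syn += 1 / 3
        return syn, 3 - syn

    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths, stop_paths = [], []
    for order in itertools.permutations(diff):
        cur, s, n, hit_stop = c1, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if translate_codon(nxt) is None or translate_codon(cur) is None:
                hit_stop = True
            if translate_codon(cur) is not None and translate_codon(cur) == translate_codon(nxt):
                s += 1
            else:
                n += 1
            cur = nxt
        (stop_paths if hit_stop else paths).append((s, n))
    use = paths or stop_paths or [(0.0, 0.0)]
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    s1, n1 = site_counts(c1)
    s2, n2 = site_counts(c2)
    return (s1 + s2) / 2, (n1 + n2) / 2, sd, nd


# ---------------------------------------------------------------------------
# 4-fold columns
# ---------------------------------------------------------------------------

def test_fourfold_set_matches_degeneracy_table():
    assert FOURFOLD_CODONS == {c for c in CODONS if oracle_fourfold(c)}


def test_fourfold_columns_toy_alignment():
    # 20 codons drawn to mix 4-fold (GGx, CTx, ...) and non-4-fold (ATG, TGG, AAA)
    rng = np.random.default_rng(0)
    codons = list(rng.choice(SENSE, size=20))
    seq = "".join(codons)
    aln = CodonAlignment({"s1": seq, "s2": seq})
    expected = [3 * i + 2 for i, c in enumerate(codons) if oracle_fourfold(c)]
    assert fourfold_degenerate_columns(aln) == expected


def test_fourfold_requires_degeneracy_in_every_sequence():
    # GGA is 4-fold, ATG is not: the column only counts if all species agree
    aln = CodonAlignment({"s1": "GGAATG", "s2": "GGAGGA"})
    assert fourfold_degenerate_columns(aln) == [2]


def test_internal_stop_is_reported_with_sequence_and_position():
    aln = CodonAlignment({"bad": "TAAGGA", "ok": "GGAGGA"})
    with pytest.raises(ValueError, match="bad.*codon 0"):
        fourfold_degenerate_columns(aln)


def test_alignment_validation():
    with pytest.raises(ValueError, match="length"):
        CodonAlignment({"a": "GGAGG", "b": "GGAGG"})
    with pytest.raises(ValueError, match="differ"):
        CodonAlignment({"a": "GGAGGA", "b": "GGA"})
    with pytest.raises(ValueError, match="non-ACGT"):
        CodonAlignment({"a": "GGN"})


# ---------------------------------------------------------------------------
# JC silent distances
# ---------------------------------------------------------------------------

def test_jc_distance_zero_iff_identical():
    aln = CodonAlignment({"a": "GGAGGCCTA", "b": "GGAGGCCTA"})
    d = jc_silent_distance(aln)
    assert d.loc["a", "b"] == 0.0


def test_jc_closed_form_at_p_01():
    assert jc_correct(0.1) == pytest.approx(0.10732563, abs=1e-6)


def test_jc_saturation_flagged():
    assert math.isnan(jc_correct(0.75))
    assert math.isnan(jc_correct(0.9))


def test_jc_distance_errors_without_usable_columns():
    aln = CodonAlignment({"a": "ATGATG", "b": "ATGATG"})
    with pytest.raises(ValueError, match="4-fold"):
        jc_silent_distance(aln)


@settings(deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=0.74))
def test_jc_monotone_below_saturation(p):
    eps = 1e-4
    if p + eps < 0.75:
        assert jc_correct(p + eps) > jc_correct(p) - 1e-12


# ---------------------------------------------------------------------------
# least-squares branch lengths
# ---------------------------------------------------------------------------

def test_three_taxon_star_closed_form():
    tree = cp.SpeciesTree.from_newick("(A:1,B:1,C:1)root;")
    d = pd.DataFrame(
        [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]],
        index=list("ABC"), columns=list("ABC"),
    )
    lengths, resid = ls_branch_lengths(tree, d)
    assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25}, abs=1e-9)
    assert resid < 1e-9


def test_additive_distances_give_zero_residual(default_tree):
    taxa = default_tree.species
    bl = default_tree.branch_lengths
    d = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            d.loc[a, b] = d.loc[b, a] = sum(
                bl[e] for e in default_tree.path_branches(a, b)
            )
    lengths, resid = ls_branch_lengths(default_tree, d)
    assert resid < 1e-9
    for b, v in bl.items():
        assert lengths[b] == pytest.approx(v, abs=1e-9)


def test_branch_fit_requires_three_taxa():
    tree = cp.SpeciesTree.from_newick("(A:1,B:1)root;")
    d = pd.DataFrame([[0, 0.1], [0.1, 0]], index=["A", "B"], columns=["A", "B"])
    with pytest.raises(ValueError, match="3 taxa"):
        ls_branch_lengths(tree, d)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def test_ng86_identical_sequences():
    ka, ks, ratio = ng86_kaks("GGAGCT", "GGAGCT")
    assert ka == 0 and ks == 0 and ratio is None


def test_ng86_single_synonymous_difference():
    ka, ks, ratio = ng86_kaks("GGAGGAGGA", "GGGGGAGGA")
    assert ka == 0.0
    assert ks > 0


def test_ng86_two_codon_pair_matches_pathway_oracle():
    s1, s2 = "ATGAAA" + "GGATTC", "ATGAAA" + "GGCTTA"
    ka, ks, _ = ng86_kaks(s1, s2)
    S = N = Sd = Nd = 0.0
    for i in range(len(s1) // 3):
        s, n, sd, nd = oracle_ng86_pair(s1[3*i:3*i+3], s2[3*i:3*i+3])
        S, N, Sd, Nd = S + s, N + n, Sd + sd, Nd + nd
    assert ks == pytest.approx(jc_correct(Sd / S), abs=1e-12)
    assert ka == pytest.approx(jc_correct(Nd / N), abs=1e-12)


def test_ng86_errors():
    with pytest.raises(ValueError, match="mismatch"):
        ng86_kaks("GGA", "GGAGGA")
    with pytest.raises(ValueError, match="stop"):
        ng86_kaks("TAAGGA", "GGAGGA")


# ---------------------------------------------------------------------------
# orthogroup filter & supermatrix
# ---------------------------------------------------------------------------

def _aln(n_codons=210, species=("a", "b")):
    seq = "GGA" * n_codons
    return CodonAlignment({s: seq for s in species})


def test_filter_rejects_duplicated_orthogroups_first():
    res = filter_orthogroups_for_phylogeny(
        {"og1": _aln()}, {"og1": [210, 210]}, {"og1": True}
    )
    assert res.retained == []
    assert res.rejections.iloc[0]["criterion"] == 1


def test_filter_kaks_criterion():
    # few synonymous but many nonsynonymous changes: Ka/Ks > 1
    a = "AAA" * 210   # Lys
    b = "AAG" * 10 + "AGA" * 100 + "AAA" * 100
    ka, ks, ratio = ng86_kaks(a, b)
    assert ratio is not None and ratio > 1
    res = filter_orthogroups_for_phylogeny(
        {"og1": CodonAlignment({"a": a, "b": b})},
        {"og1": [210, 210]},
        {"og1": False},
    )
    assert res.rejections.iloc[0]["criterion"] == 2


def test_filter_mad_criterion():
    aln = _aln(species=("a", "b", "c", "d", "e"))
    res = filter_orthogroups_for_phylogeny(
        {"og1": aln}, {"og1": [300, 300, 301, 299, 300]}, {"og1": False}
    )
    assert res.retained == ["og1"]
    res2 = filter_orthogroups_for_phylogeny(
        {"og1": aln}, {"og1": [300, 300, 301, 299, 260]}, {"og1": False}
    )
    assert res2.rejections.iloc[0]["criterion"] == 4


def test_filter_short_orthogroups_pass_via_length_window_exception():
    aln = _aln(n_codons=155, species=("a", "b", "c", "d", "e"))
    # all members within five residues: the length criterion is waived even
    # though every member is under 200 aa (it may still fail later criteria)
    res = filter_orthogroups_for_phylogeny(
        {"og1": aln}, {"og1": [150, 151, 152, 153, 148]}, {"og1": False}
    )
    assert (res.rejections["criterion"] != 3).all()
    res1 = filter_orthogroups_for_phylogeny(
        {"og1": aln}, {"og1": [150, 151, 152, 151, 150]}, {"og1": False}
    )
    assert res1.retained == ["og1"]
    res2 = filter_orthogroups_for_phylogeny(
        {"og1": aln}, {"og1": [150, 151, 152, 153, 140]}, {"og1": False}
    )
    assert res2.rejections.iloc[0]["criterion"] == 3


def test_supermatrix_partitions_and_round_trip(tmp_path):
    a1 = CodonAlignment({"a": "GGA" * 10, "b": "GGC" * 10})
    a2 = CodonAlignment({"a": "CTA" * 20, "b": "CTG" * 20})
    matrix, parts = export_supermatrix({"og2": a2, "og1": a1})
    assert list(parts["orthogroup_id"]) == ["og1", "og2"]
    assert list(parts["start"]) == [1, 31]
    assert list(parts["end"]) == [30, 90]
    assert matrix["a"] == "GGA" * 10 + "CTA" * 20
    path = tmp_path / "parts.txt"
    write_partition_file(parts, path)
    assert "DNA, og1 = 1-30" in path.read_text()


def test_supermatrix_errors():
    with pytest.raises(ValueError, match="no retained"):
        export_supermatrix({})
    a1 = CodonAlignment({"a": "GGA", "b": "GGC"})
    a2 = CodonAlignment({"a": "CTA"})
    with pytest.raises(ValueError, match="taxon set"):
        export_supermatrix({"og1": a1, "og2": a2})
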