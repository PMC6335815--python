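"""Per-branch event rates against silent branch lengths, and the
duplication-selection association.

Observed per-branch counts (orthogroups arising on internal branches,
inparalogues and inparalogue-generating orthogroups on terminal branches,
positively selected genes on all branches) are compared with the counts
expected if events accrued in proportion to silent-site branch length; the
excess is observed minus expected, and a Poisson tail probability
formalises "disproportionate".  The association between generating
inparalogues and being positively selected is summarised per species with
exact binomial (Clopper-Pearson) confidence intervals and Fisher's exact
test, and the shared differential-expression overlap between two species
is tested against independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .orthology import OrthologyMap
from .tree import SpeciesTree

__all__ = [
    "tabulate_branch_events",
    "expected_and_excess",
    "association_table",
    "clopper_pearson",
    "overlap_independence",
]

EVENT_CLASSES = (
    "orthogroups_arising",
    "orthogroups_generating_inparalogues",
    "inparalogues",
    "selected_genes",
)


def tabulate_branch_events(
    orthology: OrthologyMap,
    selection_flags: pd.DataFrame,
    tree: SpeciesTree,
    species_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Observed per-branch counts of the four event classes.

    ``selection_flags`` needs columns gene_id, branch, selected (0/1).
    Internal branches carry orthogroup-origination counts; terminal
    branches carry inparalogue counts and the number of distinct
    orthogroups generating them; selection counts appear on any branch.
    """
    lengths = tree.branch_lengths
    branches = tree.internal_branches + tree.terminal_branches
    table = pd.DataFrame(
        0, index=branches, columns=list(EVENT_CLASSES), dtype=int
    )
    table.insert(0, "silent_length", [lengths[b] for b in branches])
    table.insert(
        1,
        "branch_type",
        ["internal"] * len(tree.internal_branches)
        + ["terminal"] * len(tree.terminal_branches),
    )
    table.index.name = "branch"

    for og, branch in orthology.origin_branch.items():
        if branch in table.index:
            table.loc[branch, "orthogroups_arising"] += 1

    og_of = orthology.orthogroup_of()
    gen_ogs: dict[str, set[str]] = {}
    for gene, (sp, template) in orthology.inparalogues.items():
        if sp not in table.index:
            continue
        table.loc[sp, "inparalogues"] += 1
        og = og_of.get(template) if template else None
        if og is not None:
            gen_ogs.setdefault(sp, set()).add(og)
    for sp, ogs in gen_ogs.items():
        table.loc[sp, "orthogroups_generating_inparalogues"] = len(ogs)

    bad = set(selection_flags["branch"]) - set(table.index)
    if bad:
        raise KeyError(f"selection flags on unknown branches: {sorted(bad)}")
    sel = selection_flags[selection_flags["selected"].astype(int) == 1]
    for branch, n in sel.groupby("branch").size().items():
        table.loc[branch, "selected_genes"] = int(n)
    return table


def expected_and_excess(
    table: pd.DataFrame,
    event_classes: tuple[str, ...] = EVENT_CLASSES,
    restrict: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Expected counts, excesses, and Poisson tail probabilities.

    For each event class, expected_i = L_i * (sum c / sum L) over the
    branches where the class applies (``restrict``; by default, orthogroup
    originations are fitted over internal branches and inparalogue classes
    over terminal branches, read from a ``branch_type`` column when
    present, otherwise over all branches), so the excesses sum to zero by
    construction.  Upper and lower Poisson tails P(X >= c_i) and
    P(X <= c_i) at mean expected_i quantify disproportion.
    """
    out = table.copy()
    L = out["silent_length"].astype(float)
    if (L <= 0).all():
        raise ValueError("all branch lengths are zero")
    default_scope = {
        "orthogroups_arising": "internal",
        "orthogroups_generating_inparalogues": "terminal",
        "inparalogues": "terminal",
        "selected_genes": None,
    }
    for cls in event_classes:
        if cls not in out.columns:
            continue
        rows = restrict.get(cls) if restrict else None
        if rows is None:
            scope = default_scope.get(cls)
            if scope is not None and "branch_type" in out.columns:
                rows = list(out.index[out["branch_type"] == scope])
            else:
                rows = list(out.index)
        mask = out.index.isin(rows)
        c = out.loc[mask, cls].astype(float)
        rate = c.sum() / L[mask].sum()
        expected = pd.Series(np.nan, index=out.index)
        expected[mask] = L[mask] * rate
        out[f"{cls}_expected"] = expected
        out[f"{cls}_excess"] = out[cls] - expected
        with np.errstate(invalid="ignore"):
            out[f"{cls}_p_upper"] = stats.poisson.sf(out[cls] - 1, expected)
            out[f"{cls}_p_lower"] = stats.poisson.cdf(out[cls], expected)
    return out


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval, as proportions.

    The lower bound inverts the upper binomial tail at (1-conf)/2 (0 when
    x = 0); the upper bound analogously (1 when x = n).  Equivalent to beta
    quantiles: Beta(x, n-x+1) at alpha/2 and Beta(x+1, n-x) at 1-alpha/2.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n and n >= 1")
    alpha = 1.0 - conf
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return lower, upper


@dataclass
class AssociationRow:
    species: str
    x_no_inp: int
    n_no_inp: int
    x_inp: int
    n_inp: int
    pct_no_inp: float | None
    ci_no_inp: tuple[float, float] | None
    pct_inp: float | None
    ci_inp: tuple[float, float] | None
    p_value: float | None


def _pct(x: int, n: int) -> float | None:
    if n == 0:
        return None
    # round-half-even at 2 decimals, percentage scale
    return float(np.round(100.0 * x / n, 2))


def association_table(flags: pd.DataFrame) -> pd.DataFrame:
    """Per-species duplication-selection association.

    ``flags`` needs columns gene_id, species, has_inparalogue (bool),
    is_selected (bool).  Returns, per species, the selected fraction among
    genes without and with inparalogues (percentages, exact 95% CIs) and a
    two-sided Fisher exact p for the 2x2.
    """
    required = {"species", "has_inparalogue", "is_selected"}
    missing = required - set(flags.columns)
    if missing:
        raise KeyError(f"missing columns: {sorted(missing)}")
    rows = []
    for sp, sub in flags.groupby("species"):
        inp = sub["has_inparalogue"].astype(bool)
        sel = sub["is_selected"].astype(bool)
        x_no, n_no = int((sel & ~inp).sum()), int((~inp).sum())
        x_in, n_in = int((sel & inp).sum()), int(inp.sum())
        ci_no = clopper_pearson(x_no, n_no) if n_no else None
        ci_in = clopper_pearson(x_in, n_in) if n_in else None
        if n_no and n_in:
            _, p = stats.fisher_exact(
                [[x_in, n_in - x_in], [x_no, n_no - x_no]], alternative="two-sided"
            )
        else:
            p = None
        rows.append(
            {
                "species": sp,
                "x_no_inp": x_no, "n_no_inp": n_no,
                "pct_no_inp": _pct(x_no, n_no),
                "ci_no_inp_lower": 100 * ci_no[0] if ci_no else None,
                "ci_no_inp_upper": 100 * ci_no[1] if ci_no else None,
                "x_inp": x_in, "n_inp": n_in,
                "pct_inp": _pct(x_in, n_in),
                "ci_inp_lower": 100 * ci_in[0] if ci_in else None,
                "ci_inp_upper": 100 * ci_in[1] if ci_in else None,
                "fisher_p": p,
            }
        )
    return pd.DataFrame(rows)


def overlap_independence(
    both: int, a_only: int, b_only: int, total: int
) -> dict[str, float | None]:
    """Shared-response overlap versus independence.

    Given counts of genes responding in both species, in each species only,
    and the total gene universe, returns the expected shared count under
    independence, the fold excess, and a Pearson chi-square (df = 1) on the
    implied 2x2 table.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if both + a_only + b_only > total:
        raise ValueError("category counts exceed total")
    n_a = both + a_only
    n_b = both + b_only
    expected_both = n_a * n_b / total
    fold = both / expected_both if expected_both > 0 else None
    neither = total - both - a_only - b_only
    obs = np.array([[both, a_only], [b_only, neither]], dtype=float)
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
    chi2 = float(cells.sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return {
        "expected_both": float(expected_both),
        "fold": None if fold is None else float(fold),
        "chi2": chi2,
        "df": 1,
        "p": p,
    }


def rank_selected_genes(
    flags: pd.DataFrame, branch: str, top: int = 20
) -> pd.DataFrame:
    """Top genes under positive selection on a branch, by ascending p-value
    (ties broken by gene id).  Requires a p_value column."""
    sub = flags[(flags["branch"] == branch) & (flags["selected"].astype(int) == 1)]
    if "p_value" not in sub.columns:
        raise KeyError("selection flags carry no p_value column to rank by")
    return (
        sub.sort_values(["p_value", "gene_id"])
        .head(top)
        .reset_index(drop=True)
    )
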