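"""Heat-shock time-course transcriptomics: filtering, TMM normalisation,
the differential-expression criterion, profile standardisation, fuzzy
c-means clustering with partition-coefficient model selection, and the
cross-species cluster report.

The design is 8 time points (a control frozen immediately prior to
exposure = T0, then mid-exposure, post-exposure and five recovery points)
with 3 replicates each.  A gene is heat-responsive when it shows
FDR-adjusted p < 0.05 and |log2FC| > 1 relative to T0 at two or more of
the seven post-T0 time points.  Standardised per-gene trajectories of the
responsive genes of both species are pooled and clustered with fuzzy
c-means; cluster membership > 0.5 defines core genes, and "discriminating
genes" are core genes of the over-represented species whose orthologue is
not a core gene of the same cluster in the other species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "filter_low_expression",
    "tmm_factors",
    "log2cpm",
    "de_call",
    "DEResult",
    "standardize_profiles",
    "fuzzy_cmeans",
    "partition_coefficient",
    "select_c",
    "cluster_report",
]

N_TIMEPOINTS = 8
N_REPLICATES = 3


def _sample_layout(columns: pd.Index) -> dict[int, list[str]]:
    """Map time point -> replicate columns from T{t}_rep{r} names."""
    layout: dict[int, list[str]] = {}
    for col in columns:
        if not col.startswith("T") or "_rep" not in col:
            raise ValueError(f"unrecognised sample column {col!r}")
        t = int(col.split("_")[0][1:])
        layout.setdefault(t, []).append(col)
    return layout


def filter_low_expression(counts: pd.DataFrame, min_total: int = 50) -> pd.DataFrame:
    """Keep genes with strictly more than ``min_total`` reads over all
    samples."""
    totals = counts.sum(axis=1)
    return counts.loc[totals > min_total]


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    abundance_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    The reference sample is the one whose upper quartile (of counts scaled
    by library size) is closest to the mean upper quartile.  For each
    sample, genes expressed in both sample and reference contribute
    M = log2 ratio and A = mean log2 abundance; the upper and lower
    ``logratio_trim`` of M and ``abundance_trim`` of A are discarded and
    the remaining M values averaged with inverse-variance weights.
    Factors are normalised to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("all-zero sample in count matrix")
    uq = np.array([np.quantile(counts[c] / lib[c], 0.75) for c in counts.columns])
    ref_col = counts.columns[int(np.argmin(np.abs(uq - uq.mean())))]
    ref = counts[ref_col].to_numpy(float)
    ref_lib = lib[ref_col]

    log_factors = {}
    for col in counts.columns:
        obs = counts[col].to_numpy(float)
        obs_lib = lib[col]
        if col == ref_col:
            log_factors[col] = 0.0
            continue
        ok = (obs > 0) & (ref > 0)
        m = np.log2((obs[ok] / obs_lib) / (ref[ok] / ref_lib))
        a = 0.5 * np.log2((obs[ok] / obs_lib) * (ref[ok] / ref_lib))
        w = (obs_lib - obs[ok]) / (obs_lib * obs[ok]) + (ref_lib - ref[ok]) / (
            ref_lib * ref[ok]
        )
        n = m.size
        lo_m = np.floor(n * logratio_trim) + 1
        lo_a = np.floor(n * abundance_trim) + 1
        rank_m = stats.rankdata(m, method="ordinal")
        rank_a = stats.rankdata(a, method="ordinal")
        keep = (
            (rank_m >= lo_m) & (rank_m <= n + 1 - lo_m)
            & (rank_a >= lo_a) & (rank_a <= n + 1 - lo_a)
        )
        if keep.sum() == 0:
            log_factors[col] = 0.0
        else:
            log_factors[col] = float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    f = pd.Series({c: 2.0 ** log_factors[c] for c in counts.columns})
    return f / np.exp(np.mean(np.log(f)))


def log2cpm(
    counts: pd.DataFrame, factors: pd.Series | None = None, prior: float = 0.5
) -> pd.DataFrame:
    """log2 counts per million on TMM-effective library sizes, with a
    pseudo-count."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors
    return np.log2((counts + prior).div(lib, axis=1) * 1e6)


@dataclass
class DEResult:
    """Per-gene, per-post-T0-time-point moderated test results."""

    log2fc: pd.DataFrame      # genes x T1..T7
    p: pd.DataFrame
    q: pd.DataFrame
    de: pd.Series             # gene -> bool
    expr: pd.DataFrame        # log2cpm matrix used

    def n_de(self) -> int:
        return int(self.de.sum())


def de_call(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    fdr: float = 0.05,
    lfc: float = 1.0,
    min_timepoints: int = 2,
    prior_df: float = 4.0,
    bh_scope: str = "joint",
) -> DEResult:
    """Differential expression against the pre-exposure control (T0).

    Each post-T0 time point is tested against T0 with a two-sample t-test
    whose pooled variance is moderated towards the grand mean of gene-wise
    variances (prior df ``prior_df``); BH correction is applied jointly
    across all gene x time tests (or per time point with
    ``bh_scope='per_timepoint'``).  A gene is heat-responsive when q < fdr
    and |log2FC| > lfc at ``min_timepoints`` or more time points.
    """
    layout = _sample_layout(counts.columns)
    if 0 not in layout:
        raise ValueError("no T0 control samples found")
    for t, cols in layout.items():
        if len(cols) < 2:
            raise ValueError(f"time point T{t} has fewer than 2 replicates")
    if factors is None:
        factors = tmm_factors(counts)
    expr = log2cpm(counts, factors)

    t0 = expr[layout[0]].to_numpy()
    mean0 = t0.mean(axis=1)
    times = sorted(t for t in layout if t != 0)

    # gene-wise residual variance pooled over all time points
    ss = np.zeros(len(expr))
    df_g = 0
    for t, cols in layout.items():
        arr = expr[cols].to_numpy()
        ss += ((arr - arr.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df_g += len(cols) - 1
    s2 = ss / df_g
    s2_prior = float(np.mean(s2))
    s2_mod = (prior_df * s2_prior + df_g * s2) / (prior_df + df_g)
    dof = prior_df + df_g

    fc = {}
    pvals = {}
    n0 = t0.shape[1]
    for t in times:
        arr = expr[layout[t]].to_numpy()
        delta = arr.mean(axis=1) - mean0
        se = np.sqrt(s2_mod * (1.0 / arr.shape[1] + 1.0 / n0))
        tstat = delta / se
        pvals[f"T{t}"] = 2.0 * stats.t.sf(np.abs(tstat), dof)
        fc[f"T{t}"] = delta
    log2fc = pd.DataFrame(fc, index=expr.index)
    p = pd.DataFrame(pvals, index=expr.index)

    if bh_scope == "joint":
        q_flat = stats.false_discovery_control(p.to_numpy().ravel(), method="bh")
        q = pd.DataFrame(
            q_flat.reshape(p.shape), index=p.index, columns=p.columns
        )
    elif bh_scope == "per_timepoint":
        q = p.apply(lambda col: stats.false_discovery_control(col, method="bh"))
    else:
        raise ValueError(f"unknown bh_scope {bh_scope!r}")

    hits = (q < fdr) & (log2fc.abs() > lfc)
    de = hits.sum(axis=1) >= min_timepoints
    return DEResult(log2fc=log2fc, p=p, q=q, de=de, expr=expr)


def timepoint_means(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean log2cpm at each time point."""
    layout = _sample_layout(expr.columns)
    return pd.DataFrame(
        {f"T{t}": expr[cols].mean(axis=1) for t, cols in sorted(layout.items())}
    )


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Standardise each gene's time-point profile to mean 0, sd 1.

    Zero-variance (constant) profiles are excluded with a warning.
    """
    arr = profiles.to_numpy(float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"excluding {int(flat.sum())} constant profiles")
    z = (arr[~flat] - mu[~flat]) / sd[~flat]
    return pd.DataFrame(z, index=profiles.index[~flat], columns=profiles.columns)


# ---------------------------------------------------------------------------
# Fuzzy c-means
# ---------------------------------------------------------------------------

def _fcm_once(
    x: np.ndarray, c: int, m: float, tol: float, max_iter: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float]:
    n = x.shape[0]
    centroids = x[rng.choice(n, size=c, replace=False)].copy()
    u = np.full((n, c), 1.0 / c)
    prev_obj = np.inf
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** m
        new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        obj = float((um * d2).sum())
        if obj > prev_obj + 1e-9:
            raise AssertionError("FCM objective increased")
        shift = float(np.abs(new_centroids - centroids).max())
        centroids = new_centroids
        prev_obj = obj
        if shift < tol:
            break
    return u, centroids, prev_obj


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    restarts: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fuzzy c-means with Euclidean distance; best of ``restarts`` random
    initialisations by objective.  Returns (memberships, centroids);
    membership rows sum to 1.
    """
    n = len(profiles)
    if c < 2 or c >= n:
        raise ValueError("need 2 <= c < n_genes")
    x = profiles.to_numpy(float)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        u, cent, obj = _fcm_once(x, c, m, tol, max_iter, rng)
        if best is None or obj < best[2]:
            best = (u, cent, obj)
    u, cent, _ = best
    # stable cluster numbering: by centroid value at the first time point
    order = np.lexsort(cent.T[::-1])
    u = u[:, order]
    cent = cent[order]
    cols = [f"cluster{i + 1}" for i in range(c)]
    return (
        pd.DataFrame(u, index=profiles.index, columns=cols),
        pd.DataFrame(cent, index=cols, columns=profiles.columns),
    )


def partition_coefficient(memberships: pd.DataFrame) -> float:
    """PC = mean over genes of the sum of squared memberships (1 for a
    crisp partition, 1/c for a uniform one)."""
    u = memberships.to_numpy(float)
    return float((u ** 2).sum(axis=1).mean())


def select_c(
    profiles: pd.DataFrame,
    c_range: range = range(4, 21),
    seed: int = 0,
    **fcm_kwargs,
) -> tuple[int, pd.Series]:
    """Choose the cluster number maximising the partition coefficient over
    ``c_range`` (ties towards the smaller c)."""
    pcs = {}
    for c in c_range:
        u, _ = fuzzy_cmeans(profiles, c=c, seed=seed, **fcm_kwargs)
        pcs[c] = partition_coefficient(u)
    series = pd.Series(pcs)
    best = int(series.idxmax())  # idxmax takes the first (smallest c) on ties
    return best, series


# ---------------------------------------------------------------------------
# Cluster report
# ---------------------------------------------------------------------------

def cluster_report(
    memberships: pd.DataFrame,
    gene_species: pd.Series,
    orthologue_pairs: dict[str, str] | None,
    core_threshold: float = 0.5,
    top_n: int = 10,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], list[str]]:
    """Cross-species cluster composition, discriminating genes, and the
    genes that fit no cluster.

    ``memberships`` is the pooled two-species membership matrix (both
    species clustered against the same centroids).  ``gene_species`` maps
    row index -> species.  ``orthologue_pairs`` maps each gene to its 1:1
    orthologue in the other species; genes absent from the map are treated
    as having no orthologue (with a warning).

    Returns (per-cluster summary, per-cluster top discriminating genes,
    unclustered gene ids).  Core genes have membership > ``core_threshold``
    in a cluster; the excess species is the one with more core genes; its
    discriminating genes are core genes whose orthologue is not a core gene
    of the same cluster in the other species; the top list is the
    ``top_n`` highest-membership discriminating genes (stable id
    tie-break).
    """
    if orthologue_pairs is None:
        orthologue_pairs = {}
    species = sorted(gene_species.unique())
    if len(species) != 2:
        raise ValueError("cluster report is defined for exactly two species")
    missing = [g for g in memberships.index if g not in gene_species.index]
    if missing:
        raise KeyError(f"genes without species labels: {missing[:5]}")
    unmapped = [g for g in memberships.index if g not in orthologue_pairs]
    if unmapped and orthologue_pairs:
        warnings.warn(
            f"{len(unmapped)} clustered genes missing from the orthology map; "
            "treated as having no orthologue"
        )

    max_m = memberships.max(axis=1)
    assigned = memberships.idxmax(axis=1)
    unclustered = sorted(memberships.index[max_m <= core_threshold])

    core: dict[tuple[str, str], set[str]] = {}
    for g in memberships.index:
        if max_m[g] > core_threshold:
            core.setdefault((assigned[g], gene_species[g]), set()).add(g)

    rows = []
    top_tables: dict[str, pd.DataFrame] = {}
    for cl in memberships.columns:
        a, b = species
        core_a = core.get((cl, a), set())
        core_b = core.get((cl, b), set())
        n_a, n_b = len(core_a), len(core_b)
        if n_a == n_b == 0:
            excess_sp, excess = None, 0
        elif n_a >= n_b:
            excess_sp, excess = a, n_a - n_b
        else:
            excess_sp, excess = b, n_b - n_a
        disc: list[str] = []
        if excess_sp is not None:
            own = core_a if excess_sp == a else core_b
            other = core_b if excess_sp == a else core_a
            for g in sorted(own):
                ortho = orthologue_pairs.get(g)
                if ortho is None or ortho not in other:
                    disc.append(g)
        total = n_a + n_b
        rows.append(
            {
                "cluster": cl,
                f"n_core_{a}": n_a,
                f"n_core_{b}": n_b,
                "excess_species": excess_sp,
                "excess": excess,
                "excess_pct": 100.0 * excess / total if total else 0.0,
                "n_discriminating": len(disc),
            }
        )
        sub = memberships.loc[disc, cl] if disc else pd.Series(dtype=float)
        top = (
            sub.sort_index()
            .sort_values(ascending=False, kind="stable")
            .head(top_n)
        )
        top_tables[cl] = pd.DataFrame(
            {"gene_id": top.index, "membership": top.to_numpy()}
        )
    return pd.DataFrame(rows), top_tables, unclustered


def plot_cluster_trajectories(
    profiles: pd.DataFrame,
    memberships: pd.DataFrame,
    centroids: pd.DataFrame,
    path,
    core_threshold: float = 0.5,
) -> None:
    """Standardised-trajectory panel, one subplot per cluster (core genes in
    grey, centroid highlighted)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    clusters = list(memberships.columns)
    ncol = 4
    nrow = -(-len(clusters) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False)
    xs = np.arange(profiles.shape[1])
    assigned = memberships.idxmax(axis=1)
    for k, cl in enumerate(clusters):
        ax = axes[k // ncol][k % ncol]
        genes = memberships.index[(assigned == cl) & (memberships[cl] > core_threshold)]
        for g in genes:
            ax.plot(xs, profiles.loc[g], color="0.8", lw=0.5)
        ax.plot(xs, centroids.loc[cl], color="C3", lw=2)
        ax.set_title(f"{cl} (n={len(genes)})", fontsize=8)
    for k in range(len(clusters), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
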