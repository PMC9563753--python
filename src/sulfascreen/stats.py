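"""Per-lipid biomarker statistics between cohort groups.

Group differences are summarized per lipid by a robust Hodges-Lehmann
type fold change (median of all pairwise between-group ratios), a
nonparametric test (Mann-Whitney U for independent plasma/urine groups,
Wilcoxon signed-rank for paired tissues, Kruskal-Wallis with Conover-Iman
post hoc for stage/grade splits), matching effect sizes (rank-biserial r,
epsilon squared), and Benjamini-Hochberg FDR across the panel.  Lipids
that fail the 50%-presence inclusion criterion are analyzed as binary
present/absent channels (Fisher exact for independent groups, exact
McNemar for paired tissues).  A Spearman screen relates age and BMI to
lipid levels, and a Ward-linkage summary provides the dendrogram and
z-score matrix behind the heat maps.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hl_fold_change",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "rank_biserial",
    "kruskal_wallis",
    "conover_posthoc",
    "bh_fdr",
    "fisher_presence",
    "mcnemar_presence",
    "presence_tables",
    "spearman_screen",
    "cluster_summary",
    "group_stats",
    "paired_stats",
    "ClusterSummary",
]


def _positive(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError(f"{name} is empty")
    if np.any(x <= 0):
        raise ValueError(f"{name} contains nonpositive values; run floor imputation first")
    return x


def hl_fold_change(x_t, x_n) -> float:
    """Hodges-Lehmann type fold change: median of all pairwise T/N ratios.

    The median of an even ratio count is the mean of the central pair.
    Scale-equivariant: ``hl_fold_change(c*x, x) == c`` for any c > 0.
    """
    x_t = _positive(x_t, "x_t")
    x_n = _positive(x_n, "x_n")
    ratios = np.outer(x_t, 1.0 / x_n)
    return float(np.median(ratios))


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact null distribution when both groups have <= 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (max(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(d) -> float:
    """Two-sided Wilcoxon signed-rank p for paired differences.

    Zero differences are dropped; the exact distribution is used for
    n <= 15 without tied magnitudes, otherwise the normal approximation
    with tie and continuity corrections.  All-zero differences give p = 1.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    mags = np.abs(d)
    no_ties = len(np.unique(mags)) == mags.size
    method = "exact" if (d.size <= 15 and no_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    return float(res.pvalue)


def rank_biserial(x, y) -> float:
    """Rank-biserial effect size for the Mann-Whitney comparison.

    r = 2 U_x / (n_x n_y) - 1 where U_x counts (x > y) pairs with ties as
    one half; r is in [-1, 1], positive when x tends to exceed y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(2.0 * u_x / (x.size * y.size) - 1.0)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float, float]:
    """Kruskal-Wallis H (tie-corrected), chi-square p, epsilon-squared.

    epsilon^2 = H (n + 1) / (n^2 - 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    nonempty = [g for g in groups if g.size]
    if len(nonempty) < 2:
        raise ValueError("at least two nonempty groups are required")
    n = sum(g.size for g in nonempty)
    pooled = np.concatenate(nonempty)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, 0.0
    h, p = sps.kruskal(*nonempty)
    eps2 = h * (n + 1) / (n * n - 1)
    return float(h), float(p), float(eps2)


def conover_posthoc(groups: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Conover-Iman post hoc pairwise comparisons on pooled ranks.

    Uses the tie-corrected Kruskal-Wallis H in the pooled-variance term;
    two-sided t p-values (df = n - k) are BH-adjusted across the pairs.
    Returns a symmetric DataFrame of adjusted p-values (unit diagonal);
    pairs involving an empty group are NaN.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    sizes = np.array([g.size for g in arrays])
    idx_nonempty = [i for i in range(k) if sizes[i] > 0]
    if len(idx_nonempty) < 2:
        raise ValueError("at least two nonempty groups are required")
    pooled = np.concatenate([arrays[i] for i in idx_nonempty])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = np.full(k, np.nan)
    pos = 0
    for i in idx_nonempty:
        mean_ranks[i] = ranks[pos : pos + sizes[i]].mean()
        pos += sizes[i]
    if np.all(pooled == pooled[0]):
        h = 0.0
    else:
        h, _ = sps.kruskal(*[arrays[i] for i in idx_nonempty])
    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    df = n - len(idx_nonempty)
    pooled_var = s2 * (n - 1 - h) / max(df, 1)
    pooled_var = max(pooled_var, 0.0)
    raw = {}
    for i, j in combinations(range(k), 2):
        if sizes[i] == 0 or sizes[j] == 0:
            raw[(i, j)] = np.nan
            continue
        denom = np.sqrt(pooled_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if denom == 0:
            raw[(i, j)] = 1.0
            continue
        t = (mean_ranks[i] - mean_ranks[j]) / denom
        raw[(i, j)] = float(2.0 * sps.t.sf(abs(t), df))
    keys = [key for key, p in raw.items() if not np.isnan(p)]
    if keys:
        adj = bh_fdr([raw[key] for key in keys])
        for key, q in zip(keys, adj):
            raw[key] = float(q)
    out = pd.DataFrame(np.eye(k), dtype=float)
    for (i, j), p in raw.items():
        out.iat[i, j] = p
        out.iat[j, i] = p
    np.fill_diagonal(out.values, 1.0)
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def fisher_presence(table: np.ndarray, odds: bool = True) -> tuple[float, float, float]:
    """Two-sided Fisher exact test of a 2x2 present/absent table.

    Returns (p, conditional-MLE odds ratio, Haldane-Anscombe OR for
    display).  Rows are groups, columns (present, absent).  ``odds=False``
    skips the (comparatively slow) odds-ratio estimation and returns NaN
    placeholders.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("a 2x2 table of nonnegative counts is required")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    if not odds:
        return float(p), float("nan"), float("nan")
    cmle = sps.contingency.odds_ratio(table, kind="conditional").statistic
    a, b, c, d = table.ravel() + 0.5
    haldane = (a * d) / (b * c)
    return float(p), float(cmle), float(haldane)


def mcnemar_presence(b: int, c: int) -> float:
    """Exact McNemar p for paired presence: two-sided binomial at 1/2.

    ``b`` = present only in nontumor, ``c`` = present only in tumor;
    concordant pairs carry no information.  b + c = 0 gives p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = b + c
    if n == 0:
        return 1.0
    return float(sps.binomtest(b, n, 0.5, alternative="two-sided").pvalue)


def presence_tables(
    m,
    design: pd.Series | pd.DataFrame,
    lipids: Sequence[str],
    paired: bool = False,
) -> pd.DataFrame:
    """Present/absent contingency analysis for sub-inclusion lipids.

    ``m`` is an :class:`~sulfascreen.ingest.IntensityMatrix`; a lipid is
    "present" when its intensity exceeds the 8000-count floor.  For the
    unpaired design, ``design`` holds N/T labels per sample and each lipid
    gets a Fisher exact p with odds ratios.  For the paired design,
    ``design`` is a DataFrame with columns ``nontumor`` and ``tumor``
    holding the matched sample ids, and each lipid gets discordant counts
    with the exact McNemar p.
    """
    floor = m.loq
    present = m.values > floor
    rows = []
    if not paired:
        labels = design.reindex(m.values.index).dropna()
        t_ids = labels.index[labels == "T"]
        n_ids = labels.index[labels == "N"]
        for lipid in lipids:
            pt = int(present.loc[t_ids, lipid].sum())
            pn = int(present.loc[n_ids, lipid].sum())
            table = np.array([[pt, len(t_ids) - pt], [pn, len(n_ids) - pn]])
            p, or_cmle, or_h = fisher_presence(table)
            rows.append(
                {
                    "lipid": lipid,
                    "present_T": pt,
                    "n_T": len(t_ids),
                    "present_N": pn,
                    "n_N": len(n_ids),
                    "p_raw": p,
                    "odds_ratio": or_cmle,
                    "odds_ratio_haldane": or_h,
                    "test_name": "fisher_exact",
                }
            )
    else:
        for lipid in lipids:
            non = present.loc[design["nontumor"], lipid].to_numpy()
            tum = present.loc[design["tumor"], lipid].to_numpy()
            b = int(np.sum(non & ~tum))
            c = int(np.sum(~non & tum))
            rows.append(
                {
                    "lipid": lipid,
                    "b_nontumor_only": b,
                    "c_tumor_only": c,
                    "n_pairs": len(design),
                    "p_raw": mcnemar_presence(b, c),
                    "test_name": "mcnemar_exact",
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    return out


def spearman_screen(covariate: pd.Series, concentrations: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho/p of a clinical covariate against each lipid.

    Missing covariate values are dropped pairwise; lipids with fewer than
    4 complete pairs or a constant input are reported as missing with a
    reason.
    """
    cov = covariate.reindex(concentrations.index)
    rows = []
    for lipid in concentrations.columns:
        vals = concentrations[lipid]
        mask = cov.notna() & vals.notna()
        x = cov[mask].to_numpy(dtype=float)
        y = vals[mask].to_numpy(dtype=float)
        if x.size < 4:
            rows.append({"lipid": lipid, "rho": np.nan, "p_raw": np.nan, "note": "n<4"})
            continue
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"lipid": lipid, "rho": np.nan, "p_raw": np.nan, "note": "constant"})
            continue
        rho, p = sps.spearmanr(x, y)
        rows.append({"lipid": lipid, "rho": float(rho), "p_raw": float(p), "note": ""})
    return pd.DataFrame(rows)


@dataclass
class ClusterSummary:
    """Ward dendrogram and z-score matrix behind the clustered heat maps."""

    linkage: np.ndarray
    newick: str
    zscores: pd.DataFrame  # lipids x samples
    sample_ids: list[str]


def cluster_summary(
    transformed: pd.DataFrame,
    lipids: Sequence[str] | None = None,
) -> ClusterSummary:
    """Ward-linkage clustering of samples on selected (transformed) lipids.

    ``transformed`` should already be log-transformed and Pareto scaled
    (see :func:`sulfascreen.classify.preprocess`).  Returns the merge tree
    (scipy linkage form and Newick) plus the per-lipid z-score matrix used
    for heat-map rendering.
    """
    cols = list(lipids) if lipids is not None else list(transformed.columns)
    data = transformed[cols]
    if len(data) < 2:
        raise ValueError("clustering needs at least 2 samples")
    link = hierarchy.linkage(data.to_numpy(), method="ward", metric="euclidean")
    from skbio import TreeNode  # deferred: slow import

    ids = [str(s) for s in data.index]
    tree = TreeNode.from_linkage_matrix(link, ids)
    buf = io.StringIO()
    tree.write(buf, format="newick")
    z = data.sub(data.mean(axis=0), axis=1)
    sd = data.std(axis=0, ddof=1).replace(0.0, np.nan)
    z = z.div(sd, axis=1).T  # lipids x samples
    return ClusterSummary(linkage=link, newick=buf.getvalue().strip(), zscores=z, sample_ids=ids)


def group_stats(
    relative: pd.DataFrame,
    labels: pd.Series,
    comparison: str = "T vs N",
) -> pd.DataFrame:
    """Per-lipid unpaired comparison table (volcano-ready).

    For each lipid: HL fold change (T over N), Mann-Whitney U and p,
    rank-biserial r, presence counts, BH q, log2 FC and -log10 q columns.
    """
    labels = labels.reindex(relative.index).dropna()
    x_t = relative.loc[labels.index[labels == "T"]]
    x_n = relative.loc[labels.index[labels == "N"]]
    if x_t.empty or x_n.empty:
        raise ValueError("both groups must be nonempty")
    rows = []
    for lipid in relative.columns:
        t = x_t[lipid].to_numpy()
        n = x_n[lipid].to_numpy()
        fc = hl_fold_change(t, n)
        u, p = mann_whitney(t, n)
        rows.append(
            {
                "lipid": lipid,
                "comparison": comparison,
                "fold_change": fc,
                "U": u,
                "p_raw": p,
                "effect_size": rank_biserial(t, n),
                "n_T": t.size,
                "n_N": n.size,
                "test_name": "mann_whitney",
            }
        )
    out = pd.DataFrame(rows)
    out["q_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    out["log2_fc"] = np.log2(out["fold_change"])
    out["neg_log10_q"] = -np.log10(out["q_fdr"].clip(lower=np.finfo(float).tiny))
    return out


def paired_stats(
    relative: pd.DataFrame,
    pairs: pd.DataFrame,
    comparison: str = "tumor vs nontumor",
    paired_ratios: bool = False,
) -> pd.DataFrame:
    """Per-lipid paired tissue comparison (Wilcoxon signed-rank).

    ``pairs`` has columns ``nontumor`` and ``tumor`` with matched sample
    ids.  The fold change defaults to the HL estimator over all pairwise
    ratios (matching the unpaired definition); ``paired_ratios=True``
    instead takes the median of the per-subject tumor/nontumor ratios.
    """
    rows = []
    for lipid in relative.columns:
        non = relative.loc[pairs["nontumor"], lipid].to_numpy()
        tum = relative.loc[pairs["tumor"], lipid].to_numpy()
        if paired_ratios:
            fc = float(np.median(tum / non))
        else:
            fc = hl_fold_change(tum, non)
        d = tum - non
        p = wilcoxon_signed_rank(d)
        rows.append(
            {
                "lipid": lipid,
                "comparison": comparison,
                "fold_change": fc,
                "p_raw": p,
                "effect_size": rank_biserial(tum, non),
                "n_pairs": len(pairs),
                "test_name": "wilcoxon_signed_rank",
            }
        )
    out = pd.DataFrame(rows)
    out["q_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    out["log2_fc"] = np.log2(out["fold_change"])
    out["neg_log10_q"] = -np.log10(out["q_fdr"].clip(lower=np.finfo(float).tiny))
    return out
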