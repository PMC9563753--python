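"""Fold changes, nonparametric tests, FDR, presence analysis, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sulfascreen import stats as st

positive_vectors = hst.lists(
    hst.floats(min_value=0.01, max_value=1e4, allow_nan=False), min_size=1, max_size=12
)


# ---------------------------------------------------------------- fold change


def test_hl_fold_change_examples():
    x = np.array([3.0, 1.0, 7.0])
    assert st.hl_fold_change(x, x) == pytest.approx(1.0)
    assert st.hl_fold_change(2 * x, x) == pytest.approx(2.0)
    assert st.hl_fold_change([2, 4], [1, 2]) == pytest.approx(2.0)  # median(2,1,4,2)


@settings(max_examples=50, derandomize=True)
@given(positive_vectors, hst.floats(min_value=0.1, max_value=10.0))
def test_hl_fold_change_scale_equivariance(x, c):
    x = np.asarray(x)
    assert st.hl_fold_change(c * x, x) == pytest.approx(c, rel=1e-9)


def test_hl_fold_change_rejects_nonpositive():
    with pytest.raises(ValueError):
        st.hl_fold_change([1.0, 0.0], [1.0])


def hl_bruteforce(x_t, x_n):
    ratios = sorted(a / b for a in x_t for b in x_n)
    k = len(ratios)
    mid = k // 2
    return ratios[mid] if k % 2 else 0.5 * (ratios[mid - 1] + ratios[mid])


def test_hl_fold_change_matches_double_loop_oracle(rng):
    for _ in range(200):
        x = rng.lognormal(0, 1, size=rng.integers(1, 10))
        y = rng.lognormal(0, 1, size=rng.integers(1, 10))
        assert st.hl_fold_change(x, y) == pytest.approx(hl_bruteforce(x, y), rel=1e-12)


# ---------------------------------------------------------------- rank tests


def test_mann_whitney_exact_example():
    u, p = st.mann_whitney([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2/20 rank assignments as extreme


def test_mann_whitney_degenerate_and_symmetry(rng):
    _, p = st.mann_whitney([5.0, 5.0], [5.0, 5.0, 5.0])
    assert p == 1.0
    x, y = rng.normal(size=10), rng.normal(size=12)
    assert st.mann_whitney(x, y)[1] == pytest.approx(st.mann_whitney(y, x)[1])


def test_wilcoxon_exact_example_and_symmetry(rng):
    d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    assert st.wilcoxon_signed_rank(d) == pytest.approx(2 / 64)
    assert st.wilcoxon_signed_rank(np.zeros(5)) == 1.0
    d = rng.normal(size=20)
    assert st.wilcoxon_signed_rank(d) == pytest.approx(st.wilcoxon_signed_rank(-d))


def test_wilcoxon_antisymmetric_differences():
    assert st.wilcoxon_signed_rank([-2.0, -1.0, 1.0, 2.0]) == pytest.approx(1.0)


def test_rank_biserial_examples():
    assert st.rank_biserial([10, 11, 12], [1, 2, 3]) == 1.0
    assert st.rank_biserial([1, 2, 3], [1, 2, 3]) == 0.0
    assert st.rank_biserial([1, 3], [2, 4]) == pytest.approx(-0.5)


def test_kruskal_wallis_examples():
    h, p, eps2 = st.kruskal_wallis([[1.0, 1.0], [1.0], [1.0, 1.0]])
    assert (h, eps2) == (0.0, 0.0) and p == 1.0
    # fully ordered groups of 2: H = 12/(6*7) * (2*2^2 + 0 + 2*2^2) = 32/7
    h, p, eps2 = st.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert h == pytest.approx(32 / 7)
    assert eps2 == pytest.approx(32 / 35)  # H (n+1) / (n^2 - 1)


def test_kruskal_wallis_permutation_invariance(rng):
    groups = [rng.normal(size=7), rng.normal(1, 1, size=5), rng.normal(2, 1, size=6)]
    h1, _, _ = st.kruskal_wallis(groups)
    h2, _, _ = st.kruskal_wallis(groups[::-1])
    assert h1 == pytest.approx(h2)


def test_conover_identical_groups_all_one():
    out = st.conover_posthoc([[1.0, 1.0, 1.0]] * 3)
    np.testing.assert_allclose(out.values, 1.0)


def test_conover_structure_and_separated_groups(rng):
    groups = [rng.normal(0, 1, 10), rng.normal(4, 1, 10), rng.normal(8, 1, 10)]
    out = st.conover_posthoc(groups)
    np.testing.assert_allclose(out.values, out.values.T)
    np.testing.assert_allclose(np.diag(out.values), 1.0)
    off = out.values[np.triu_indices(3, k=1)]
    assert (off < 0.05).all()


def test_conover_empty_group_reported_missing(rng):
    out = st.conover_posthoc([rng.normal(size=5), [], rng.normal(size=5)])
    assert np.isnan(out.iat[0, 1]) and np.isnan(out.iat[1, 2])
    assert np.isfinite(out.iat[0, 2])


# ----------------------------------------------------------------------- FDR


def test_bh_fdr_step_up_example():
    np.testing.assert_allclose(st.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(st.bh_fdr([0.2]), [0.2])
    np.testing.assert_allclose(st.bh_fdr([1.0, 1.0, 1.0]), 1.0)
    with pytest.raises(ValueError):
        st.bh_fdr([0.5, 1.5])


@settings(max_examples=50, derandomize=True)
@given(hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_fdr_dominates_p_and_is_monotone(p):
    p = np.asarray(p)
    q = st.bh_fdr(p)
    assert (q >= p - 1e-12).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


# ----------------------------------------------------------- presence tables


def test_fisher_presence_on_cohort_scale_counts():
    # 24 of 143 cancer plasmas vs 2 of 207 controls carry the lactosylsulfatide
    p, or_cmle, _ = st.fisher_presence([[24, 119], [2, 205]])
    assert p < 1e-6
    assert or_cmle > 1


def fisher_oracle(table):
    """Hypergeometric enumeration of the two-sided Fisher p."""
    from scipy.stats import hypergeom

    a, b, c, d = np.asarray(table).ravel()
    n1, n0, npos = a + b, c + d, a + c
    total = n1 + n0
    support = np.arange(max(0, npos - n0), min(npos, n1) + 1)
    pmf = hypergeom.pmf(support, total, npos, n1)
    cutoff = hypergeom.pmf(a, total, npos, n1)
    return float(pmf[pmf <= cutoff * (1 + 1e-9)].sum())


@pytest.mark.parametrize("table", [[[3, 7], [6, 2]], [[0, 5], [5, 0]], [[2, 2], [2, 2]]])
def test_fisher_matches_hypergeometric_enumeration(table):
    p, _, _ = st.fisher_presence(table)
    assert p == pytest.approx(fisher_oracle(table), abs=1e-12)


def test_mcnemar_examples():
    assert st.mcnemar_presence(6, 0) == pytest.approx(2 / 64)
    assert st.mcnemar_presence(0, 0) == 1.0
    # b = c is the least extreme outcome for fixed b + c
    p_eq = st.mcnemar_presence(5, 5)
    assert p_eq == max(st.mcnemar_presence(b, 10 - b) for b in range(11))


def test_presence_tables_unpaired(plasma_small):
    from sulfascreen import workflow

    quant = workflow.quantify(plasma_small)
    cohort = plasma_small.cohort
    m = plasma_small.matrix.copy()
    m.values = m.values.loc[cohort.index]
    out = st.presence_tables(m, cohort["group"], quant.dropped_presence)
    assert set(out["lipid"]) == set(quant.dropped_presence)
    assert ((out["p_raw"] >= 0) & (out["p_raw"] <= 1)).all()
    assert (out["q_fdr"] >= out["p_raw"] - 1e-12).all()


# ------------------------------------------------------------------ spearman


def test_spearman_screen_monotone_and_constant():
    conc = pd.DataFrame(
        {
            "up": [1.0, 2.0, 3.0, 4.0, 5.0],
            "down": [5.0, 4.0, 3.0, 2.0, 1.0],
            "flat": [1.0, 1.0, 1.0, 1.0, 1.0],
        },
        index=list("abcde"),
    )
    cov = pd.Series([10.0, 20.0, 30.0, 40.0, 50.0], index=list("abcde"))
    out = st.spearman_screen(cov, conc).set_index("lipid")
    assert out.loc["up", "rho"] == pytest.approx(1.0)
    assert out.loc["down", "rho"] == pytest.approx(-1.0)
    assert out.loc["flat", "note"] == "constant"


def test_spearman_screen_small_n_missing():
    conc = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc"))
    cov = pd.Series([1.0, 2.0, np.nan], index=list("abc"))
    out = st.spearman_screen(cov, conc)
    assert out.iloc[0]["note"] == "n<4"


# ---------------------------------------------------------------- clustering


def ward_oracle(data):
    """Naive O(n^3) Ward agglomeration via the Lance-Williams update."""
    n = len(data)
    d2 = np.sum((data[:, None, :] - data[None, :, :]) ** 2, axis=-1)
    active = {i: (1, i) for i in range(n)}  # id -> (size, column)
    merges = []
    next_id = n
    d2 = d2.astype(float)
    cols = {i: i for i in range(n)}
    cur = d2.copy()
    ids = list(range(n))
    while len(ids) > 1:
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                v = cur[cols[i], cols[j]]
                if best is None or v < best[0]:
                    best = (v, i, j)
        v, i, j = best
        si, sj = active[i][0], active[j][0]
        merges.append((min(i, j), max(i, j), np.sqrt(v), si + sj))
        # Lance-Williams Ward update on squared distances
        ci, cj = cols[i], cols[j]
        for k in ids:
            if k in (i, j):
                continue
            sk = active[k][0]
            ck = cols[k]
            t = si + sj + sk
            cur[ci, ck] = cur[ck, ci] = (
                (si + sk) * cur[ci, ck] + (sj + sk) * cur[cj, ck] - sk * cur[ci, cj]
            ) / t
        active[next_id] = (si + sj, None)
        cols[next_id] = ci
        ids = [k for k in ids if k not in (i, j)] + [next_id]
        next_id += 1
    return merges


def test_ward_linkage_matches_naive_oracle(rng):
    from scipy.cluster import hierarchy

    for n in (4, 6, 9, 12):
        data = rng.normal(size=(n, 3))
        link = hierarchy.linkage(data, method="ward")
        oracle = ward_oracle(data)
        heights = [m[2] for m in oracle]
        np.testing.assert_allclose(link[:, 2], heights, rtol=1e-8)
        np.testing.assert_allclose(link[:, 3], [m[3] for m in oracle])


def test_cluster_summary_duplicates_merge_first_and_zscores(rng):
    data = rng.normal(size=(5, 4))
    data = np.vstack([data, data[0]])  # duplicate sample 0
    df = pd.DataFrame(data, columns=list("wxyz"), index=[f"s{i}" for i in range(6)])
    out = st.cluster_summary(df)
    assert out.linkage[0, 2] == pytest.approx(0.0)
    assert set(out.linkage[0, :2].astype(int)) == {0, 5}
    np.testing.assert_allclose(out.zscores.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.zscores.std(axis=1, ddof=1), 1.0, rtol=1e-12)
    assert out.newick.endswith(";") and "s0" in out.newick


def test_cluster_summary_needs_two_samples():
    df = pd.DataFrame({"x": [1.0]}, index=["s0"])
    with pytest.raises(ValueError):
        st.cluster_summary(df)


# ------------------------------------------------------------- result tables


def test_group_stats_table(plasma_small, plasma_small_quant):
    labels = plasma_small.cohort["group"]
    out = st.group_stats(plasma_small_quant.relative, labels)
    assert len(out) == len(plasma_small_quant.relative.columns)
    assert ((out["p_raw"] >= 0) & (out["p_raw"] <= 1)).all()
    assert (out["q_fdr"] >= out["p_raw"] - 1e-12).all()
    assert (out["fold_change"] > 0).all()
    assert out["effect_size"].between(-1, 1).all()
    np.testing.assert_allclose(out["log2_fc"], np.log2(out["fold_change"]))


def test_paired_stats_table(rng):
    idx_n = [f"S{i:02d}-NT" for i in range(12)]
    idx_t = [f"S{i:02d}-TU" for i in range(12)]
    base = rng.lognormal(3, 0.3, size=12)
    rel = pd.DataFrame(
        {"SHexCer 40:1;O3": np.concatenate([base, base * 0.5])},
        index=idx_n + idx_t,
    )
    pairs = pd.DataFrame({"nontumor": idx_n, "tumor": idx_t})
    out = st.paired_stats(rel, pairs)
    assert out.iloc[0]["fold_change"] == pytest.approx(0.5, rel=0.2)
    assert out.iloc[0]["p_raw"] < 0.01
    paired_fc = st.paired_stats(rel, pairs, paired_ratios=True).iloc[0]["fold_change"]
    assert paired_fc == pytest.approx(0.5, rel=1e-9)
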