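"""Expression calling: Fisher/BH arithmetic, microarray pipeline, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gonadpi.expression import (
    array_pipeline, benjamini_hochberg, classify_sex_specificity, cluster_biased,
    fisher_exact_two_sided, platform_concordance, pooled_sex_counts,
    quantile_normalize, replicate_cv, select_array_candidates, seq_de_table,
    seq_logfc,
)


# ---------------------------------------------------------------------------
# sequencing side

@pytest.mark.parametrize("ovary,testis,expected", [
    (12, 0, "ovary_specific"),
    (0, 12, "testis_specific"),
    (5, 0, "low_count"),
    (0, 0, "low_count"),
    (3, 8, "shared"),
])
def test_sex_specificity_categories(ovary, testis, expected):
    assert classify_sex_specificity(ovary, testis) == expected


def test_sex_specificity_rejects_negative():
    with pytest.raises(ValueError):
        classify_sex_specificity(-1, 0)


def test_seq_logfc_worked_example_and_antisymmetry():
    assert seq_logfc(40, 10, 100, 100) == pytest.approx(np.log2(40.5 / 10.5))
    assert seq_logfc(10, 10, 100, 100) == 0.0
    assert seq_logfc(7, 31, 120, 90) == pytest.approx(-seq_logfc(31, 7, 90, 120))


def test_fisher_exact_worked_examples():
    assert fisher_exact_two_sided([[2, 0], [0, 2]]) == pytest.approx(1 / 3)
    assert fisher_exact_two_sided([[5, 5], [5, 5]]) == pytest.approx(1.0)


def fisher_two_sided_enumeration(a, b, c, d):
    """Oracle: sum hypergeometric point masses <= that of the observed table."""
    from math import comb

    n1, n2, k, N = a + b, c + d, a + c, a + b + c + d

    def pmf(x):
        return comb(n1, x) * comb(n2, k - x) / comb(N, k)

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def test_fisher_matches_enumeration_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(100):
        a, b, c, d = rng.integers(0, 16, size=4)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
            fisher_two_sided_enumeration(int(a), int(b), int(c), int(d)), rel=1e-9
        )


def bh_direct(p):
    """Oracle: padj_i = min over j with p_(j) >= p_i of p_(j) * m / rank(j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for pos, i in enumerate(order):
        out[i] = min(
            min(p[order[q]] * m / (q + 1) for q in range(pos, m)), 1.0
        )
    return out


def test_bh_worked_example_and_oracle():
    assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = rng.random(rng.integers(1, 30))
        mine = benjamini_hochberg(p)
        assert mine == pytest.approx(bh_direct(p))
        # cross-check against statsmodels' step-up
        from statsmodels.stats.multitest import multipletests

        assert mine == pytest.approx(multipletests(p, method="fdr_bh")[1])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_properties(p):
    adj = benjamini_hochberg(p)
    assert (adj <= 1.0 + 1e-12).all() and (adj >= np.asarray(p) - 1e-12).all()
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(adj[order]) >= -1e-12).all()
    if len(p) == 1:
        assert adj[0] == pytest.approx(min(p[0], 1.0))


def test_seq_de_table_and_candidate_selection(small_world, small_libraries):
    _, counts = small_libraries
    table = counts.rename(columns={})
    table["length"] = table["sequence"].str.len()
    table["total"] = table[["ovary1", "ovary2", "testis1", "testis2"]].sum(axis=1)
    de = seq_de_table(table)
    assert set(de["category"]) <= {"ovary_specific", "testis_specific", "shared", "low_count"}
    assert (de["padj"] >= de["p"] - 1e-12).all()
    # truth recovery: ovary-only piRNAs with enough reads call ovary_specific
    truth = small_world.truth
    merged = truth.merge(de, on="sequence")
    oo = merged[(merged["class"] == "piRNA") & (merged.sex_category == "ovary_only")
                & (merged.ovary_pool >= 10)]
    assert (oo["category"] == "ovary_specific").mean() >= 0.95
    cands = select_array_candidates(de)
    assert ((cands["is_de"]) | (cands["is_high_expr"])).all()
    # inclusive lower bound of the high-expression window
    row = de[de.ovary_pool == 50]
    if len(row):
        assert set(row.index) <= set(cands.index)


def test_pooled_counts_require_both_sexes():
    t = pd.DataFrame({"sequence": ["A" * 26], "length": [26], "ovary1": [3], "total": [3]})
    with pytest.raises(ValueError):
        pooled_sex_counts(t)


# ---------------------------------------------------------------------------
# microarray side

def test_quantile_normalization_worked_example_and_fixed_point():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
    qn = quantile_normalize(df)
    assert qn["a"].tolist() == [2.5, 3.5, 4.5]
    assert qn["b"].tolist() == [2.5, 3.5, 4.5]
    same = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
    pd.testing.assert_frame_equal(quantile_normalize(same), same)


def test_quantile_normalization_sorted_columns_identical_and_idempotent():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.lognormal(size=(40, 6)), columns=list("abcdef"))
    qn = quantile_normalize(df)
    ref = np.sort(qn["a"].to_numpy())
    for c in qn.columns:
        assert np.allclose(np.sort(qn[c].to_numpy()), ref)
    assert np.allclose(qn.mean(axis=0), qn.mean(axis=0).iloc[0])
    pd.testing.assert_frame_equal(quantile_normalize(qn), qn)


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(3)
    for _ in range(200):
        a = rng.normal(size=3)
        b = rng.normal(size=3)
        f, pf = stats.f_oneway(a, b)
        t, pt = stats.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-9)
        assert pf == pytest.approx(pt, rel=1e-9)
    f, _ = stats.f_oneway([1, 2, 3], [4, 5, 6])
    assert f == pytest.approx(13.5)


def _array_tables(n_probes=60, seed=4, lfc_for=None, noise=0.05):
    """Raw/background pair with optional per-probe planted log2 fold changes."""
    rng = np.random.default_rng(seed)
    cols = [f"{s}_r{r}" for s in
            ("ovary1", "ovary2", "ovary3", "testis1", "testis2", "testis3")
            for r in (1, 2, 3)]
    sig = 400 * rng.lognormal(0, 0.5, n_probes)
    raw = np.zeros((n_probes, 18))
    bg = np.full((n_probes, 18), 40.0)
    for i in range(n_probes):
        lfc = 0.0 if lfc_for is None else lfc_for[i]
        for j, c in enumerate(cols):
            fac = 2 ** (lfc / 2) if c.startswith("ovary") else 2 ** (-lfc / 2)
            raw[i, j] = bg[i, j] + sig[i] * fac * rng.lognormal(0, noise)
    idx = [f"P{i:03d}" for i in range(n_probes)]
    return (pd.DataFrame(raw, index=idx, columns=cols),
            pd.DataFrame(bg, index=idx, columns=cols))


def test_array_pipeline_categories_partition_probes():
    lfc = [2.0] * 10 + [0.0] * 50
    raw, bg = _array_tables(60, lfc_for=lfc)
    res = array_pipeline(raw, bg)
    assert len(res) == 60
    assert set(res["category"]) <= {"ovary_up", "testis_up", "co_expressed",
                                    "filtered", "nonsignificant"}
    assert res["category"].notna().all()
    called = res.loc[[f"P{i:03d}" for i in range(10)], "category"]
    assert (called == "ovary_up").mean() >= 0.9


def test_array_pipeline_rejects_incongruent_matrices():
    raw, bg = _array_tables(10)
    with pytest.raises(ValueError):
        array_pipeline(raw, bg.iloc[:5])


def test_replicate_cv_definition():
    assert replicate_cv(np.array([1.0, 1.0, 1.0])) == 0.0
    v = np.array([1.0, 2.0, 3.0])
    assert replicate_cv(v) == pytest.approx(v.std(ddof=1) / 2.0)
    assert replicate_cv(np.zeros(3)) == np.inf


def test_cluster_biased_separable_blocks_and_k1():
    lfc = [3.0] * 12 + [-3.0] * 12
    raw, bg = _array_tables(24, seed=5, lfc_for=lfc, noise=0.02)
    res = array_pipeline(raw, bg)
    clades = cluster_biased(res, k=2)
    up = res.loc[clades.index, "category"]
    by_cat = {cat: set(clades[up == cat]) for cat in ("ovary_up", "testis_up")}
    assert by_cat["ovary_up"].isdisjoint(by_cat["testis_up"])
    assert cluster_biased(res, k=1).nunique() == 1


def test_cluster_labels_invariant_under_row_permutation():
    lfc = [3.0] * 8 + [-3.0] * 8 + [0.0] * 10
    raw, bg = _array_tables(26, seed=6, lfc_for=lfc, noise=0.03)
    res = array_pipeline(raw, bg)
    c1 = cluster_biased(res, k=4)
    rng = np.random.default_rng(7)
    perm = rng.permutation(len(res))
    c2 = cluster_biased(res.iloc[perm], k=4)
    # same partition up to relabelling
    import itertools

    pairs1 = {frozenset(p) for p in itertools.combinations(sorted(c1.index), 2)
              if c1[p[0]] == c1[p[1]]}
    pairs2 = {frozenset(p) for p in itertools.combinations(sorted(c2.index), 2)
              if c2[p[0]] == c2[p[1]]}
    assert pairs1 == pairs2


def test_platform_concordance_extremes_and_attenuation():
    x = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
    assert platform_concordance(x, x)["r"] == pytest.approx(1.0)
    assert platform_concordance(x, -x)["r"] == pytest.approx(-1.0)
    assert platform_concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])["defined"] is False
    with pytest.raises(ValueError):
        platform_concordance([1.0], [2.0])
    # attenuation: r approx sqrt applied to independent-noise channels
    rng = np.random.default_rng(8)
    n = 300
    sig = rng.normal(0, 1.0, n)
    sx = sig + rng.normal(0, 0.5, n)
    sy = sig + rng.normal(0, 0.5, n)
    rho = 1.0 / (1.0 + 0.25)  # sigma_sig^2/(sigma_sig^2+sigma_noise^2)
    r = platform_concordance(sx, sy)["r"]
    assert abs(r - rho) <= 3 * (1 - rho ** 2) / np.sqrt(n - 1)
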