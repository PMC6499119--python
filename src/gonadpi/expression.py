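"""Sex-specific and sex-biased expression calling.

Sequencing side: sequences are pooled per sex across libraries, classified
as ovary-/testis-specific (one sex zero, the other above a count floor),
shared, or low-count; differential expression between sexes is tested with
a two-sided Fisher exact test on pooled counts (an exact choice suitable
for two libraries per sex) with Benjamini-Hochberg correction.

Microarray side: background subtraction, a replicate-CV filter, quantile
normalization of the spot columns, per-sample replicate medians, a
per-probe one-way ANOVA across the two sex groups, log2 fold change of the
group medians, and category calls (ovary_up / testis_up / co_expressed /
nonsignificant / filtered). Sex-biased probes can be clustered into clades
and compared with the sequencing log-fold-changes.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .config import ArrayThresholds, SeqThresholds
from .reads import count_columns

# ---------------------------------------------------------------------------
# shared statistics


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values: padj_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# sequencing side


def pooled_sex_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Sum library count columns into ovary/testis pools (by column prefix)."""
    libs = count_columns(table)
    ovary = [c for c in libs if c.startswith("ovary")]
    testis = [c for c in libs if c.startswith("testis")]
    if not ovary or not testis:
        raise ValueError("need at least one ovary* and one testis* count column")
    out = table[["sequence"]].copy() if "sequence" in table else pd.DataFrame(index=table.index)
    out["ovary_pool"] = table[ovary].sum(axis=1).astype(int)
    out["testis_pool"] = table[testis].sum(axis=1).astype(int)
    out["ovary_libsize"] = int(table[ovary].sum().sum())
    out["testis_libsize"] = int(table[testis].sum().sum())
    return out


def classify_sex_specificity(ovary: int, testis: int, min_count: int = 10) -> str:
    """Category from pooled per-sex counts."""
    if ovary < 0 or testis < 0:
        raise ValueError("counts must be non-negative")
    if testis == 0 and ovary >= min_count:
        return "ovary_specific"
    if ovary == 0 and testis >= min_count:
        return "testis_specific"
    if ovary > 0 and testis > 0:
        return "shared"
    return "low_count"


def seq_logfc(
    ovary: float, testis: float,
    ovary_libsize: float, testis_libsize: float,
    pseudocount: float = 0.5,
) -> float:
    """log2 ovary/testis ratio of library-size-normalised pooled counts.

    Counts are rescaled so each sex's library total matches the mean total
    (a no-op for equal sizes), then the pseudocount is added to both.
    """
    if ovary_libsize <= 0 or testis_libsize <= 0:
        raise ValueError("library sizes must be positive")
    scale = (ovary_libsize + testis_libsize) / 2.0
    no = ovary * scale / ovary_libsize
    nt = testis * scale / testis_libsize
    return float(np.log2((no + pseudocount) / (nt + pseudocount)))


def seq_de_table(
    table: pd.DataFrame,
    thresholds: SeqThresholds | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-sequence sex-expression record: pools, logFC, Fisher P, BH Padj, category.

    The Fisher test contrasts [count, library remainder] between sexes on
    the pooled counts.
    """
    thresholds = thresholds or SeqThresholds()
    pooled = pooled_sex_counts(table)
    o = pooled["ovary_pool"].to_numpy()
    t = pooled["testis_pool"].to_numpy()
    No = int(pooled["ovary_libsize"].iloc[0]) if len(pooled) else 0
    Nt = int(pooled["testis_libsize"].iloc[0]) if len(pooled) else 0
    if len(pooled) and (No == 0 or Nt == 0):
        raise ValueError("zero total library size; cannot test")
    lfc = np.array([
        seq_logfc(oi, ti, No, Nt, pseudocount) for oi, ti in zip(o, t)
    ])
    pvals = np.array([
        fisher_exact_two_sided([[oi, No - oi], [ti, Nt - ti]]) for oi, ti in zip(o, t)
    ])
    padj = benjamini_hochberg(pvals)
    cats = [classify_sex_specificity(oi, ti, thresholds.min_count) for oi, ti in zip(o, t)]
    out = pooled.copy()
    out["log2fc"] = lfc
    out["p"] = pvals
    out["padj"] = padj
    out["category"] = cats
    return out


def select_array_candidates(
    de: pd.DataFrame, thresholds: SeqThresholds | None = None
) -> pd.DataFrame:
    """Union of the DE-filtered and the highly-expressed sequences.

    DE: |logFC| >= lfc, P <= p, Padj <= padj, pooled count in either sex
    above min_count. High expression: ovary pool within high_expr_ovary or
    testis pool within high_expr_testis (inclusive bounds). The provenance
    of each candidate is flagged.
    """
    th = thresholds or SeqThresholds()
    de_mask = (
        (de["log2fc"].abs() >= th.lfc)
        & (de["p"] <= th.p)
        & (de["padj"] <= th.padj)
        & ((de["ovary_pool"] > th.min_count) | (de["testis_pool"] > th.min_count))
    )
    o_lo, o_hi = th.high_expr_ovary
    t_lo, t_hi = th.high_expr_testis
    hi_mask = (
        de["ovary_pool"].between(o_lo, o_hi) | de["testis_pool"].between(t_lo, t_hi)
    )
    out = de[de_mask | hi_mask].copy()
    out["is_de"] = de_mask[de_mask | hi_mask]
    out["is_high_expr"] = hi_mask[de_mask | hi_mask]
    return out


# ---------------------------------------------------------------------------
# microarray side


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the distribution of rank-wise column means.

    Ties within a column receive the mean of the reference values at their
    tied ranks. Idempotent; identical columns are a fixed point.
    """
    x = df.to_numpy(dtype=float)
    if x.size == 0:
        return df.copy()
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, len(ref) + 1), ref)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def _sample_of(col: str) -> str:
    return col.rsplit("_r", 1)[0]


def replicate_cv(values: np.ndarray) -> float:
    """sd/mean of replicate spots (sample sd); infinite when the mean is 0."""
    m = values.mean()
    if m == 0:
        return np.inf
    return float(values.std(ddof=1) / m)


def array_pipeline(
    raw: pd.DataFrame,
    background: pd.DataFrame,
    thresholds: ArrayThresholds | None = None,
    lfc_pseudo: float = 0.01,
) -> pd.DataFrame:
    """Full microarray analysis: subtract, CV-filter, normalize, test, call.

    `raw` and `background` are probe x spot matrices whose columns are
    ``<sample>_r<replicate>`` ids with samples named ovary*/testis*. Steps:
    (1) background subtraction floored at 0; (2) probes with replicate CV
    >= threshold in any sample are set aside as ``filtered``; (3) quantile
    normalization over the spot columns; (4) per-sample replicate medians;
    (5) one-way ANOVA of ovary vs testis sample medians; (6) log2FC of
    group medians with a small pseudo-intensity; (7) one category per probe.
    """
    th = thresholds or ArrayThresholds()
    if raw.shape != background.shape or list(raw.columns) != list(background.columns):
        raise ValueError("raw and background matrices are not congruent")
    samples = sorted({_sample_of(c) for c in raw.columns})
    ovary_s = [s for s in samples if s.startswith("ovary")]
    testis_s = [s for s in samples if s.startswith("testis")]
    if not ovary_s or not testis_s:
        raise ValueError("need ovary* and testis* samples")

    sub = raw.to_numpy(dtype=float) - background.to_numpy(dtype=float)
    n_floored = int((sub < 0).sum())
    if n_floored:
        warnings.warn(f"{n_floored} background-subtracted spots were negative; floored at 0")
    sub = pd.DataFrame(np.maximum(sub, 0.0), index=raw.index, columns=raw.columns)

    rep_cols = {s: [c for c in raw.columns if _sample_of(c) == s] for s in samples}
    cv = pd.DataFrame({
        s: sub[cols].apply(lambda r: replicate_cv(r.to_numpy()), axis=1)
        for s, cols in rep_cols.items()
    })
    keep = (cv < th.cv).all(axis=1)

    result = pd.DataFrame(index=raw.index)
    result["max_cv"] = cv.max(axis=1)
    result["category"] = "filtered"
    result["f_stat"] = np.nan
    result["p"] = np.nan
    result["log2fc"] = np.nan
    for s in samples:
        result[f"median_{s}"] = np.nan
    result["ovary_median"] = np.nan
    result["testis_median"] = np.nan

    passed = sub.loc[keep]
    if passed.empty:
        return result

    norm = quantile_normalize(passed)
    medians = pd.DataFrame({s: norm[cols].median(axis=1) for s, cols in rep_cols.items()})
    om = medians[ovary_s].to_numpy()
    tm = medians[testis_s].to_numpy()
    f = np.full(len(medians), np.nan)
    p = np.full(len(medians), np.nan)
    for i in range(len(medians)):
        if np.ptp(om[i]) == 0 and np.ptp(tm[i]) == 0 and om[i].mean() == tm[i].mean():
            f[i], p[i] = 0.0, 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f[i], p[i] = stats.f_oneway(om[i], tm[i])
    g_ov = np.median(om, axis=1)
    g_te = np.median(tm, axis=1)
    lfc = np.log2((g_ov + lfc_pseudo) / (g_te + lfc_pseudo))

    cats = np.where(
        (np.abs(lfc) >= th.lfc) & (p <= th.p),
        np.where(lfc > 0, "ovary_up", "testis_up"),
        np.where(
            (g_ov > th.coexpr_median) & (g_te > th.coexpr_median) & (p > th.p),
            "co_expressed",
            "nonsignificant",
        ),
    )
    idx = passed.index
    for s in samples:
        result.loc[idx, f"median_{s}"] = medians[s].to_numpy()
    result.loc[idx, "ovary_median"] = g_ov
    result.loc[idx, "testis_median"] = g_te
    result.loc[idx, "f_stat"] = f
    result.loc[idx, "p"] = p
    result.loc[idx, "log2fc"] = lfc
    result.loc[idx, "category"] = cats
    return result


def cluster_biased(result: pd.DataFrame, k: int = 10) -> pd.Series:
    """Cut average-linkage correlation-distance clustering into k clades.

    Operates on z-scored per-sample medians of the sex-biased probes;
    deterministic for a fixed input order.
    """
    biased = result[result["category"].isin(["ovary_up", "testis_up"])]
    med_cols = [c for c in result.columns if c.startswith("median_")]
    x = biased[med_cols].to_numpy(dtype=float)
    if len(biased) == 0:
        return pd.Series(dtype=int)
    if len(biased) < k:
        warnings.warn(f"only {len(biased)} biased probes; k reduced from {k}")
        k = max(1, len(biased))
    if k == 1 or len(biased) == 1:
        return pd.Series(1, index=biased.index)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    link = hierarchy.linkage(z, method="average", metric="correlation")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=biased.index)


def platform_concordance(seq_lfc, array_lfc) -> dict:
    """Pearson correlation between sequencing and microarray log2FC."""
    x = np.asarray(seq_lfc, dtype=float)
    y = np.asarray(array_lfc, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": np.nan, "p": np.nan, "n": int(len(x)), "defined": False}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x)), "defined": True}
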