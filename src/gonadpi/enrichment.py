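"""piRNA-generating genes and hypergeometric term enrichment.

A transcript is piRNA-generating when at least one predicted piRNA maps to
it exactly; per-gene statistics count unique piRNAs once per gene. Term
enrichment is the upper-tail hypergeometric test against a user-supplied
term-to-gene map, BH-corrected across terms.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .expression import benjamini_hochberg
from .index import ReferenceIndex


def map_pirnas_to_genes(
    pirnas: pd.DataFrame,
    index: ReferenceIndex,
    seq_col: str = "sequence",
) -> tuple[pd.DataFrame, dict]:
    """Map predicted piRNAs onto transcripts.

    Returns (gene table, summary). The gene table has one row per
    piRNA-generating gene with its length and unique piRNA count; a piRNA
    hitting several genes counts once in each (per-gene uniqueness). The
    summary reports gene count, gene-length statistics and mean piRNAs per
    gene.
    """
    gene_hits: dict[str, set[str]] = {}
    seq_to_genes: dict[str, set[str]] = {}
    for seq in pirnas[seq_col]:
        genes = {h.ref_id for h in index.transcriptome.lookup(seq)}
        seq_to_genes[seq] = genes
        for g in genes:
            gene_hits.setdefault(g, set()).add(seq)
    rows = [
        {"gene_id": g, "gene_length": len(index.transcriptome.refs[g]),
         "n_pirna": len(seqs)}
        for g, seqs in sorted(gene_hits.items())
    ]
    table = pd.DataFrame(rows, columns=["gene_id", "gene_length", "n_pirna"])
    if len(table):
        lengths = table["gene_length"]
        summary = {
            "n_genes": int(len(table)),
            "mean_length": float(lengths.mean()),
            "median_length": float(lengths.median()),
            "min_length": int(lengths.min()),
            "max_length": int(lengths.max()),
            "mean_pirnas_per_gene": float(table["n_pirna"].mean()),
            "max_pirnas_per_gene": int(table["n_pirna"].max()),
        }
    else:
        summary = {"n_genes": 0}
    table.attrs["seq_to_genes"] = seq_to_genes
    return table, summary


def sex_partition(
    gene_table: pd.DataFrame,
    ovary_specific: set[str],
    testis_specific: set[str],
    seq_to_genes: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Partition piRNA-generating genes by the sex-specific piRNAs they host.

    A gene is `ovary` when only ovary-specific piRNAs map to it, `testis`
    symmetrically, and `both` when it hosts at least one of each. Genes
    with no sex-specific piRNAs are left out of the partition.
    """
    seq_to_genes = seq_to_genes if seq_to_genes is not None else gene_table.attrs["seq_to_genes"]
    ov_genes: set[str] = set()
    te_genes: set[str] = set()
    for seq, genes in seq_to_genes.items():
        if seq in ovary_specific:
            ov_genes |= genes
        if seq in testis_specific:
            te_genes |= genes
    out = gene_table.copy()
    partition = []
    for g in out["gene_id"]:
        in_o, in_t = g in ov_genes, g in te_genes
        partition.append("both" if in_o and in_t else "ovary" if in_o else "testis" if in_t else "none")
    out["sex_partition"] = partition
    return out


def enrich(
    study: set[str],
    background: set[str],
    term_map: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of `study` within `background`.

    `term_map` columns: term_id, gene_id, and optionally term_name. Genes
    outside the background are ignored on the term side; a study gene
    missing from the background is an error. P(X >= k) is computed per term
    and BH-corrected; `enriched` flags Padj < alpha.
    """
    offenders = sorted(study - background)
    if offenders:
        raise ValueError(f"study genes absent from background: {offenders[:10]}")
    tm = term_map[term_map["gene_id"].isin(background)]
    names = (
        tm.drop_duplicates("term_id").set_index("term_id")["term_name"]
        if "term_name" in tm.columns else None
    )
    N = len(background)
    n = len(study)
    rows = []
    for term, sub in tm.groupby("term_id"):
        members = set(sub["gene_id"])
        K = len(members)
        k = len(members & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({
            "term_id": term,
            "term_name": names.get(term, "") if names is not None else "",
            "k": k, "K": K, "n": n, "N": N, "p": p,
        })
    res = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    if len(res):
        res["padj"] = benjamini_hochberg(res["p"].to_numpy())
        res["enriched"] = res["padj"] < alpha
        res = res.sort_values("padj", kind="mergesort").reset_index(drop=True)
    else:
        res["padj"] = []
        res["enriched"] = []
    return res
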