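"""piRNA signature statistics.

Position-specific base usage (5'U / position-10 A bias), length
distributions per group, sense/antisense composition, and genic-feature
(5'UTR / CDS / 3'UTR) assignment of mapped piRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .report import percentage

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
FEATURES = ["five_prime_UTR", "CDS", "three_prime_UTR", "unannotated"]


@dataclass
class PositionFrequencyMatrix:
    """Per-position base frequencies over a read set (ragged lengths allowed)."""

    freqs: pd.DataFrame  # index: position 1..P, columns A,C,G,U
    n_reads: float  # reads (or total count weight) contributing at position 1

    @property
    def fraction_U_at_1(self) -> float:
        return float(self.freqs.loc[1, "U"])

    @property
    def fraction_A_at_10(self) -> float:
        return float(self.freqs.loc[10, "A"])


def position_base_frequencies(
    sequences: Sequence[str],
    counts: Sequence[int] | None = None,
    weight_by_counts: bool = False,
    max_position: int = 32,
) -> PositionFrequencyMatrix:
    """Base usage per position 1..max_position.

    Positions beyond a read's length do not contribute to that position's
    denominator. With ``weight_by_counts`` each sequence contributes its
    read count, otherwise once (unique-sequence mode).
    """
    if len(sequences) == 0:
        raise ValueError("empty read set")
    if weight_by_counts:
        if counts is None:
            raise ValueError("weight_by_counts=True requires counts")
        w = np.asarray(counts, dtype=float)
    else:
        w = np.ones(len(sequences))
    mat = np.zeros((max_position, 4))
    for seq, wi in zip(sequences, w):
        for p in range(min(len(seq), max_position)):
            b = _BASE_IDX.get(seq[p])
            if b is not None:
                mat[p, b] += wi
    totals = mat.sum(axis=1)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals[:, None] > 0, mat / np.where(totals[:, None] > 0, totals[:, None], 1), np.nan)
    df = pd.DataFrame(freqs, index=pd.RangeIndex(1, max_position + 1, name="position"),
                      columns=["A", "C", "G", "U"])  # T reported as U
    # column order ACGT encoded; relabel T->U for reporting
    return PositionFrequencyMatrix(freqs=df, n_reads=float(totals[0]) if len(totals) else 0.0)


def length_distribution(
    lengths: Sequence[int],
    groups: Sequence[str],
    weights: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Percent of reads at each nt length, per group (columns sum to 100)."""
    df = pd.DataFrame({
        "length": np.asarray(lengths, dtype=int),
        "group": list(groups),
        "w": np.ones(len(lengths)) if weights is None else np.asarray(weights, dtype=float),
    })
    out = {}
    for g, sub in df.groupby("group"):
        total = sub["w"].sum()
        if total == 0:
            warnings.warn(f"group {g!r} empty; skipped")
            continue
        out[g] = sub.groupby("length")["w"].sum() / total * 100.0
    res = pd.DataFrame(out).fillna(0.0)
    res.index.name = "length"
    return res.sort_index()


def strand_composition(strands: Sequence[str]) -> dict:
    """Sense/antisense counts and half-up percentages of the total."""
    s = pd.Series(list(strands))
    sense = int((s == "+").sum())
    anti = int((s == "-").sum())
    total = sense + anti
    return {
        "sense": sense,
        "antisense": anti,
        "total": total,
        "sense_pct": percentage(sense, total) if total else 0.0,
        "antisense_pct": percentage(anti, total) if total else 0.0,
    }


def feature_assignment(
    transcript_id: str,
    start: int,
    end: int,
    gene_models: pd.DataFrame,
    transcript_lengths: Mapping[str, int] | None = None,
) -> str:
    """Majority-overlap genic feature of the read interval [start, end).

    Ties break CDS > 3'UTR > 5'UTR; transcripts without a gene model yield
    ``unannotated``. A hit beyond the transcript end is corrupt input.
    """
    if transcript_lengths is not None:
        tlen = transcript_lengths.get(transcript_id)
        if tlen is not None and end > tlen:
            raise ValueError(
                f"hit [{start},{end}) beyond end of {transcript_id} (len {tlen})"
            )
    spans = gene_models[gene_models["transcript_id"] == transcript_id]
    if spans.empty:
        return "unannotated"
    prio = {"CDS": 0, "three_prime_UTR": 1, "five_prime_UTR": 2}
    best, best_ov = "unannotated", 0
    for row in sorted(spans.itertuples(index=False), key=lambda r: prio.get(r.feature, 3)):
        ov = max(0, min(end, row.end) - max(start, row.start))
        if ov > best_ov:
            best, best_ov = row.feature, ov
    return best


def feature_distribution(
    hits: pd.DataFrame, gene_models: pd.DataFrame,
    transcript_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Counts and percentages over genic features for mapped piRNAs.

    `hits` needs columns hit_transcript, hit_start and length (interval is
    [hit_start, hit_start + length)). Unmapped rows count as unannotated.
    """
    # index spans per transcript once; per-row filtering would be quadratic
    spans_by_tid: dict[str, pd.DataFrame] = {
        tid: sub for tid, sub in gene_models.groupby("transcript_id")
    }
    labels = []
    for row in hits.itertuples(index=False):
        tid = row.hit_transcript
        if tid is None or (isinstance(tid, float) and np.isnan(tid)):
            labels.append("unannotated")
            continue
        sub = spans_by_tid.get(tid)
        if sub is None:
            labels.append("unannotated")
            continue
        labels.append(
            feature_assignment(tid, int(row.hit_start), int(row.hit_start) + int(row.length),
                               sub, transcript_lengths)
        )
    counts = pd.Series(labels).value_counts()
    total = int(counts.sum())
    rows = []
    for feat in FEATURES:
        c = int(counts.get(feat, 0))
        rows.append({"feature": feat, "count": c,
                     "pct": percentage(c, total) if total else 0.0})
    return pd.DataFrame(rows)
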