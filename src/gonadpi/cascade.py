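"""Sequential small-RNA annotation cascade.

Mapped unique reads are assigned exactly one label in priority order:
conserved miRNA, then structural ncRNA (rRNA/tRNA/snRNA/snoRNA), then
repeat, then novel miRNA (hairpin-context test on 18-25 nt reads), then
piRNA candidate (26-32 nt), then other. Unmapped reads are reported
separately and excluded from the annotation summary.

The novel-miRNA stand-in extracts +/-70 nt of transcript context around a
read's mapping position and asks whether the window folds into a
precursor-like stem: maximum nested base pairing (Watson-Crick + GU
wobble, minimum hairpin loop 3) of at least ``min_pairs``, with the read
lying wholly within one arm of an optimal structure.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from numba import njit

from .index import MappingHit, ReferenceIndex
from .reads import count_columns
from .report import percentage

LABELS = [
    "conserved_miRNA", "rRNA", "tRNA", "snRNA", "snoRNA",
    "repeat", "novel_miRNA", "piRNA_candidate", "other",
]

_NC_SET_TO_LABEL = {"rrna": "rRNA", "trna": "tRNA", "snrna": "snRNA", "snorna": "snoRNA"}

_ENC = np.full(128, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i

_MIN_LOOP = 3  # minimum unpaired bases enclosed by a pair


@njit(cache=False)
def _nussinov_dp(code):  # pragma: no cover - exercised via wrapper
    n = code.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            for k in range(i, j - _MIN_LOOP):
                a, b = code[k], code[j]
                paired = (
                    (a == 0 and b == 3) or (a == 3 and b == 0)
                    or (a == 1 and b == 2) or (a == 2 and b == 1)
                    or (a == 2 and b == 3) or (a == 3 and b == 2)
                )
                if paired:
                    left = dp[i, k - 1] if k > i else 0
                    cand = left + 1 + dp[k + 1, j - 1]
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


def nussinov_max_pairs(seq: str) -> int:
    """Maximum number of nested pairs (WC + GU, min loop 3) of a sequence."""
    return int(_dp_matrix(seq)[0, -1]) if len(seq) >= _MIN_LOOP + 2 else 0


def _dp_matrix(seq: str) -> np.ndarray:
    code = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if np.any(code == 255):
        code = code.copy()
        code[code == 255] = 4  # non-ACGT bases never pair
    return _nussinov_dp(code)


def _can_pair(a: str, b: str) -> bool:
    return (a + b) in ("AT", "TA", "CG", "GC", "GT", "TG")


def nussinov_pairs(seq: str) -> list[tuple[int, int]]:
    """One optimal nested pairing (pair list) via DP traceback."""
    n = len(seq)
    if n < _MIN_LOOP + 2:
        return []
    dp = _dp_matrix(seq)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= _MIN_LOOP or dp[i, j] == 0:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - _MIN_LOOP):
            if not _can_pair(seq[k], seq[j]):
                continue
            left = dp[i, k - 1] if k > i else 0
            if left + 1 + dp[k + 1, j - 1] == dp[i, j]:
                pairs.append((k, j))
                if k > i:
                    stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    return pairs


def hairpin_novel_mirna_filter(
    read: str,
    hit: MappingHit,
    transcripts: dict[str, str],
    context: int = 70,
    min_pairs: int = 18,
) -> bool:
    """True when a mapped 18-25 nt read sits in one arm of a foldable hairpin."""
    tseq = transcripts[hit.ref_id]
    if hit.start + hit.length > len(tseq):
        raise ValueError("mapping hit extends beyond transcript end")
    lo = max(0, hit.start - context)
    hi = min(len(tseq), hit.start + hit.length + context)
    window = tseq[lo:hi]
    if nussinov_max_pairs(window) < min_pairs:
        return False
    rs, re = hit.start - lo, hit.start - lo + hit.length
    for a, b in nussinov_pairs(window):
        if rs <= a < re and rs <= b < re:
            return False  # read folds onto itself: not a clean precursor arm
    return True


def annotate_cascade(
    table: pd.DataFrame,
    ref,
    index: ReferenceIndex,
    pirna_window: tuple[int, int] = (26, 32),
    novel_mirna_window: tuple[int, int] = (18, 25),
    hairpin_min_pairs: int = 18,
    hairpin_context: int = 70,
) -> pd.DataFrame:
    """Label every unique read; returns the table with `label` and hit columns.

    Unmapped reads get label ``unmapped``; all other reads get exactly one
    cascade label. The primary mapping hit recorded per read is the
    lexicographically smallest (transcript id, offset, strand).
    """
    labels = []
    hit_tid, hit_start, hit_strand = [], [], []
    lo_p, hi_p = pirna_window
    lo_n, hi_n = novel_mirna_window
    for seq in table["sequence"]:
        hits = index.transcriptome.lookup(seq)
        if not hits:
            labels.append("unmapped")
            hit_tid.append(None)
            hit_start.append(-1)
            hit_strand.append(None)
            continue
        h = hits[0]
        hit_tid.append(h.ref_id)
        hit_start.append(h.start)
        hit_strand.append(h.strand)
        L = len(seq)
        if index.sets.get("mirna") and index.sets["mirna"].contains(seq):
            labels.append("conserved_miRNA")
            continue
        nc_label = None
        for set_name, label in _NC_SET_TO_LABEL.items():
            if index.sets.get(set_name) and index.sets[set_name].contains(seq):
                nc_label = label
                break
        if nc_label:
            labels.append(nc_label)
        elif index.sets.get("repeat") and index.sets["repeat"].contains(seq):
            labels.append("repeat")
        elif lo_n <= L <= hi_n and hairpin_novel_mirna_filter(
            seq, h, ref.transcripts, hairpin_context, hairpin_min_pairs
        ):
            labels.append("novel_miRNA")
        elif lo_p <= L <= hi_p:
            labels.append("piRNA_candidate")
        else:
            labels.append("other")
    out = table.copy()
    out["label"] = labels
    out["hit_transcript"] = hit_tid
    out["hit_start"] = hit_start
    out["hit_strand"] = hit_strand
    return out


def summarize_annotation(labelled: pd.DataFrame) -> pd.DataFrame:
    """Per-library read accounting over the cascade labels.

    Percentages are of the library's mapped read count, half-up to 2
    decimals; label counts partition the mapped count exactly.
    """
    libs = [c for c in count_columns(labelled)
            if c not in ("label", "hit_transcript", "hit_start", "hit_strand")]
    mapped = labelled[labelled["label"] != "unmapped"]
    rows = []
    for lib in libs:
        total = int(mapped[lib].sum())
        row: dict[str, object] = {"library": lib, "mapped": total}
        for label in LABELS:
            c = int(mapped.loc[mapped["label"] == label, lib].sum())
            row[label] = c
            if total == 0:
                row[f"{label}_pct"] = 0.0
            else:
                row[f"{label}_pct"] = percentage(c, total)
        if total == 0:
            warnings.warn(f"library {lib}: mapped total is 0; percentages set to 0.00")
        rows.append(row)
    return pd.DataFrame(rows)
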