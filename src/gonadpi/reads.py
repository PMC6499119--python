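"""FASTQ cleaning, per-library QC, and unique-read collapsing.

The central object downstream is the unique-read table: one row per
distinct sequence with per-library occurrence counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO


@dataclass
class LibraryQC:
    """Raw-read quality summary for one library.

    error_rate and q30 / gc are percentages; error rate is the mean
    per-base miscall probability 10^(-Q/10) expressed in percent.
    """

    library: str
    total_reads: int
    retained_reads: int
    error_rate: float
    q30_fraction: float
    gc_content: float

    def as_dict(self) -> dict:
        return dict(
            library=self.library, total_reads=self.total_reads,
            retained_reads=self.retained_reads, error_rate=self.error_rate,
            q30_fraction=self.q30_fraction, gc_content=self.gc_content,
        )


class FastqFormatError(ValueError):
    pass


def _parse_fastq(path: str | Path):
    """Yield (seq, qualities) pairs, raising with file and record index on damage."""
    i = 0
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            i += 1
            yield str(rec.seq).upper(), rec.letter_annotations["phred_quality"]
    except ValueError as exc:
        raise FastqFormatError(
            f"malformed FASTQ in {path} near record {i + 1}: {exc}"
        ) from exc


def clean_and_collapse(
    fastq_paths: Mapping[str, str | Path],
    min_quality: float = 20.0,
    length_window: tuple[int, int] = (18, 35),
    adapter: Optional[str] = None,
) -> tuple[pd.DataFrame, list[LibraryQC]]:
    """Clean reads and collapse them into a unique-read table.

    Cleaning drops reads containing N, reads with mean Phred quality below
    ``min_quality`` and reads whose (post-trim) length falls outside
    ``length_window``; when ``adapter`` is given, everything from its first
    occurrence onward is removed. QC statistics are computed on the raw
    reads of each library.

    Returns (table, qc) where the table has columns ``sequence``, ``length``,
    one count column per library, and ``total``.
    """
    lo, hi = length_window
    per_lib_counts: dict[str, dict[str, int]] = {}
    qcs: list[LibraryQC] = []
    for lib, path in fastq_paths.items():
        counts: dict[str, int] = {}
        total = retained = 0
        err_sum = 0.0
        q30_bases = 0
        n_bases = 0
        gc_bases = 0
        for seq, quals in _parse_fastq(path):
            total += 1
            q = np.asarray(quals, dtype=float)
            if len(q):
                err_sum += float(np.mean(10.0 ** (-q / 10.0)))
                q30_bases += int(np.sum(q >= 30))
                n_bases += len(q)
                gc_bases += seq.count("G") + seq.count("C")
            if adapter:
                cut = seq.find(adapter)
                if cut != -1:
                    seq = seq[:cut]
                    q = q[:cut]
            if "N" in seq:
                continue
            if len(q) == 0 or float(np.mean(q)) < min_quality:
                continue
            if not lo <= len(seq) <= hi:
                continue
            retained += 1
            counts[seq] = counts.get(seq, 0) + 1
        per_lib_counts[lib] = counts
        qcs.append(
            LibraryQC(
                library=lib,
                total_reads=total,
                retained_reads=retained,
                error_rate=100.0 * err_sum / total if total else 0.0,
                q30_fraction=100.0 * q30_bases / n_bases if n_bases else 0.0,
                gc_content=100.0 * gc_bases / n_bases if n_bases else 0.0,
            )
        )
    table = collapse_counts(per_lib_counts)
    return table, qcs


def collapse_counts(per_lib_counts: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Assemble the unique-read table from per-library sequence counters."""
    libs = list(per_lib_counts)
    all_seqs = sorted(set().union(*[set(c) for c in per_lib_counts.values()]) if libs else set())
    data = {"sequence": all_seqs, "length": [len(s) for s in all_seqs]}
    for lib in libs:
        c = per_lib_counts[lib]
        data[lib] = [c.get(s, 0) for s in all_seqs]
    table = pd.DataFrame(data)
    table["total"] = table[libs].sum(axis=1) if libs else 0
    return table


def count_columns(table: pd.DataFrame) -> list[str]:
    """Library count columns of a unique-read table."""
    return [c for c in table.columns if c not in ("sequence", "length", "total")]
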