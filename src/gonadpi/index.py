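"""Exact-match sequence index (0-mismatch, end-to-end, both orientations).

The mapping contract mirrors ungapped 0-mismatch short-read alignment:
a query hits a reference wherever the query (sense) or its reverse
complement (antisense) occurs as an exact substring. Lookups run over a
fixed-length seed dictionary with full verification, so the hit set is
identical to a brute-force scan of every offset and both strands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from ._seq import revcomp


@dataclass(frozen=True, order=True)
class MappingHit:
    """Exact occurrence of a query on a reference (forward-strand coords)."""

    ref_id: str
    start: int  # 0-based offset on the reference forward strand
    strand: str  # '+' sense, '-' antisense
    length: int


class ExactIndex:
    """Seed-and-verify exact substring index over one sequence database."""

    def __init__(self, refs: Mapping[str, str], seed_len: int = 12):
        self.seed_len = seed_len
        self.refs = dict(refs)
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in self.refs.items():
            for i in range(len(seq) - seed_len + 1):
                self._seeds.setdefault(seq[i : i + seed_len], []).append((rid, i))

    def _occurrences(self, query: str) -> list[tuple[str, int]]:
        k = self.seed_len
        if len(query) < k:
            # rare short-query path: direct scan
            out = []
            for rid, seq in self.refs.items():
                p = seq.find(query)
                while p != -1:
                    out.append((rid, p))
                    p = seq.find(query, p + 1)
            return out
        seed = query[:k]
        out = []
        for rid, pos in self._seeds.get(seed, ()):  # verify full match
            if self.refs[rid][pos : pos + len(query)] == query:
                out.append((rid, pos))
        return out

    def lookup(self, query: str) -> list[MappingHit]:
        """All exact hits of `query` in both orientations, sorted."""
        L = len(query)
        hits = [MappingHit(rid, pos, "+", L) for rid, pos in self._occurrences(query)]
        rc = revcomp(query)
        hits += [MappingHit(rid, pos, "-", L) for rid, pos in self._occurrences(rc)]
        return sorted(hits)

    def contains(self, query: str) -> bool:
        """True if the query occurs anywhere in the database (either strand)."""
        if self._occurrences(query):
            return True
        return bool(self._occurrences(revcomp(query)))


@dataclass
class ReferenceIndex:
    """Exact indexes over the transcriptome and each annotation database."""

    transcriptome: ExactIndex
    sets: dict[str, ExactIndex]


def build_exact_index(ref, seed_len: int = 12) -> ReferenceIndex:
    """Index a :class:`~gonadpi.simulate.ReferenceBundle` for the cascade."""
    return ReferenceIndex(
        transcriptome=ExactIndex(ref.transcripts, seed_len),
        sets={name: ExactIndex(seqs, seed_len) for name, seqs in ref.sets.items()},
    )
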