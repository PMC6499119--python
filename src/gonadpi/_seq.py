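"""Small sequence helpers shared across the package.

DNA alphabet (ACGT) throughout; summaries report U for T where the RNA
convention is expected.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def random_dna_many(rng: np.random.Generator, lengths) -> list[str]:
    """Draw several random DNA strings in one vectorised call."""
    lengths = np.asarray(lengths, dtype=int)
    total = int(lengths.sum())
    flat = rng.integers(0, 4, size=total)
    letters = np.array(list(BASES))[flat]
    out = []
    pos = 0
    for n in lengths:
        out.append("".join(letters[pos : pos + n]))
        pos += n
    return out


def gc_content(seq: str) -> float:
    """GC fraction of a sequence (0..1); 0 for empty input."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
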