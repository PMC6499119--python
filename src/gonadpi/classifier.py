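"""k-mer sequence classifier for 26-32 nt piRNA candidates.

Features are the concatenated k-mer frequency blocks for k = 1..kmax
(1,364 dimensions at kmax = 5). Each feature receives a signed Fisher
ratio weight learned from positive (piRNA) and negative (non-piRNA)
training sequences; the decision score is the linear combination and the
threshold is chosen to maximise Youden's J on the training data. A
position-specific base-usage ("static") scorer is provided as the
comparison baseline, and known-piRNA homolog search is exact full-sequence
identity.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


def kmer_feature_names(kmax: int) -> list[str]:
    names = []
    for k in range(1, kmax + 1):
        names.extend("".join(t) for t in itertools.product("ACGT", repeat=k))
    return names


def n_features(kmax: int) -> int:
    return sum(4 ** k for k in range(1, kmax + 1))


def extract_kmer_features(seq: str, kmax: int = 5) -> np.ndarray:
    """Concatenated k-mer frequency vector for k = 1..kmax.

    Each block is occurrences/(L - k + 1); windows containing non-ACGT
    characters are excluded from both numerator and denominator, so each
    block sums to 1 for clean sequences.
    """
    L = len(seq)
    if L < kmax:
        raise ValueError(f"sequence of length {L} shorter than kmax={kmax}")
    out = np.zeros(n_features(kmax))
    offset = 0
    for k in range(1, kmax + 1):
        block = np.zeros(4 ** k)
        valid = 0
        for i in range(L - k + 1):
            idx = 0
            ok = True
            for c in seq[i : i + k]:
                b = _BASE_IDX.get(c)
                if b is None:
                    ok = False
                    break
                idx = idx * 4 + b
            if ok:
                block[idx] += 1
                valid += 1
        if valid:
            block /= valid
        out[offset : offset + 4 ** k] = block
        offset += 4 ** k
    return out


def feature_matrix(seqs: Sequence[str], kmax: int = 5) -> np.ndarray:
    return np.vstack([extract_kmer_features(s, kmax) for s in seqs]) if len(seqs) else np.zeros((0, n_features(kmax)))


@dataclass
class ClassifierModel:
    """Signed Fisher-ratio weights with a Youden-J decision threshold."""

    kmax: int
    weights: np.ndarray
    threshold: float
    n_pos: int = 0
    n_neg: int = 0
    seed: int | None = None

    def score(self, seqs: Sequence[str]) -> np.ndarray:
        return feature_matrix(seqs, self.kmax) @ self.weights

    def to_json(self, path: str | Path | None = None) -> str:
        blob = json.dumps(
            dict(kmax=self.kmax, weights=list(self.weights),
                 threshold=self.threshold, n_pos=self.n_pos, n_neg=self.n_neg,
                 seed=self.seed),
        )
        if path is not None:
            Path(path).write_text(blob)
        return blob

    @classmethod
    def from_json(cls, blob_or_path: str | Path) -> "ClassifierModel":
        p = Path(str(blob_or_path))
        text = p.read_text() if p.exists() else str(blob_or_path)
        d = json.loads(text)
        return cls(kmax=d["kmax"], weights=np.array(d["weights"]),
                   threshold=d["threshold"], n_pos=d["n_pos"], n_neg=d["n_neg"],
                   seed=d["seed"])


_VAR_FLOOR = 1e-9


def train_fisher(
    positives: Sequence[str],
    negatives: Sequence[str],
    kmax: int = 5,
    seed: int | None = None,
) -> ClassifierModel:
    """Fit signed Fisher-ratio weights and a Youden-J threshold.

    Per feature j: F_j = (m+_j - m-_j)^2 / (v+_j + v-_j + eps) and
    w_j = sign(m+_j - m-_j) * F_j, where m/v are the class means and
    variances. Scores are x @ w; the threshold maximises TPR - FPR over the
    training scores (smallest maximiser on ties).
    """
    if len(positives) < 2 or len(negatives) < 2:
        raise ValueError("each training class needs at least 2 sequences")
    xp = feature_matrix(positives, kmax)
    xn = feature_matrix(negatives, kmax)
    diff = xp.mean(axis=0) - xn.mean(axis=0)
    denom = xp.var(axis=0, ddof=1) + xn.var(axis=0, ddof=1) + _VAR_FLOOR
    weights = np.sign(diff) * diff ** 2 / denom
    sp = xp @ weights
    sn = xn @ weights
    threshold = _youden_threshold(sp, sn)
    return ClassifierModel(kmax=kmax, weights=weights, threshold=threshold,
                           n_pos=len(positives), n_neg=len(negatives), seed=seed)


def _youden_threshold(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Score cut maximising sensitivity + specificity - 1 (positive: score >= t)."""
    candidates = np.unique(np.concatenate([pos_scores, neg_scores]))
    best_t, best_j = float(candidates[0]), -np.inf
    for t in candidates:
        tpr = float(np.mean(pos_scores >= t))
        fpr = float(np.mean(neg_scores >= t))
        j = tpr - fpr
        if j > best_j:
            best_j, best_t = j, float(t)
    return best_t


def classify(
    candidates: Sequence[str],
    model: ClassifierModel,
    length_window: tuple[int, int] = (26, 32),
) -> "pd.DataFrame":
    """Score candidate sequences; positive iff score >= model.threshold."""
    import pandas as pd

    lo, hi = length_window
    bad = [s for s in candidates if not lo <= len(s) <= hi]
    if bad:
        raise ValueError(
            f"{len(bad)} candidate(s) outside the {lo}-{hi} nt window, e.g. {bad[0]!r}"
        )
    scores = model.score(list(candidates))
    return pd.DataFrame(
        {"sequence": list(candidates), "score": scores,
         "predicted_pirna": scores >= model.threshold}
    )


def auroc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) identity."""
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos_scores, neg_scores]))
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    return (ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# position-specific ("static") baseline

@dataclass
class PositionBaseMatrix:
    """Smoothed per-position base frequencies with log-odds scoring."""

    freqs: np.ndarray  # positions x 4, rows sum to 1
    pseudocount: float = 1.0

    @property
    def n_positions(self) -> int:
        return self.freqs.shape[0]

    def score(self, seq: str) -> float:
        """Sum over positions of log(f[p, base] / 0.25), up to min(L, P)."""
        total = 0.0
        for p in range(min(len(seq), self.n_positions)):
            b = _BASE_IDX.get(seq[p])
            if b is None:
                continue
            total += float(np.log(self.freqs[p, b] / 0.25))
        return total


def train_static_scheme(
    positives: Sequence[str], n_positions: int = 20, pseudocount: float = 1.0
) -> PositionBaseMatrix:
    """Position-specific base usage: f[p,b] = (count + 0.25*pc)/(n + pc)."""
    if not len(positives):
        raise ValueError("positives must be non-empty")
    counts = np.zeros((n_positions, 4))
    n_at = np.zeros(n_positions)
    for s in positives:
        for p in range(min(len(s), n_positions)):
            b = _BASE_IDX.get(s[p])
            if b is None:
                continue
            counts[p, b] += 1
            n_at[p] += 1
    freqs = (counts + 0.25 * pseudocount) / (n_at[:, None] + pseudocount)
    return PositionBaseMatrix(freqs=freqs, pseudocount=pseudocount)


def static_score(seqs: Sequence[str], matrix: PositionBaseMatrix) -> np.ndarray:
    return np.array([matrix.score(s) for s in seqs])


def compare_kmer_static(
    positives: Sequence[str],
    negatives: Sequence[str],
    kmax: int = 5,
    holdout_fraction: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """Benchmark the k-mer scheme against the static scheme.

    Both are trained on a common split and evaluated by AUROC on the same
    held-out sequences; returns {'kmer_auroc': ..., 'static_auroc': ...}.
    """
    rng = np.random.default_rng(seed)
    pos = list(positives)
    neg = list(negatives)
    rng.shuffle(pos)
    rng.shuffle(neg)
    np_tr = max(2, int(len(pos) * (1 - holdout_fraction)))
    nn_tr = max(2, int(len(neg) * (1 - holdout_fraction)))
    model = train_fisher(pos[:np_tr], neg[:nn_tr], kmax=kmax, seed=seed)
    pbm = train_static_scheme(pos[:np_tr])
    pos_te, neg_te = pos[np_tr:], neg[nn_tr:]
    return {
        "kmer_auroc": auroc(model.score(pos_te), model.score(neg_te)),
        "static_auroc": auroc(static_score(pos_te, pbm), static_score(neg_te, pbm)),
        "n_heldout_pos": len(pos_te),
        "n_heldout_neg": len(neg_te),
    }


# ---------------------------------------------------------------------------
# known-piRNA homolog search

@dataclass(frozen=True)
class HomologHit:
    query: str
    known_id: str
    match_type: str = "exact"


def match_known(predictions: Iterable[str], known: Mapping[str, str]) -> list[HomologHit]:
    """Exact full-sequence identity matches against the known-piRNA set."""
    by_seq: dict[str, str] = {}
    for kid, seq in known.items():
        by_seq.setdefault(seq, kid)
    hits = []
    for q in predictions:
        kid = by_seq.get(q)
        if kid is not None:
            hits.append(HomologHit(query=q, known_id=kid))
    return hits
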