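"""Synthetic gonadal small-RNA world with known ground truth.

Generates a reference bundle (transcriptome with gene models, contaminant
small-RNA reference sets, a known-piRNA set), a piRNA pool with tunable
5'U / position-10 A biases and sex-expression classes, per-library FASTQ
reads with negative-binomial counts, and single-channel microarray
intensity matrices with replicate spots — together with a truth table that
downstream recovery tests compare against.

Design notes
------------
* Contaminant source sequences (mature miRNAs, rRNA/tRNA/snRNA/snoRNA,
  repeats) are embedded verbatim into a reserved tail of "host" transcripts
  so that contaminant-derived reads map to the transcriptome exactly, the
  way assembled transcriptomes carry structural-RNA and repeat content.
* piRNA 5' and position-10 base biases are written back into the
  transcriptome before sequences are extracted, so every truth record's
  origin coordinates reproduce its sequence exactly from the emitted FASTA.
* Coordinates are 0-based half-open internally and 1-based closed in the
  emitted GFF3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import random_dna_many, revcomp
from .config import SimConfig

NCRNA_KINDS = ("rRNA", "tRNA", "snRNA", "snoRNA")
SET_NAMES = ("mirna", "rrna", "trna", "snrna", "snorna", "repeat")

TRUTH_COLUMNS = [
    "seq_id", "sequence", "length", "class", "transcript_id", "start", "end",
    "strand", "feature", "sex_category", "true_log2fc", "mean_ovary", "mean_testis",
]


@dataclass
class ReferenceBundle:
    """Named reference sets plus gene models for one synthetic world."""

    transcripts: dict[str, str]
    gene_models: pd.DataFrame  # transcript_id, feature, start, end (0-based, half-open)
    sets: dict[str, dict[str, str]]  # set name -> {seq id -> sequence}
    known_pirna: dict[str, str]
    host_ids: set[str] = field(default_factory=set)
    _world: "World | None" = field(default=None, repr=False, compare=False)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_fasta(out / "transcriptome.fasta", self.transcripts)
        for name, seqs in self.sets.items():
            _write_fasta(out / f"{name}.fasta", seqs)
        _write_fasta(out / "known_pirna.fasta", self.known_pirna)
        _write_gff3(out / "gene_models.gff3", self.gene_models)

    @classmethod
    def load(cls, ref_dir: str | Path) -> "ReferenceBundle":
        ref_dir = Path(ref_dir)
        sets = {}
        for name in SET_NAMES:
            path = ref_dir / f"{name}.fasta"
            sets[name] = _read_fasta(path) if path.exists() else {}
        return cls(
            transcripts=_read_fasta(ref_dir / "transcriptome.fasta"),
            gene_models=_read_gff3(ref_dir / "gene_models.gff3"),
            sets=sets,
            known_pirna=_read_fasta(ref_dir / "known_pirna.fasta"),
        )


@dataclass
class World:
    """Full generative state for one SimConfig: reference + pool + truth."""

    config: SimConfig
    reference: ReferenceBundle
    truth: pd.DataFrame  # one row per distinct simulated sequence


# ---------------------------------------------------------------------------
# FASTA / GFF3 plumbing (Biopython for parsing; writing is line-oriented)

def _write_fasta(path: Path, seqs: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


_GFF_TYPES = {"five_prime_UTR", "CDS", "three_prime_UTR"}


def _write_gff3(path: Path, models: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in models.itertuples(index=False):
            # 0-based half-open -> 1-based closed
            fh.write(
                f"{row.transcript_id}\tgonadpi_sim\t{row.feature}\t"
                f"{row.start + 1}\t{row.end}\t.\t+\t.\tID={row.transcript_id}.{row.feature}\n"
            )


def _read_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] not in _GFF_TYPES:
                continue
            rows.append((f[0], f[2], int(f[3]) - 1, int(f[4])))
    return pd.DataFrame(rows, columns=["transcript_id", "feature", "start", "end"])


# ---------------------------------------------------------------------------
# world generation

def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


def _feature_spans(length: int, fractions: tuple[float, float, float]):
    """Partition [0, length) into 5'UTR/CDS/3'UTR spans by fractions."""
    f5, _, f3 = fractions
    l5 = int(round(length * f5))
    l3 = int(round(length * f3))
    l5 = min(l5, length)
    l3 = min(l3, length - l5)
    return [
        ("five_prime_UTR", 0, l5),
        ("CDS", l5, length - l3),
        ("three_prime_UTR", length - l3, length),
    ]


def _feature_of(spans, start: int, end: int) -> str:
    """Majority-overlap feature of [start, end); ties CDS > 3'UTR > 5'UTR."""
    prio = {"CDS": 0, "three_prime_UTR": 1, "five_prime_UTR": 2}
    best, best_ov = "unannotated", 0
    for feat, s, e in sorted(spans, key=lambda t: prio[t[0]]):
        ov = max(0, min(end, e) - max(start, s))
        if ov > best_ov:
            best, best_ov = feat, ov
    return best


def _shuffled_decoy(rng: np.random.Generator, seq: str, forbidden: set[str]) -> str:
    letters = list(seq)
    for _ in range(50):
        rng.shuffle(letters)
        cand = "".join(letters)
        if cand not in forbidden:
            return cand
    return "".join(letters)  # pathological low-complexity input; accept


def build_world(config: SimConfig) -> World:
    """Generate the complete synthetic world deterministically from config."""
    config.validate()
    rng_ref = _stage_rng(config.seed, 1)
    lo, hi = config.transcript_length_range

    n = config.n_genes
    lengths = rng_ref.integers(lo, hi + 1, size=n) if n else np.array([], dtype=int)
    tids = [f"TR{i + 1:05d}" for i in range(n)]
    seqs = random_dna_many(rng_ref, lengths)
    transcripts = dict(zip(tids, seqs))

    # contaminant reference sets
    mirna = {
        f"miR-{i + 1}": s
        for i, s in enumerate(
            _biased_smallrna(rng_ref, config.n_mirna, lo_len=20, hi_len=24, p_5u=0.8)
        )
    }
    ncrna_sets: dict[str, dict[str, str]] = {k.lower(): {} for k in NCRNA_KINDS}
    kinds = [NCRNA_KINDS[i % len(NCRNA_KINDS)] for i in range(config.n_ncrna)]
    nc_lengths = rng_ref.integers(60, 121, size=config.n_ncrna)
    for i, (kind, s) in enumerate(zip(kinds, random_dna_many(rng_ref, nc_lengths))):
        ncrna_sets[kind.lower()][f"{kind}-{i + 1}"] = s
    rep_lengths = rng_ref.integers(60, 201, size=config.n_repeat)
    repeats = {
        f"REP-{i + 1}": s for i, s in enumerate(random_dna_many(rng_ref, rep_lengths))
    }

    # embed contaminant sources into a reserved tail of host transcripts
    n_hosts = min(n, max(1, n // 10)) if n else 0
    host_ids = set(tids[-n_hosts:]) if n_hosts else set()
    contaminant_seqs = (
        list(mirna.values())
        + [s for d in ncrna_sets.values() for s in d.values()]
        + list(repeats.values())
    )
    if contaminant_seqs and not host_ids:
        warnings.warn("no transcripts available to host contaminant sequences")
    embedded: set[str] = set()
    contaminant_items = (
        list(mirna.items())
        + [kv for d in ncrna_sets.values() for kv in d.items()]
        + list(repeats.items())
    )
    if host_ids:
        hosts = sorted(host_ids)
        occupied: dict[str, list[tuple[int, int]]] = {t: [] for t in hosts}
        for cid, seq in contaminant_items:
            candidates = [t for t in hosts if len(transcripts[t]) >= len(seq)]
            if not candidates:
                continue
            # place without overlapping earlier embeddings so every planted
            # contaminant survives verbatim in the emitted transcriptome
            for _ in range(60):
                t = candidates[int(rng_ref.integers(len(candidates)))]
                pos = int(rng_ref.integers(0, len(transcripts[t]) - len(seq) + 1))
                if all(pos + len(seq) <= s or pos >= e for s, e in occupied[t]):
                    occupied[t].append((pos, pos + len(seq)))
                    transcripts[t] = (
                        transcripts[t][:pos] + seq + transcripts[t][pos + len(seq):]
                    )
                    embedded.add(cid)
                    break

    # gene models over final transcript lengths
    model_rows = [
        (tid, feat, s, e)
        for tid in tids
        for feat, s, e in _feature_spans(len(transcripts[tid]), config.utr_fractions)
        if e > s
    ]
    gene_models = pd.DataFrame(
        model_rows, columns=["transcript_id", "feature", "start", "end"]
    )
    spans_by_tid: dict[str, list] = {}
    for tid, feat, s, e in model_rows:
        spans_by_tid.setdefault(tid, []).append((feat, s, e))

    # piRNA pool: choose origins, write biases back into the transcriptome,
    # then extract all sequences from the final mutated transcripts
    rng_pool = _stage_rng(config.seed, 2)
    origin_tids = [
        t for t in tids if t not in host_ids and len(transcripts[t]) >= 32
    ]
    n_pirna = config.n_pirna
    if n_pirna and not origin_tids:
        warnings.warn("no transcript of >=32 nt available; piRNA pool left empty")
        n_pirna = 0
    short = [t for t in tids if len(transcripts[t]) < 32]
    if short and n_pirna:
        warnings.warn(f"{len(short)} transcripts shorter than 32 nt skipped as piRNA origins")

    mutable = {t: list(transcripts[t]) for t in origin_tids}
    lengths_supp = np.array(sorted(config.pirna_length_weights), dtype=int)
    lengths_prob = np.array([config.pirna_length_weights[k] for k in lengths_supp])
    pir_origins = []
    for _ in range(n_pirna):
        tid = origin_tids[int(rng_pool.integers(len(origin_tids)))]
        L = int(rng_pool.choice(lengths_supp, p=lengths_prob))
        tlen = len(mutable[tid])
        start = int(rng_pool.integers(0, tlen - L + 1))
        antisense = bool(rng_pool.random() < config.antisense_fraction)
        # force read-frame base 1 (5'U) and base 10 (A), written to transcript;
        # the "else" branch draws uniformly from the complementary bases so the
        # realised bias equals the configured probability exactly
        read_base1 = (
            "T" if rng_pool.random() < config.p_5prime_U
            else "ACG"[int(rng_pool.integers(3))]
        )
        read_base10 = (
            "A" if rng_pool.random() < config.p_pos10_A
            else "CGT"[int(rng_pool.integers(3))]
        )
        _write_read_base(mutable[tid], start, L, antisense, 0, read_base1)
        if L >= 10:
            _write_read_base(mutable[tid], start, L, antisense, 9, read_base10)
        pir_origins.append((tid, start, L, antisense))
    for tid in mutable:
        transcripts[tid] = "".join(mutable[tid])

    # sex classes
    cls_names = list(config.sex_class_proportions)
    cls_probs = np.array([config.sex_class_proportions[c] for c in cls_names])
    truth_rows = []
    seen: dict[str, int] = {}
    for i, (tid, start, L, antisense) in enumerate(pir_origins):
        seq = transcripts[tid][start : start + L]
        if antisense:
            seq = revcomp(seq)
        sex = cls_names[int(rng_pool.choice(len(cls_names), p=cls_probs))]
        if sex == "ovary_only":
            lfc = np.inf
        elif sex == "testis_only":
            lfc = -np.inf
        elif sex == "biased":
            lfc = config.biased_log2fc * (1 if rng_pool.random() < 0.5 else -1)
        else:
            lfc = 0.0
        feature = _feature_of(spans_by_tid.get(tid, []), start, start + L)
        if seq in seen:
            continue  # identical sequences collapse to one truth record
        seen[seq] = i
        truth_rows.append(
            dict(
                seq_id=f"piR-{len(truth_rows) + 1:05d}", sequence=seq, length=L,
                klass="piRNA", transcript_id=tid, start=start, end=start + L,
                strand="-" if antisense else "+", feature=feature,
                sex_category=sex, true_log2fc=lfc,
            )
        )

    # contaminant-derived and unclassified reads
    rng_bg = _stage_rng(config.seed, 3)

    def _add_fragments(source: dict[str, str], n: int, klass: str, lo_l: int, hi_l: int):
        items = [(k, v) for k, v in source.items() if len(v) >= lo_l]
        for _ in range(n):
            if not items:
                break
            sid, sseq = items[int(rng_bg.integers(len(items)))]
            L = int(rng_bg.integers(lo_l, min(hi_l, len(sseq)) + 1))
            start = int(rng_bg.integers(0, len(sseq) - L + 1))
            frag = sseq[start : start + L]
            if frag in seen:
                continue
            seen[frag] = 1
            truth_rows.append(
                dict(
                    seq_id=f"{klass}-read-{len(truth_rows) + 1:05d}", sequence=frag,
                    length=L, klass=klass, transcript_id=sid, start=start,
                    end=start + L, strand="+", feature="unannotated",
                    sex_category="shared", true_log2fc=0.0,
                )
            )

    for mid, mseq in mirna.items():
        if mseq in seen or mid not in embedded:
            continue
        seen[mseq] = 1
        truth_rows.append(
            dict(
                seq_id=f"miRNA-read-{len(truth_rows) + 1:05d}", sequence=mseq,
                length=len(mseq), klass="miRNA", transcript_id=mid, start=0,
                end=len(mseq), strand="+", feature="unannotated",
                sex_category="shared", true_log2fc=0.0,
            )
        )
    # fragments are drawn only from contaminant sources that were embedded,
    # so every contaminant read maps to the transcriptome
    nc_all = {k: v for d in ncrna_sets.values() for k, v in d.items() if k in embedded}
    _add_fragments(nc_all, config.n_ncrna * 3, "ncRNA", 18, 32)
    _add_fragments({k: v for k, v in repeats.items() if k in embedded},
                   config.n_repeat * 3, "repeat", 18, 32)
    # "other": mapped transcript fragments outside every annotation class
    other_src = {t: transcripts[t] for t in origin_tids}
    _add_fragments(other_src, config.n_other, "other", 18, 25)

    truth = pd.DataFrame(truth_rows).rename(columns={"klass": "class"})
    if truth.empty:
        truth = pd.DataFrame(columns=TRUTH_COLUMNS[:-2])

    # expected per-library mean counts
    rng_expr = _stage_rng(config.seed, 4)
    n_seq = len(truth)
    mean_o = np.zeros(n_seq)
    mean_t = np.zeros(n_seq)
    if n_seq:
        weights = rng_expr.lognormal(mean=0.0, sigma=1.0, size=n_seq)
        # per-library expected count: abundance weight scaled so each library
        # totals roughly depth_per_library
        base = weights / weights.sum() * config.depth_per_library
        cls = truth["class"].to_numpy()
        sex = truth["sex_category"].to_numpy()
        lfc = truth["true_log2fc"].to_numpy(dtype=float)
        fo = np.ones(n_seq)
        ft = np.ones(n_seq)
        is_pir = cls == "piRNA"
        m = is_pir & (sex == "ovary_only")
        fo[m], ft[m] = 2.0, 0.0
        m = is_pir & (sex == "testis_only")
        fo[m], ft[m] = 0.0, 2.0
        m = is_pir & (sex == "biased")
        fo[m] = 2.0 ** (lfc[m] / 2)
        ft[m] = 2.0 ** (-lfc[m] / 2)
        mean_o = base * fo
        mean_t = base * ft
    truth["mean_ovary"] = mean_o
    truth["mean_testis"] = mean_t

    ref = ReferenceBundle(
        transcripts=transcripts,
        gene_models=gene_models,
        sets={"mirna": mirna, **ncrna_sets, "repeat": repeats},
        known_pirna={},
        host_ids=host_ids,
    )

    # known-piRNA set: planted homologs from the pool plus shuffled decoys
    rng_known = _stage_rng(config.seed, 5)
    pir_seqs = truth.loc[truth["class"] == "piRNA", "sequence"].tolist()
    n_known = min(config.n_known, len(pir_seqs))
    chosen = rng_known.choice(len(pir_seqs), size=n_known, replace=False) if n_known else []
    known = {f"known-piR-{j + 1:04d}": pir_seqs[int(i)] for j, i in enumerate(chosen)}
    all_seqs = set(truth["sequence"])
    for j in range(config.n_known_decoys):
        src = pir_seqs[int(rng_known.integers(len(pir_seqs)))] if pir_seqs else None
        if src is None:
            break
        known[f"decoy-piR-{j + 1:04d}"] = _shuffled_decoy(rng_known, src, all_seqs)
    ref.known_pirna = known

    world = World(config=config, reference=ref, truth=truth)
    ref._world = world
    return world


def _write_read_base(
    chars: list[str], start: int, L: int, antisense: bool, read_pos: int, base: str
) -> None:
    """Set the transcript base so the read's position `read_pos` equals `base`."""
    if antisense:
        chars[start + L - 1 - read_pos] = revcomp(base)
    else:
        chars[start + read_pos] = base


def _biased_smallrna(rng, n: int, lo_len: int, hi_len: int, p_5u: float) -> list[str]:
    lengths = rng.integers(lo_len, hi_len + 1, size=n)
    seqs = random_dna_many(rng, lengths)
    out = []
    for s in seqs:
        if s and rng.random() < p_5u:
            s = "T" + s[1:]
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# public operations

def build_reference(config: SimConfig, out_dir: str | Path | None = None) -> ReferenceBundle:
    """Build (and optionally write) the reference bundle for a config."""
    ref = build_world(config).reference
    if out_dir is not None:
        ref.write(out_dir)
    return ref


def simulate_pirna_pool(config: SimConfig, ref: ReferenceBundle):
    """Return (piRNA sequences, full truth table) for the world behind `ref`.

    `ref` must come from :func:`build_reference` with the same config; the
    truth table also carries the contaminant and background classes so that
    annotation recovery can be scored per read.
    """
    if ref._world is None or ref._world.config != config:
        raise ValueError("reference bundle does not belong to this SimConfig")
    truth = ref._world.truth
    return truth.loc[truth["class"] == "piRNA", "sequence"].tolist(), truth


def library_names(config: SimConfig) -> list[str]:
    return [f"ovary{i + 1}" for i in range(config.libraries_per_sex)] + [
        f"testis{i + 1}" for i in range(config.libraries_per_sex)
    ]


def simulate_libraries(
    config: SimConfig, truth: pd.DataFrame, out_dir: str | Path
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Emit per-library FASTQ files and the drawn true count table.

    Counts are negative binomial around the truth table's per-sex means
    (Poisson in the dispersion -> 0 limit); ovary-only sequences never
    appear in testis libraries and vice versa.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = _stage_rng(config.seed, 6)
    libs = library_names(config)
    data = {}
    for lib in libs:
        sex = "ovary" if lib.startswith("ovary") else "testis"
        means = truth[f"mean_{sex}"].to_numpy(dtype=float)
        data[lib] = _nb_draw(rng, means, config.nb_dispersion)
    counts = pd.DataFrame(data, index=pd.Index(truth["sequence"], name="sequence"))

    paths = {}
    for lib in libs:
        path = out / f"{lib}.fastq"
        with open(path, "w") as fh:
            i = 0
            for seq, c in zip(truth["sequence"], counts[lib]):
                emit = seq + (config.adapter or "")
                for _ in range(int(c)):
                    i += 1
                    if config.low_quality_fraction and rng.random() < config.low_quality_fraction:
                        qual = "+" * len(emit)  # Q10
                    else:
                        qual = "I" * len(emit)  # Q40
                    fh.write(f"@{lib}_read{i}\n{emit}\n+\n{qual}\n")
        paths[lib] = path
    counts = counts.reset_index().rename(columns={"index": "sequence"})
    counts.insert(0, "seq_id", truth["seq_id"].to_numpy())
    counts.to_csv(out / "true_counts.tsv", sep="\t", index=False)
    return paths, counts


def _nb_draw(rng: np.random.Generator, means: np.ndarray, dispersion: float) -> np.ndarray:
    out = np.zeros(len(means), dtype=int)
    pos = means > 0
    if dispersion <= 1e-9:
        out[pos] = rng.poisson(means[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + means[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_microarray(
    config: SimConfig, probe_truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate single-channel microarray raw + background matrices.

    `probe_truth` is a slice of the truth table (one row per probe). Returns
    (raw, background, high_cv_flag), each indexed by seq_id with one column
    per sample-replicate spot (e.g. ``ovary1_r2``). Spot intensity is
    background + signal x 2^(group effect) x lognormal noise; a configured
    fraction of probes receives inflated replicate noise to exercise the
    CV filter.
    """
    if probe_truth.empty:
        raise ValueError("probe set is empty")
    if config.array_replicates < 1:
        raise ValueError("array_replicates must be >= 1")
    rng = _stage_rng(config.seed, 7)
    samples = [f"ovary{i + 1}" for i in range(config.array_samples_per_sex)] + [
        f"testis{i + 1}" for i in range(config.array_samples_per_sex)
    ]
    cols = [f"{s}_r{r + 1}" for s in samples for r in range(config.array_replicates)]
    n = len(probe_truth)
    signal = config.array_signal_mean * rng.lognormal(0.0, 0.8, size=n)
    high_cv = pd.Series(rng.random(n) < config.array_high_cv_fraction,
                        index=probe_truth["seq_id"].to_numpy())

    raw = np.zeros((n, len(cols)))
    bg = np.zeros((n, len(cols)))
    lfc = probe_truth["true_log2fc"].to_numpy(dtype=float)
    sexcat = probe_truth["sex_category"].to_numpy()
    for i in range(n):
        if sexcat[i] == "ovary_only":
            fo, ft = 2.0, 2.0 * config.array_crosshyb
        elif sexcat[i] == "testis_only":
            fo, ft = 2.0 * config.array_crosshyb, 2.0
        elif np.isfinite(lfc[i]) and lfc[i] != 0:
            fo, ft = 2.0 ** (lfc[i] / 2), 2.0 ** (-lfc[i] / 2)
        else:
            fo = ft = 1.0
        cv = config.array_high_cv_level if high_cv.iloc[i] else config.array_noise_cv
        for j, col in enumerate(cols):
            factor = fo if col.startswith("ovary") else ft
            noise = _lognormal_unit_mean(rng, cv)
            bg_noise = _lognormal_unit_mean(rng, config.array_noise_cv)
            bg[i, j] = config.array_background_mean * bg_noise
            raw[i, j] = bg[i, j] + signal[i] * factor * noise

    idx = probe_truth["seq_id"].to_numpy()
    return (
        pd.DataFrame(raw, index=idx, columns=cols),
        pd.DataFrame(bg, index=idx, columns=cols),
        high_cv,
    )


def _lognormal_unit_mean(rng: np.random.Generator, cv: float) -> float:
    """Lognormal draw with mean 1 and the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(rng.lognormal(-sigma2 / 2, np.sqrt(sigma2)))


def simulate_term_map(
    config: SimConfig,
    genes: list[str],
    n_terms: int = 30,
    enriched_terms: int = 2,
    study_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Random term-to-gene map (term_id, gene_id, term_name).

    Terms get 5-60 member genes; `enriched_terms` terms are stacked with
    `study_genes` members so that enrichment has planted positives.
    """
    rng = _stage_rng(config.seed, 8)
    rows = []
    study = list(study_genes or [])
    for t in range(n_terms):
        term = f"TERM:{t + 1:04d}"
        size = int(rng.integers(5, min(61, max(6, len(genes)))))
        members = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
        if t < enriched_terms and study:
            planted = list(
                rng.choice(study, size=min(len(study), max(3, size // 2)), replace=False)
            )
            members = sorted(set(members) | set(planted))
        for g in members:
            rows.append((term, g, f"synthetic term {t + 1}"))
    return pd.DataFrame(rows, columns=["term_id", "gene_id", "term_name"])
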