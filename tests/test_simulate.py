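"""Synthetic-world generator: determinism, truth consistency, bias forcing."""

import warnings

import numpy as np
import pandas as pd
import pytest

from gonadpi._seq import revcomp
from gonadpi.config import SimConfig
from gonadpi.simulate import (
    ReferenceBundle, build_reference, build_world, simulate_libraries,
    simulate_microarray, simulate_pirna_pool,
)


def test_empty_world_yields_empty_but_valid_outputs(tmp_path):
    cfg = SimConfig(seed=1, n_genes=0, n_pirna=0, n_mirna=0, n_ncrna=0,
                    n_repeat=0, n_other=0, n_known=0, n_known_decoys=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = build_reference(cfg, tmp_path)
    assert ref.transcripts == {}
    assert ref.gene_models.empty
    assert (tmp_path / "transcriptome.fasta").read_text() == ""
    loaded = ReferenceBundle.load(tmp_path)
    assert loaded.transcripts == {}


def test_same_seed_byte_identical_outputs(tmp_path):
    cfg = SimConfig(seed=5, n_genes=20, n_pirna=50, depth_per_library=500,
                    n_mirna=5, n_ncrna=4, n_repeat=3, n_other=5)
    outs = []
    for sub in ("a", "b"):
        d = tmp_path / sub
        world = build_world(cfg)
        world.reference.write(d / "ref")
        simulate_libraries(cfg, world.truth, d / "reads")
        blob = b"".join(
            p.read_bytes() for p in sorted((d / "ref").iterdir())
        ) + b"".join(p.read_bytes() for p in sorted((d / "reads").iterdir()))
        outs.append(blob)
    assert outs[0] == outs[1]


def test_gene_model_spans_partition_transcripts():
    """utr_fractions (0.1, 0.7, 0.2) on 1000 nt -> spans 100/700/200 (+-1)."""
    cfg = SimConfig(seed=2, n_genes=10, transcript_length_range=(1000, 1000),
                    utr_fractions=(0.1, 0.7, 0.2), n_pirna=0, n_mirna=0,
                    n_ncrna=0, n_repeat=0, n_other=0, n_known=0, n_known_decoys=0)
    ref = build_reference(cfg)
    gm = ref.gene_models
    assert set(gm["transcript_id"]) == set(ref.transcripts)
    for tid, sub in gm.groupby("transcript_id"):
        sub = sub.sort_values("start")
        assert sub.iloc[0]["start"] == 0
        assert sub.iloc[-1]["end"] == len(ref.transcripts[tid]) == 1000
        # contiguous, non-overlapping
        assert (sub["start"].iloc[1:].to_numpy() == sub["end"].iloc[:-1].to_numpy()).all()
        widths = dict(zip(sub["feature"], sub["end"] - sub["start"]))
        assert abs(widths["five_prime_UTR"] - 100) <= 1
        assert abs(widths["CDS"] - 700) <= 1
        assert abs(widths["three_prime_UTR"] - 200) <= 1


def test_forced_5prime_u_bias_is_total_when_p_is_one():
    cfg = SimConfig(seed=3, n_genes=40, n_pirna=100, p_5prime_U=1.0,
                    n_mirna=0, n_ncrna=0, n_repeat=0, n_other=0)
    ref = build_reference(cfg)
    seqs, truth = simulate_pirna_pool(cfg, ref)
    assert len(seqs) == 100
    assert all(s.startswith("T") for s in seqs)
    assert set(truth.loc[truth["class"] == "piRNA", "length"]) <= set(range(26, 33))


def test_pool_biases_within_3se_of_configured():
    cfg = SimConfig(seed=4, n_genes=600, n_pirna=10_000, p_5prime_U=0.8,
                    transcript_length_range=(500, 2500),
                    n_mirna=0, n_ncrna=0, n_repeat=0, n_other=0)
    ref = build_reference(cfg)
    seqs, _ = simulate_pirna_pool(cfg, ref)
    frac = np.mean([s[0] == "T" for s in seqs])
    se = np.sqrt(0.8 * 0.2 / len(seqs))
    assert abs(frac - 0.8) <= 3 * se


def test_origin_coordinates_reproduce_sequences(small_world):
    """Re-extracting each truth origin from the transcriptome gives the sequence."""
    ref = small_world.reference
    pir = small_world.truth[small_world.truth["class"] == "piRNA"]
    for row in pir.itertuples(index=False):
        frag = ref.transcripts[row.transcript_id][row.start:row.end]
        if row.strand == "-":
            frag = revcomp(frag)
        assert frag == row.sequence


def test_truth_covers_every_emitted_read(small_world, small_libraries):
    paths, counts = small_libraries
    truth_seqs = set(small_world.truth["sequence"])
    from Bio import SeqIO

    for lib, path in paths.items():
        for rec in SeqIO.parse(str(path), "fastq"):
            assert str(rec.seq) in truth_seqs


def test_sex_classes_respected_in_counts(small_world, small_libraries):
    _, counts = small_libraries
    truth = small_world.truth
    merged = truth.merge(counts, on="sequence", suffixes=("", "_c"))
    ovary_only = merged[(merged["class"] == "piRNA") & (merged.sex_category == "ovary_only")]
    assert (ovary_only[["testis1", "testis2"]].to_numpy() == 0).all()
    testis_only = merged[(merged["class"] == "piRNA") & (merged.sex_category == "testis_only")]
    assert (testis_only[["ovary1", "ovary2"]].to_numpy() == 0).all()


def test_zero_depth_gives_empty_fastq(tmp_path):
    cfg = SimConfig(seed=6, n_genes=20, n_pirna=30, depth_per_library=0,
                    n_mirna=0, n_ncrna=0, n_repeat=0, n_other=0)
    world = build_world(cfg)
    paths, counts = simulate_libraries(cfg, world.truth, tmp_path)
    assert len(paths) == 4
    for p in paths.values():
        assert p.read_text() == ""


def test_shared_class_frequencies_near_expected_at_low_dispersion(tmp_path):
    """Poisson limit: per-library counts track truth means (law of large numbers)."""
    cfg = SimConfig(seed=7, n_genes=100, n_pirna=300, depth_per_library=60_000,
                    nb_dispersion=0.0, n_mirna=0, n_ncrna=0, n_repeat=0, n_other=0)
    world = build_world(cfg)
    _, counts = simulate_libraries(cfg, world.truth, tmp_path)
    merged = world.truth.merge(counts, on="sequence")
    shared = merged[merged.sex_category == "shared"]
    big = shared[shared["mean_ovary"] >= 50]
    assert len(big) > 5
    lam = big["mean_ovary"].to_numpy()
    obs = big["ovary1"].to_numpy()
    assert (np.abs(obs - lam) <= 3 * np.sqrt(lam) + 1).all()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(utr_fractions=(0.5, 0.6, 0.2)).validate()
    with pytest.raises(ValueError):
        SimConfig(p_5prime_U=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(pirna_length_weights={20: 1.0}).validate()
    with pytest.raises(ValueError):
        SimConfig(array_replicates=0).validate()


class TestMicroarraySim:
    def _probe_truth(self, n, lfc=2.0):
        return pd.DataFrame({
            "seq_id": [f"P{i:04d}" for i in range(n)],
            "sequence": ["ACGT"] * n,
            "sex_category": ["biased"] * n,
            "true_log2fc": [lfc] * n,
        })

    def test_zero_noise_replicates_identical(self):
        cfg = SimConfig(seed=8, array_noise_cv=0.0, array_high_cv_fraction=0.0)
        raw, bg, _ = simulate_microarray(cfg, self._probe_truth(5))
        for s in ("ovary1", "testis3"):
            cols = [c for c in raw.columns if c.startswith(s + "_")]
            assert np.allclose(raw[cols].to_numpy().std(axis=1), 0.0)

    def test_zero_noise_logfc2_means_ratio_4(self):
        cfg = SimConfig(seed=8, array_noise_cv=0.0, array_high_cv_fraction=0.0)
        raw, bg, _ = simulate_microarray(cfg, self._probe_truth(3, lfc=2.0))
        sub = raw - bg
        ov = sub[[c for c in sub.columns if c.startswith("ovary")]].mean(axis=1)
        te = sub[[c for c in sub.columns if c.startswith("testis")]].mean(axis=1)
        assert np.allclose(ov / te, 4.0)

    def test_high_cv_injection_fails_cv_filter(self):
        from gonadpi.expression import replicate_cv

        cfg = SimConfig(seed=9, array_noise_cv=0.05, array_high_cv_fraction=0.1,
                        array_high_cv_level=0.6)
        raw, bg, flags = simulate_microarray(cfg, self._probe_truth(1000, lfc=0.0))
        sub = (raw - bg).clip(lower=0)
        cols = [c for c in raw.columns if c.startswith("ovary1_")]
        cv = sub[cols].apply(lambda r: replicate_cv(r.to_numpy()), axis=1)
        flagged = flags[flags].index
        # at least 90% of intentionally noisy probes fail CV < 0.3 somewhere
        fail_any = pd.Series(False, index=raw.index)
        for s in ("ovary1", "ovary2", "ovary3", "testis1", "testis2", "testis3"):
            cc = [c for c in raw.columns if c.startswith(s + "_")]
            fail_any |= sub[cc].apply(lambda r: replicate_cv(r.to_numpy()), axis=1) >= 0.3
        assert fail_any.loc[flagged].mean() >= 0.9

    def test_replicates_below_one_rejected(self):
        cfg = SimConfig(seed=8, array_replicates=0)
        with pytest.raises(ValueError):
            simulate_microarray(cfg, self._probe_truth(3))


def test_pool_rejects_foreign_reference():
    cfg_a = SimConfig(seed=1, n_genes=10, n_pirna=5, n_mirna=0, n_ncrna=0,
                      n_repeat=0, n_other=0)
    cfg_b = SimConfig(seed=2, n_genes=10, n_pirna=5, n_mirna=0, n_ncrna=0,
                      n_repeat=0, n_other=0)
    ref_a = build_reference(cfg_a)
    with pytest.raises(ValueError):
        simulate_pirna_pool(cfg_b, ref_a)
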