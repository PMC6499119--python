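"""End-to-end pipeline: simulate -> clean -> annotate -> classify -> report.

Each stage writes its table under the run directory and can be re-run from
the previous stage's outputs; all randomness derives from the single
configured seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seq import random_dna_many
from .cascade import annotate_cascade, summarize_annotation
from .classifier import classify, match_known, train_fisher
from .config import PipelineConfig, SimConfig
from .enrichment import enrich, map_pirnas_to_genes, sex_partition
from .expression import (
    array_pipeline, cluster_biased, platform_concordance,
    select_array_candidates, seq_de_table,
)
from .index import build_exact_index
from .reads import clean_and_collapse
from .report import RunReport
from .signatures import (
    feature_distribution, length_distribution, position_base_frequencies,
    strand_composition,
)
from .simulate import (
    build_world, simulate_libraries, simulate_term_map,
)

log = logging.getLogger("gonadpi")


def sample_training_sets(
    config: SimConfig, transcripts: dict[str, str], n_per_class: int, seed: int
) -> tuple[list[str], list[str]]:
    """Draw classifier training sets from the generative model.

    Positives are 26-32 nt fragments with the configured 5'U/10A biases
    applied; negatives are unbiased random-composition sequences of the
    same lengths (a stand-in for curated non-piRNA training sets).
    """
    rng = np.random.default_rng([9, seed])
    lengths = np.array(sorted(config.pirna_length_weights))
    probs = np.array([config.pirna_length_weights[k] for k in lengths])
    tids = [t for t in transcripts if len(transcripts[t]) >= 32]
    pos = []
    for _ in range(n_per_class):
        L = int(rng.choice(lengths, p=probs))
        if tids:
            t = tids[int(rng.integers(len(tids)))]
            s = int(rng.integers(0, len(transcripts[t]) - L + 1))
            seq = list(transcripts[t][s : s + L])
        else:
            seq = list(random_dna_many(rng, [L])[0])
        seq[0] = "T" if rng.random() < config.p_5prime_U else "ACG"[int(rng.integers(3))]
        if L >= 10:
            seq[9] = "A" if rng.random() < config.p_pos10_A else "CGT"[int(rng.integers(3))]
        pos.append("".join(seq))
    neg_lengths = rng.choice(lengths, p=probs, size=n_per_class)
    neg = random_dna_many(rng, neg_lengths)
    return pos, neg


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis on a simulated world and emit all stage outputs."""
    config.sim.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    report = RunReport(config_hash=config.config_hash(), tool_version=__version__)

    # stage 1: simulate
    log.info("stage simulate: building synthetic world (seed=%d)", config.sim.seed)
    world = build_world(config.sim)
    ref = world.reference
    ref.write(out / "reference")
    fastq_paths, true_counts = simulate_libraries(config.sim, world.truth, out / "reads")
    world.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    report.add("simulate", "n_truth_sequences", len(world.truth))

    # stage 2: clean + collapse
    table, qcs = clean_and_collapse(
        fastq_paths, min_quality=config.min_quality,
        length_window=config.length_window, adapter=config.sim.adapter,
    )
    log.info("stage clean: %d unique reads", len(table))
    pd.DataFrame([q.as_dict() for q in qcs]).to_csv(out / "library_qc.tsv", sep="\t", index=False)
    table.to_csv(out / "unique_reads.tsv", sep="\t", index=False)
    report.add("clean", "unique_reads", len(table))
    report.add("clean", "qc", [q.as_dict() for q in qcs])
    if table.empty:
        log.warning("no reads survived cleaning; emitting empty report")
        report.to_json(out / "report.json")
        return report

    # stage 3: annotation cascade
    index = build_exact_index(ref)
    labelled = annotate_cascade(table, ref, index)
    summary = summarize_annotation(labelled)
    labelled.to_csv(out / "annotated_reads.tsv", sep="\t", index=False)
    summary.to_csv(out / "annotation_summary.tsv", sep="\t", index=False)
    report.add("annotate", "summary", summary.to_dict(orient="records"))
    log.info("stage annotate: %d mapped / %d unique reads",
             int((labelled["label"] != "unmapped").sum()), len(labelled))

    # stage 4: classifier
    pos, neg = sample_training_sets(config.sim, ref.transcripts, 1000, config.seed)
    model = train_fisher(pos, neg, kmax=5, seed=config.seed)
    model.to_json(out / "classifier_model.json")
    candidates = labelled[labelled["label"] == "piRNA_candidate"]
    if candidates.empty:
        predictions = candidates.assign(score=[], predicted_pirna=[])
        predicted = candidates
    else:
        scored = classify(candidates["sequence"].tolist(), model)
        predictions = candidates.merge(scored, on="sequence")
        predicted = predictions[predictions["predicted_pirna"]]
    predictions.to_csv(out / "pirna_predictions.tsv", sep="\t", index=False)
    report.add_fraction("classify", "predicted_of_candidates",
                        len(predicted), max(len(candidates), 1))
    homologs = match_known(predicted["sequence"], ref.known_pirna)
    report.add("classify", "known_homologs", len(homologs))
    log.info("stage classify: %d/%d candidates predicted as piRNA, %d known homologs",
             len(predicted), len(candidates), len(homologs))

    # stage 5: signatures
    if not predicted.empty:
        pfm = position_base_frequencies(predicted["sequence"].tolist())
        report.add("signatures", "fraction_U_at_1", pfm.fraction_U_at_1)
        report.add("signatures", "fraction_A_at_10", pfm.fraction_A_at_10)
        sc = strand_composition(predicted["hit_strand"].tolist())
        report.add("signatures", "strand", sc)
        ld = length_distribution(labelled["length"], labelled["label"])
        ld.to_csv(out / "length_distribution.tsv", sep="\t")
        fd = feature_distribution(
            predicted, ref.gene_models,
            {t: len(s) for t, s in ref.transcripts.items()},
        )
        fd.to_csv(out / "feature_distribution.tsv", sep="\t", index=False)
        report.add("signatures", "features", fd.to_dict(orient="records"))

    # stage 6: sequencing expression
    de = seq_de_table(predicted, config.thresholds.seq) if not predicted.empty else pd.DataFrame()
    if not de.empty:
        de.to_csv(out / "seq_expression.tsv", sep="\t", index=False)
        tallies = de["category"].value_counts().to_dict()
        report.add("expression_seq", "categories", tallies)
        for cat in ("ovary_specific", "testis_specific"):
            report.add_fraction("expression_seq", cat, int(tallies.get(cat, 0)), len(de))

    # stage 7: microarray validation
    arr_result = pd.DataFrame()
    if not de.empty:
        cands = select_array_candidates(de, config.thresholds.seq)
        report.add("array", "n_candidates", len(cands))
        probe_truth = world.truth[world.truth["sequence"].isin(cands["sequence"])]
        if not probe_truth.empty:
            from .simulate import simulate_microarray

            raw, bg, _ = simulate_microarray(config.sim, probe_truth)
            raw.to_csv(out / "array_raw.tsv", sep="\t")
            bg.to_csv(out / "array_background.tsv", sep="\t")
            arr_result = array_pipeline(raw, bg, config.thresholds.array)
            arr_result.to_csv(out / "array_result.tsv", sep="\t")
            report.add("array", "categories",
                       arr_result["category"].value_counts().to_dict())
            clades = cluster_biased(arr_result, k=10)
            report.add("array", "n_clades", int(clades.nunique()) if len(clades) else 0)
            biased_ids = arr_result.index[
                arr_result["category"].isin(["ovary_up", "testis_up"])
            ]
            paired = probe_truth.set_index("seq_id").loc[biased_ids]
            seq_lfc_map = de.set_index("sequence")["log2fc"]
            try:
                conc = platform_concordance(
                    seq_lfc_map.loc[paired["sequence"]].to_numpy(),
                    arr_result.loc[biased_ids, "log2fc"].to_numpy(),
                )
                report.add("array", "concordance", conc)
            except ValueError:
                report.add("array", "concordance", None)

    # stage 8: piRNA-generating genes and enrichment
    if not predicted.empty:
        gene_table, gsummary = map_pirnas_to_genes(predicted, index)
        seq_cat = de.set_index("sequence")["category"] if not de.empty else pd.Series(dtype=object)
        ov = set(seq_cat[seq_cat == "ovary_specific"].index)
        te = set(seq_cat[seq_cat == "testis_specific"].index)
        gene_table = sex_partition(gene_table, ov, te)
        gene_table.to_csv(out / "pirna_genes.tsv", sep="\t", index=False)
        report.add("genes", "summary", gsummary)
        report.add("genes", "sex_partition",
                   gene_table["sex_partition"].value_counts().to_dict())
        background = set(gene_table["gene_id"])
        study = set(gene_table.loc[gene_table["sex_partition"] != "none", "gene_id"])
        term_map = simulate_term_map(config.sim, sorted(background), study_genes=sorted(study))
        term_map.to_csv(out / "term_map.tsv", sep="\t", index=False)
        if study and len(term_map):
            enr = enrich(study, background, term_map)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            report.add("enrich", "n_terms", len(enr))
            report.add("enrich", "n_enriched", int(enr["enriched"].sum()))

    report.to_json(out / "report.json")
    log.info("pipeline complete; report at %s", out / "report.json")
    return report
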