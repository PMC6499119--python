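"""Train the k-mer Fisher classifier and predict piRNAs among candidates.

Also benchmarks the k-mer scheme against the position-specific ("static")
baseline on a common held-out split, and counts exact homologs of the
planted known-piRNA set among predictions.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

from common import RESULTS, SCRATCH, SEED, SIM, ensure_dirs
from gonadpi.classifier import classify, compare_kmer_static, match_known, train_fisher
from gonadpi.pipeline import sample_training_sets
from gonadpi.simulate import ReferenceBundle


def main():
    ensure_dirs()
    labelled = pd.read_csv(SCRATCH / "annotated_reads.tsv", sep="\t")
    ref = ReferenceBundle.load(SCRATCH / "reference")

    pos, neg = sample_training_sets(SIM, ref.transcripts, 1000, seed=SEED)
    model = train_fisher(pos, neg, seed=SEED)
    model.to_json(SCRATCH / "classifier_model.json")
    bench = compare_kmer_static(pos, neg, seed=SEED)

    candidates = labelled[labelled["label"] == "piRNA_candidate"]
    scored = classify(candidates["sequence"].tolist(), model)
    predictions = candidates.merge(scored, on="sequence")
    predicted = predictions[predictions["predicted_pirna"]]
    predictions.to_csv(SCRATCH / "pirna_predictions.tsv", sep="\t", index=False)

    homologs = match_known(predicted["sequence"], ref.known_pirna)
    out = {
        "n_candidates": int(len(candidates)),
        "n_predicted": int(len(predicted)),
        "n_known_homologs": len(homologs),
        "kmer_heldout_auroc": bench["kmer_auroc"],
        "static_heldout_auroc": bench["static_auroc"],
    }
    (RESULTS / "03_classifier_summary.json").write_text(json.dumps(out, indent=2))
    print(f"{out['n_predicted']}/{out['n_candidates']} candidates predicted as piRNA; "
          f"{out['n_known_homologs']} exact known-piRNA homologs")
    print(f"held-out AUROC: k-mer {out['kmer_heldout_auroc']:.3f} vs "
          f"static {out['static_heldout_auroc']:.3f} "
          "(the positional scheme sees the positional 5'U/10A bias; the "
          "composition scheme largely cannot)")


if __name__ == "__main__":
    main()
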