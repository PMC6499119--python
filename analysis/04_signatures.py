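"""piRNA signature statistics of the predicted set.

Position-specific base usage (5'U and position-10 A bias), length
distribution per annotation class, sense/antisense composition, and the
genic-feature (5'UTR/CDS/3'UTR) distribution.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

from common import RESULTS, SCRATCH, SIM, ensure_dirs
from gonadpi.signatures import (
    feature_distribution, length_distribution, position_base_frequencies,
    strand_composition,
)
from gonadpi.simulate import ReferenceBundle


def main():
    ensure_dirs()
    ref = ReferenceBundle.load(SCRATCH / "reference")
    labelled = pd.read_csv(SCRATCH / "annotated_reads.tsv", sep="\t")
    predictions = pd.read_csv(SCRATCH / "pirna_predictions.tsv", sep="\t")
    predicted = predictions[predictions["predicted_pirna"]]

    pfm = position_base_frequencies(predicted["sequence"].tolist())
    pfm.freqs.to_csv(RESULTS / "04_position_base_frequencies.tsv", sep="\t")
    ld = length_distribution(labelled["length"], labelled["label"],
                             weights=labelled["total"])
    ld.to_csv(RESULTS / "04_length_distribution.tsv", sep="\t")
    sc = strand_composition(predicted["hit_strand"].tolist())
    fd = feature_distribution(predicted, ref.gene_models,
                              {t: len(s) for t, s in ref.transcripts.items()})
    fd.to_csv(RESULTS / "04_feature_distribution.tsv", sep="\t", index=False)
    (RESULTS / "04_signature_summary.json").write_text(json.dumps({
        "fraction_U_at_1": pfm.fraction_U_at_1,
        "fraction_A_at_10": pfm.fraction_A_at_10,
        "strand": sc,
    }, indent=2))

    print(f"predicted piRNAs: 5'U fraction {pfm.fraction_U_at_1:.3f} "
          f"(generator {SIM.p_5prime_U}), 10A fraction {pfm.fraction_A_at_10:.3f} "
          f"(generator {SIM.p_pos10_A})")
    print(f"strand: {sc['sense_pct']}% sense / {sc['antisense_pct']}% antisense "
          f"(generator antisense {SIM.antisense_fraction})")
    print(fd.to_string(index=False))


if __name__ == "__main__":
    main()
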