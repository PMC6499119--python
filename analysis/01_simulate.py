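"""Simulate the synthetic gonadal small-RNA world.

Builds the reference transcriptome (with embedded contaminant sources),
the 26-32 nt piRNA pool with 5'U/10A biases and sex-expression classes,
and two ovary + two testis FASTQ libraries with negative-binomial counts.
Bulky outputs go to scratch/; a compact truth summary goes to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

from common import RESULTS, SCRATCH, SIM, ensure_dirs
from gonadpi.simulate import build_world, simulate_libraries


def main():
    ensure_dirs()
    world = build_world(SIM)
    world.reference.write(SCRATCH / "reference")
    paths, counts = simulate_libraries(SIM, world.truth, SCRATCH / "reads")
    world.truth.to_csv(SCRATCH / "truth.tsv", sep="\t", index=False)

    truth = world.truth
    by_class = truth["class"].value_counts()
    pir = truth[truth["class"] == "piRNA"]
    by_sex = pir["sex_category"].value_counts()
    lib_sizes = counts.drop(columns=["seq_id", "sequence"]).sum()

    summary = pd.concat([
        by_class.rename("n").rename_axis("group").reset_index().assign(kind="class"),
        by_sex.rename("n").rename_axis("group").reset_index().assign(kind="sex_category"),
        lib_sizes.rename("n").rename_axis("group").reset_index().assign(kind="library_reads"),
    ])
    summary.to_csv(RESULTS / "01_truth_summary.tsv", sep="\t", index=False)

    print(f"world: {len(truth)} distinct sequences "
          f"({by_class.to_dict()}); piRNA sex classes {by_sex.to_dict()}")
    print(f"library read totals: {lib_sizes.to_dict()}")
    print(f"wrote reference/reads/truth under {SCRATCH}, summary to results/01_truth_summary.tsv")


if __name__ == "__main__":
    main()
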