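"""Shared configuration for the numbered analysis scripts.

All drivers use one deterministic synthetic world (seed 2019). Bulky
intermediates (FASTQ, per-read tables) live under scratch/; only compact
summary tables are written to results/.
"""

from pathlib import Path

from gonadpi.config import PipelineConfig, SimConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 2019

SIM = SimConfig(
    seed=SEED,
    n_genes=300,
    n_pirna=2000,
    depth_per_library=20_000,
    n_mirna=60,
    n_ncrna=48,
    n_repeat=32,
    n_other=80,
)

PIPELINE = PipelineConfig(seed=SEED, out_dir=str(SCRATCH / "run"), sim=SIM)


def ensure_dirs():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
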