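"""Configuration objects for the simulator, thresholds, and pipeline runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


def _default_length_weights() -> dict[int, float]:
    # piRNA-length profile: 26-32 nt support with the mass concentrated on
    # 26-30 nt, the range gonadal libraries peak in.
    return {26: 0.18, 27: 0.20, 28: 0.20, 29: 0.16, 30: 0.14, 31: 0.07, 32: 0.05}


def _default_sex_proportions() -> dict[str, float]:
    # Sex-specific classes dominate gonadal piRNA populations (~44% per sex),
    # the remainder split between quantitatively biased and shared expression.
    return {"ovary_only": 0.44, "testis_only": 0.44, "biased": 0.06, "shared": 0.06}


@dataclass
class SimConfig:
    """Parameters of the synthetic gonadal small-RNA world.

    The defaults describe the data regime the analysis is designed for:
    26-32 nt piRNAs with a strong 5' U bias and a position-10 A bias, two
    sequencing libraries per sex, negative-binomial read counts, and a
    single-channel microarray with three replicate spots per probe and
    three samples per sex.
    """

    seed: int = 0

    # reference transcriptome
    n_genes: int = 300
    transcript_length_range: tuple[int, int] = (150, 2500)
    utr_fractions: tuple[float, float, float] = (0.1, 0.7, 0.2)  # 5'UTR/CDS/3'UTR

    # piRNA pool
    n_pirna: int = 2000
    pirna_length_weights: dict[int, float] = field(default_factory=_default_length_weights)
    p_5prime_U: float = 0.8
    p_pos10_A: float = 0.6
    antisense_fraction: float = 0.57
    sex_class_proportions: dict[str, float] = field(default_factory=_default_sex_proportions)
    biased_log2fc: float = 2.0

    # sequencing libraries
    depth_per_library: int = 50_000
    nb_dispersion: float = 0.2
    libraries_per_sex: int = 2

    # contaminant / background classes
    n_mirna: int = 80
    n_ncrna: int = 60
    n_repeat: int = 40
    n_other: int = 100

    # known-piRNA reference (planted homologs + shuffled decoys)
    n_known: int = 93
    n_known_decoys: int = 200

    # microarray
    array_replicates: int = 3
    array_samples_per_sex: int = 3
    array_background_mean: float = 50.0
    array_signal_mean: float = 500.0
    array_noise_cv: float = 0.1
    array_high_cv_fraction: float = 0.1
    array_high_cv_level: float = 0.6
    # detection floor: sex-specific probes still hybridise faintly in the
    # other sex (cross-hybridisation), as single-channel arrays never
    # measure a true zero
    array_crosshyb: float = 0.02

    # read emission
    adapter: Optional[str] = None  # fixed 3' adapter suffix appended when set
    low_quality_fraction: float = 0.0  # fraction of reads emitted at Q10

    def validate(self) -> None:
        probs = {
            "p_5prime_U": self.p_5prime_U,
            "p_pos10_A": self.p_pos10_A,
            "antisense_fraction": self.antisense_fraction,
            "array_high_cv_fraction": self.array_high_cv_fraction,
            "low_quality_fraction": self.low_quality_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if abs(sum(self.sex_class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("sex_class_proportions must sum to 1")
        if not set(self.pirna_length_weights) <= set(range(26, 33)):
            raise ValueError("pirna_length_weights support must lie within 26..32 nt")
        if abs(sum(self.pirna_length_weights.values()) - 1.0) > 1e-9:
            raise ValueError("pirna_length_weights must sum to 1")
        f5, fc, f3 = self.utr_fractions
        if min(f5, fc, f3) < 0 or abs(f5 + fc + f3 - 1.0) > 1e-9:
            raise ValueError("utr_fractions must be non-negative and sum to 1")
        lo, hi = self.transcript_length_range
        if lo < 1 or hi < lo:
            raise ValueError("transcript_length_range must satisfy 1 <= lo <= hi")
        if self.depth_per_library < 0:
            raise ValueError("depth_per_library must be >= 0")
        if self.array_replicates < 1:
            raise ValueError("array_replicates must be >= 1")
        for name in ("n_genes", "n_pirna", "n_mirna", "n_ncrna", "n_repeat", "n_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SeqThresholds:
    """Sequencing-side expression thresholds."""

    min_count: int = 10
    lfc: float = 1.5
    p: float = 0.01
    padj: float = 0.05
    high_expr_ovary: tuple[float, float] = (50, 4646)
    high_expr_testis: tuple[float, float] = (50, 8177)


@dataclass
class ArrayThresholds:
    """Microarray-side thresholds."""

    cv: float = 0.3
    lfc: float = 1.0
    p: float = 0.05
    coexpr_median: float = 1.0


@dataclass
class ThresholdsConfig:
    seq: SeqThresholds = field(default_factory=SeqThresholds)
    array: ArrayThresholds = field(default_factory=ArrayThresholds)


@dataclass
class PipelineConfig:
    """End-to-end run configuration (simulate + analyse)."""

    seed: int = 0
    out_dir: str = "gonadpi_run"
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: ThresholdsConfig = field(default_factory=ThresholdsConfig)
    min_quality: float = 20.0
    length_window: tuple[int, int] = (18, 35)
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Stable hash over all semantic fields (excludes out_dir and logging)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload.pop("log_level")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML, with defaults for absent keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = SimConfig(**data.pop("sim", {}))
    thr_raw = data.pop("thresholds", {})
    thresholds = ThresholdsConfig(
        seq=SeqThresholds(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in thr_raw.get("seq", {}).items()}),
        array=ArrayThresholds(**thr_raw.get("array", {})),
    )
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    extra = set(data) - known
    if extra:
        raise ValueError(f"unknown config keys: {sorted(extra)}")
    if "length_window" in data:
        data["length_window"] = tuple(data["length_window"])
    if "transcript_length_range" in data:
        data["transcript_length_range"] = tuple(data["transcript_length_range"])
    cfg = PipelineConfig(sim=sim, thresholds=thresholds, **data)
    cfg.sim.validate()
    return cfg
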