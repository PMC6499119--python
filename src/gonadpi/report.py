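"""Report formatting helpers: half-up percentages and run-report assembly."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at `ndigits` decimals (ties like 0.125 -> 0.13)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 2) -> float:
    """Percentage numerator/denominator*100 rounded half-up to `ndigits` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def format_percentage(numerator: int, denominator: int, ndigits: int = 2) -> str:
    return f"{percentage(numerator, denominator, ndigits):.{ndigits}f}%"


@dataclass
class RunReport:
    """Per-stage tallies of a pipeline run.

    Every percentage entry is stored as (numerator, denominator, percent)
    so the printed number can always be re-derived.
    """

    config_hash: str
    tool_version: str
    stages: dict[str, Any] = field(default_factory=dict)

    def add_fraction(self, stage: str, name: str, num: int, den: int) -> None:
        entry = self.stages.setdefault(stage, {})
        entry[name] = {
            "numerator": int(num),
            "denominator": int(den),
            "percent": percentage(num, den) if den else 0.0,
        }

    def add(self, stage: str, name: str, value) -> None:
        self.stages.setdefault(stage, {})[name] = value

    def to_json(self, path: str | Path | None = None) -> str:
        blob = json.dumps(
            {"config_hash": self.config_hash, "tool_version": self.tool_version,
             "stages": self.stages},
            indent=2, sort_keys=True, default=_jsonable,
        )
        if path is not None:
            Path(path).write_text(blob + "\n")
        return blob


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
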