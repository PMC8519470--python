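"""Result container shared by the semi-continuous and continuous LR engines."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = ["LRReport", "PER_LOCUS_COLUMNS"]

#: Column order of the per-locus table written by both engines.
PER_LOCUS_COLUMNS = [
    "locus_id",
    "evidence_class",
    "case_num",
    "case_den",
    "L_num",
    "L_den",
    "log10_lr",
    "ceiling",
    "ceiling_flag",
    "infinite",
]


@dataclass
class LRReport:
    """Per-locus and protocol-wide likelihood-ratio results.

    The protocol ``log10_lr`` is the sum of the per-locus log10 LRs over the
    included loci (the product rule in log space, which avoids underflow over
    hundreds of loci).  Loci whose denominator likelihood is zero carry an
    infinite LR and are flagged; they are included in the protocol total
    unless the engine was asked to drop them.
    """

    engine: str
    label_num: str
    label_den: str
    per_locus: pd.DataFrame
    log10_lr: float
    mr_ex: tuple[float, ...] | None = None
    notes: list[str] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def lr(self) -> float:
        """Protocol likelihood ratio on the natural scale (may overflow to inf)."""
        if math.isinf(self.log10_lr):
            return math.inf if self.log10_lr > 0 else 0.0
        try:
            return 10.0 ** self.log10_lr
        except OverflowError:
            return math.inf

    @property
    def n_loci(self) -> int:
        return len(self.per_locus)

    def to_dict(self) -> dict[str, Any]:
        return {
            "engine": self.engine,
            "hypothesis_numerator": self.label_num,
            "hypothesis_denominator": self.label_den,
            "log10_lr": self.log10_lr,
            "n_loci": self.n_loci,
            "mr_ex": list(self.mr_ex) if self.mr_ex is not None else None,
            "notes": list(self.notes),
            "metadata": dict(self.metadata),
        }

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def write(self, outdir: str | Path, stem: str = "report") -> tuple[Path, Path]:
        """Write ``<stem>.json`` and ``<stem>_per_locus.csv`` under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        json_path = outdir / f"{stem}.json"
        csv_path = outdir / f"{stem}_per_locus.csv"
        json_path.write_text(self.to_json())
        self.per_locus.to_csv(csv_path, index=False)
        return json_path, csv_path
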