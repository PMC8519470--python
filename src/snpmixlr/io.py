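"""Readers/writers for the tabular formats and the run orchestration.

All tables are plain UTF-8 CSV with a header row:

- frequency panel: ``locus_id,allele1,allele2,freq1,freq2``
- evidence table:  ``locus_id,allele1,allele2,reads1,reads2``
- profile table:   ``sample_id,locus_id,allele1,allele2`` (homozygotes
  repeat the allele)

Profiles are stored as two named alleles per locus and converted to the
per-locus AA/AB/BB codes only after the evidence-driven relabeling, so the
same profile file works against evidence files that flip major/minor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import LocusEvidence, LocusFrequencies, ReferenceProfile, relabel_alleles
from .quantitative import continuous_lr
from .report import LRReport
from .semicontinuous import Hypothesis, semicont_lr

__all__ = [
    "FormatError",
    "read_panel",
    "read_evidence",
    "read_profiles",
    "build_dataset",
    "RunConfig",
    "run",
]

logger = logging.getLogger("snpmixlr")

_PANEL_COLS = ["locus_id", "allele1", "allele2", "freq1", "freq2"]
_EVIDENCE_COLS = ["locus_id", "allele1", "allele2", "reads1", "reads2"]
_PROFILE_COLS = ["sample_id", "locus_id", "allele1", "allele2"]


class FormatError(ValueError):
    """A structural problem in an input table, naming the offending rows."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")


def read_panel(path: str | Path) -> pd.DataFrame:
    """Read and validate a frequency panel."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _PANEL_COLS, str(path))
    dup = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
    if dup:
        raise FormatError(f"{path}: duplicate loci {dup}")
    bad = df[(df["freq1"] <= 0) | (df["freq2"] <= 0)]
    if len(bad):
        raise FormatError(
            f"{path}: nonpositive frequencies at loci {bad['locus_id'].tolist()}"
        )
    off = df[(df["freq1"] + df["freq2"] - 1.0).abs() > 1e-6]
    if len(off):
        raise FormatError(
            f"{path}: frequencies do not sum to 1 at loci {off['locus_id'].tolist()}"
        )
    same = df[df["allele1"] == df["allele2"]]
    if len(same):
        raise FormatError(
            f"{path}: identical allele names at loci {same['locus_id'].tolist()}"
        )
    return df[_PANEL_COLS]


def read_evidence(path: str | Path) -> pd.DataFrame:
    """Read and validate an evidence (read-count) table."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _EVIDENCE_COLS, str(path))
    dup = df.loc[df["locus_id"].duplicated(), "locus_id"].tolist()
    if dup:
        raise FormatError(f"{path}: duplicate loci {dup}")
    for col in ("reads1", "reads2"):
        if not pd.api.types.is_integer_dtype(df[col]):
            if (df[col] % 1 != 0).any() or df[col].isna().any():
                raise FormatError(f"{path}: column {col} must hold integer reads")
            df[col] = df[col].astype(int)
    neg = df[(df["reads1"] < 0) | (df["reads2"] < 0)]
    if len(neg):
        raise FormatError(
            f"{path}: negative read counts at loci {neg['locus_id'].tolist()}"
        )
    return df[_EVIDENCE_COLS]


def read_profiles(path: str | Path) -> dict[str, ReferenceProfile]:
    """Read a profile table into ReferenceProfile objects keyed by sample id."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _PROFILE_COLS, str(path))
    dup = df[df.duplicated(subset=["sample_id", "locus_id"])]
    if len(dup):
        raise FormatError(
            f"{path}: duplicated (sample, locus) rows: "
            f"{dup[['sample_id', 'locus_id']].to_records(index=False).tolist()}"
        )
    profiles: dict[str, ReferenceProfile] = {}
    for row in df.itertuples(index=False):
        prof = profiles.setdefault(str(row.sample_id), ReferenceProfile(str(row.sample_id)))
        prof.genotypes[str(row.locus_id)] = (str(row.allele1), str(row.allele2))
    return profiles


def build_dataset(
    panel: pd.DataFrame,
    evidence: pd.DataFrame,
    tau: float = 0.05,
) -> list[tuple[LocusEvidence, LocusFrequencies]]:
    """Join panel and evidence into relabeled per-locus engine inputs.

    Every evidence locus must appear in the panel (with matching allele
    names); mismatches are reported with their locus ids.  Loci with zero
    total reads carry no evidence and are logged and excluded.
    """
    panel_by_locus = {r.locus_id: r for r in panel.itertuples(index=False)}
    missing = [
        r.locus_id
        for r in evidence.itertuples(index=False)
        if r.locus_id not in panel_by_locus
    ]
    if missing:
        raise FormatError(f"evidence loci absent from the panel: {missing}")
    dataset = []
    for r in evidence.itertuples(index=False):
        p = panel_by_locus[r.locus_id]
        if {r.allele1, r.allele2} != {p.allele1, p.allele2}:
            raise FormatError(
                f"locus {r.locus_id}: evidence alleles {{{r.allele1},{r.allele2}}} "
                f"do not match panel alleles {{{p.allele1},{p.allele2}}}"
            )
        reads = {r.allele1: int(r.reads1), r.allele2: int(r.reads2)}
        if sum(reads.values()) == 0:
            logger.warning("locus %s: zero reads for both alleles, excluded", r.locus_id)
            continue
        freqs = {p.allele1: float(p.freq1), p.allele2: float(p.freq2)}
        dataset.append(relabel_alleles(r.locus_id, reads, freqs, tau))
    return dataset


@dataclass
class RunConfig:
    """One reproducible LR run: input paths, hypotheses and engine choice."""

    panel_path: str
    evidence_path: str
    profiles_path: str | None = None
    engine: str = "semicont"  # or "continuous"
    n_num: int = 2
    poi_ids: tuple[str, ...] = ()
    n_den: int = 2
    poi_ids_den: tuple[str, ...] = ()
    tau: float = 0.05
    mrex_override: float | None = None
    drop_infinite: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.engine not in ("semicont", "continuous"):
            raise ValueError(f"unknown engine {self.engine!r}")


def run(config: RunConfig) -> LRReport:
    """Execute a configured LR run; optionally write report.json + CSV + log."""
    panel = read_panel(config.panel_path)
    evidence = read_evidence(config.evidence_path)
    profiles = read_profiles(config.profiles_path) if config.profiles_path else {}
    for pid in (*config.poi_ids, *config.poi_ids_den):
        if pid not in profiles:
            raise FormatError(f"POI id {pid!r} not found in the profile table")
    dataset = build_dataset(panel, evidence, tau=config.tau)

    num = Hypothesis(config.n_num, tuple(profiles[p] for p in config.poi_ids))
    den = Hypothesis(config.n_den, tuple(profiles[p] for p in config.poi_ids_den))
    if config.engine == "semicont":
        report = semicont_lr(num, den, dataset, drop_infinite=config.drop_infinite)
    else:
        report = continuous_lr(
            num,
            den,
            dataset,
            mrex_override=config.mrex_override,
            drop_infinite=config.drop_infinite,
        )
    report.metadata.update(
        {
            "panel": str(config.panel_path),
            "evidence": str(config.evidence_path),
            "tau": config.tau,
        }
    )
    if config.outdir:
        outdir = Path(config.outdir)
        report.write(outdir)
        (outdir / "run.log").write_text("\n".join(report.notes) + "\n")
    return report
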