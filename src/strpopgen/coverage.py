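"""Depth-of-coverage (DoC) summarisation and run-level QC flags.

The DoC of a locus in a sample is the sum of valid reads assigned to that
locus; the per-locus DoC reported here is its mean over samples. The QC
summary flags loci whose mean falls below a configurable threshold (default
650x) and reports the highest-to-lowest mean ratio.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class CoverageTable:
    """Long-form (locus, sample, valid reads) coverage records."""

    frame: pd.DataFrame  # columns: locus, sample, reads

    def __post_init__(self) -> None:
        required = {"locus", "sample", "reads"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"coverage table needs columns {sorted(required)}")
        if (self.frame["reads"] < 0).any():
            raise ValueError("negative read counts")

    def per_locus_mean(self) -> pd.Series:
        return self.frame.groupby("locus", sort=True)["reads"].mean()

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CoverageTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class CoverageSummary:
    per_locus_mean: dict[str, float]
    panel_mean: float
    max_locus: str
    min_locus: str
    ratio: float
    ratio_rounded: int
    below_threshold: list[str]
    threshold: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "per_locus_mean": self.per_locus_mean,
                    "panel_mean": self.panel_mean,
                    "max_locus": self.max_locus,
                    "min_locus": self.min_locus,
                    "ratio": self.ratio,
                    "ratio_rounded": self.ratio_rounded,
                    "below_threshold": self.below_threshold,
                    "threshold": self.threshold,
                },
                indent=2,
                sort_keys=True,
            )
        )


def doc_summary(cov: CoverageTable, threshold: float = 650.0) -> CoverageSummary:
    """Per-locus mean DoC, flagged low-coverage loci, and the max/min ratio
    (rounded to integer for reporting). A locus with zero mean coverage is
    flagged, and makes the ratio undefined (error)."""
    means = cov.per_locus_mean()
    if means.empty:
        raise ValueError("empty coverage table")
    below = sorted(means.index[means < threshold])
    min_locus = means.idxmin()
    max_locus = means.idxmax()
    if means[min_locus] == 0:
        raise ValueError(f"locus {min_locus} has zero mean coverage; ratio undefined")
    ratio = float(means[max_locus] / means[min_locus])
    return CoverageSummary(
        per_locus_mean={str(k): float(v) for k, v in means.items()},
        panel_mean=float(means.mean()),
        max_locus=str(max_locus),
        min_locus=str(min_locus),
        ratio=ratio,
        ratio_rounded=int(round(ratio)),
        below_threshold=[str(x) for x in below],
        threshold=float(threshold),
    )
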