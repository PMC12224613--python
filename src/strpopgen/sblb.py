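"""Sequence-based vs length-based allele accounting.

For each locus the observed set of sequence-based (SB) alleles is collapsed
to its length designations (LB alleles); the gain in unique alleles and its
source are reported. Within each length class, SB alleles can differ in
their repeat-region (RR) block structure, in their flanking-region (FR)
variant annotations, or both; a locus is classified ``RR_only`` when every
gain traces to RR differences, ``FR_only`` when every gain traces to FR
differences, ``both`` when both occur, and ``none`` when SB and LB counts
coincide.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import json

import pandas as pd

from .nomenclature import SequenceAllele, collapse_to_length

RR_ONLY = "RR_only"
FR_ONLY = "FR_only"
BOTH = "both"
NONE = "none"


@dataclass
class LocusComparison:
    locus: str
    chrom_class: str
    n_sb: int
    n_lb: int
    source_class: str

    @property
    def pct_increase(self) -> float:
        return (self.n_sb - self.n_lb) / self.n_lb * 100.0


def compare_locus(sb_alleles: Iterable[SequenceAllele]) -> LocusComparison:
    """Collapse one locus's SB alleles and classify the variation source.

    Within every designation class, RR variation means the block structures
    differ somewhere; FR variation means the flank-variant lists differ.
    """
    alleles = set(sb_alleles)
    if not alleles:
        raise ValueError("compare_locus needs a non-empty allele set")
    classes = collapse_to_length(alleles)
    locus = next(iter(alleles)).locus
    rr = False
    fr = False
    for members in classes.values():
        blocks = {a.blocks for a in members}
        flanks = {a.flank_variants for a in members}
        if len(blocks) > 1:
            rr = True
        if len(flanks) > 1:
            fr = True
    n_sb = len(alleles)
    n_lb = len(classes)
    if n_sb == n_lb:
        source = NONE
    elif rr and fr:
        source = BOTH
    elif rr:
        source = RR_ONLY
    else:
        source = FR_ONLY
    return LocusComparison(
        locus=locus.name,
        chrom_class=locus.chrom_class,
        n_sb=n_sb,
        n_lb=n_lb,
        source_class=source,
    )


@dataclass
class PanelGain:
    """Unique-allele totals per chromosome class and overall.

    Two aggregation conventions are reported side by side: the ratio of
    summed totals, and the mean of per-locus percentage gains — published
    headline percentages do not always state which one they use.
    """

    per_class: dict[str, dict[str, float]]
    total_sb: int
    total_lb: int
    sum_gain_pct: float
    mean_gain_pct: float


def panel_summary(comparisons: Sequence[LocusComparison]) -> PanelGain:
    if not comparisons:
        raise ValueError("panel_summary needs at least one locus")
    per_class: dict[str, dict[str, float]] = {}
    for c in comparisons:
        d = per_class.setdefault(
            c.chrom_class, {"n_loci": 0, "n_sb": 0, "n_lb": 0}
        )
        d["n_loci"] += 1
        d["n_sb"] += c.n_sb
        d["n_lb"] += c.n_lb
    for d in per_class.values():
        d["sum_gain_pct"] = (d["n_sb"] - d["n_lb"]) / d["n_lb"] * 100.0
    total_sb = sum(c.n_sb for c in comparisons)
    total_lb = sum(c.n_lb for c in comparisons)
    return PanelGain(
        per_class=per_class,
        total_sb=total_sb,
        total_lb=total_lb,
        sum_gain_pct=(total_sb - total_lb) / total_lb * 100.0,
        mean_gain_pct=sum(c.pct_increase for c in comparisons) / len(comparisons),
    )


def write_comparison_csv(comparisons: Sequence[LocusComparison], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "locus": c.locus,
                "class": c.chrom_class,
                "n_sb": c.n_sb,
                "n_lb": c.n_lb,
                "pct_increase": c.pct_increase,
                "source_class": c.source_class,
            }
            for c in comparisons
        ]
    ).to_csv(path, index=False)


def write_panel_gain_json(gain: PanelGain, path: str | Path) -> None:
    payload = {
        "per_class": gain.per_class,
        "total_sb": gain.total_sb,
        "total_lb": gain.total_lb,
        "sum_gain_pct": gain.sum_gain_pct,
        "mean_gain_pct": gain.mean_gain_pct,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
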