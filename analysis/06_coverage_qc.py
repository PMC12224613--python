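#!/usr/bin/env python
"""Depth-of-coverage QC.

Summarises per-locus mean depth of coverage (sum of valid reads per locus
per sample, averaged over samples), flags loci whose mean falls below the
650x QC threshold, and reports the highest-to-lowest ratio.

Writes coverage_summary.json under results/.
"""
from __future__ import annotations

import argparse
from pathlib import Path

from strpopgen import CoverageTable, doc_summary

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--threshold", type=float, default=650.0)
    args = ap.parse_args()

    cov = CoverageTable.read_tsv(args.cohort / "coverage.tsv")
    summary = doc_summary(cov, threshold=args.threshold)
    args.results.mkdir(exist_ok=True)
    summary.to_json(args.results / "coverage_summary.json")

    print(f"panel mean DoC: {summary.panel_mean:.0f}x")
    print(f"range: {summary.per_locus_mean[summary.min_locus]:.0f}x "
          f"({summary.min_locus}) to "
          f"{summary.per_locus_mean[summary.max_locus]:.0f}x ({summary.max_locus}); "
          f"ratio {summary.ratio_rounded}")
    print(f"{len(summary.below_threshold)} loci below {args.threshold:.0f}x: "
          f"{', '.join(summary.below_threshold[:8])}"
          f"{'...' if len(summary.below_threshold) > 8 else ''}")
    print(f"wrote {args.results}/coverage_summary.json")


if __name__ == "__main__":
    main()
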