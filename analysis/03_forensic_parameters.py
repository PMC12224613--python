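#!/usr/bin/env python
"""Forensic parameter suite per marker class, plus combined panel values.

Autosomal STRs and SNPs get the PowerStats-style bundle (Hobs, Hexp, PIC,
MP/PD, PE, TPI) from observed genotypes; X-STRs get PD_M/PD_F and the four
mean exclusion chances from pooled frequencies; Y-STRs get per-locus gene
diversity plus haplotype diversity and discrimination capacity. Combined
statistics (CMP/CPD/CPE/CPI) are accumulated in log space.

Writes astr_stats.csv, xstr_stats.csv, ystr_stats.csv, snp_stats.csv and
panel_stats.json under results/.
"""
from __future__ import annotations

import argparse
import json
from pathlib import Path

import pandas as pd

from strpopgen import (
    assemble_y_haplotypes,
    combine_panel,
    compute_allele_frequencies,
    gene_diversity,
    haplotype_diversity,
    load_locus_catalogue,
    read_genotype_table,
)
from strpopgen.loci import AUTOSOMAL, SNP, STR, X, Y
from strpopgen.pipeline import stats_for_diploid_locus, stats_for_x_locus

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    catalogue = load_locus_catalogue(args.cohort / "catalogue.tsv")
    gt = read_genotype_table(args.cohort / "genotypes.tsv", catalogue)
    args.results.mkdir(exist_ok=True)

    a_str = [l for l in gt.loci.values() if l.chrom_class == AUTOSOMAL and l.marker_type == STR]
    a_snp = [l for l in gt.loci.values() if l.chrom_class == AUTOSOMAL and l.marker_type == SNP]
    x_str = [l for l in gt.loci.values() if l.chrom_class == X and l.marker_type == STR]
    y_str = [l for l in gt.loci.values() if l.chrom_class == Y and l.marker_type == STR]

    astr = [stats_for_diploid_locus(gt, l) for l in a_str]
    snps = [stats_for_diploid_locus(gt, l) for l in a_snp]
    pd.DataFrame([vars(s) for s in astr]).round(4).to_csv(
        args.results / "astr_stats.csv", index=False
    )
    pd.DataFrame([vars(s) for s in snps]).round(4).to_csv(
        args.results / "snp_stats.csv", index=False
    )

    xstats = [stats_for_x_locus(gt, l) for l in x_str]
    pd.DataFrame([vars(s) for s in xstats]).round(4).to_csv(
        args.results / "xstr_stats.csv", index=False
    )

    y_rows = []
    for l in y_str:
        ft = compute_allele_frequencies(gt, l)
        y_rows.append({"locus": l.name, "n_obs": ft.denominator,
                       "GD": round(gene_diversity(ft, ft.denominator), 4)})
    pd.DataFrame(y_rows).to_csv(args.results / "ystr_stats.csv", index=False)
    ystats = haplotype_diversity(assemble_y_haplotypes(gt, y_str))

    panel = {
        "A-STR": combine_panel(astr).render(),
        "A-SNP": combine_panel(snps).render(),
        "Y": {"n": ystats.n, "k": ystats.k, "HD": round(ystats.HD, 4),
              "DC": round(ystats.DC, 4),
              "unique_fraction": round(ystats.unique_fraction, 4)},
    }
    (args.results / "panel_stats.json").write_text(json.dumps(panel, indent=2, sort_keys=True))

    best = max(astr, key=lambda s: s.Hobs)
    print(f"most heterozygous A-STR: {best.locus} (Hobs={best.Hobs:.2f})")
    print(f"A-STR combined: CPD {panel['A-STR']['CPD']}, CPE {panel['A-STR']['CPE']}, "
          f"CPI {panel['A-STR']['CPI']:.3e}")
    print(f"A-SNP combined: CMP {panel['A-SNP']['CMP']:.3e}, "
          f"CPE {panel['A-SNP']['CPE_percent']:.9f}%")
    print(f"Y: HD {panel['Y']['HD']}, DC {panel['Y']['DC']} (k={ystats.k}/N={ystats.n})")
    print(f"wrote per-class stats CSVs and panel_stats.json under {args.results}/")


if __name__ == "__main__":
    main()
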