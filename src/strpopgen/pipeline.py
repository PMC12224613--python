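"""End-to-end pipeline: frequencies -> forensic statistics -> HWE/LD ->
sequence-vs-length comparison -> coverage QC.

File dialects are plain UTF-8 TSV/CSV with a header row (see the module
docs of :mod:`strpopgen.genotypes`, :mod:`strpopgen.frequencies`,
:mod:`strpopgen.coverage`); every output is re-readable by the package's
own readers. A run manifest (seed, config echo, package and library
versions, stage list) fully determines a reproduction of the run; with a
fixed seed, re-running produces byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .coverage import CoverageTable, doc_summary
from .equilibrium import TestResult, bonferroni_plan, hwe_exact, ld_pairwise
from .forensic import (
    LocusStats,
    XStats,
    autosomal_locus_stats,
    combine_panel,
    gene_diversity,
    haplotype_diversity,
    mec_suite,
    snp_stats,
)
from .frequencies import (
    FrequencyTable,
    assemble_y_haplotypes,
    compute_allele_frequencies,
    write_frequency_csv,
)
from .genotypes import GenotypeTable, read_genotype_table, read_genotype_xlsx
from .loci import AUTOSOMAL, LocusDef, SNP, STR, X, Y, load_locus_catalogue
from .nomenclature import AlleleParseError, parse_bracket
from .sblb import compare_locus, panel_summary, write_comparison_csv, write_panel_gain_json

logger = logging.getLogger("strpopgen")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    genotype_path: str
    coverage_path: str
    catalogue_path: str
    out_dir: str
    seed: int
    alpha: float = 0.05
    bonferroni_scope: str = "all-pairs"  # or "tested-pairs"
    mc_steps: int = 20_000
    permutations: int = 199
    max_ld_pairs: int = 20
    coverage_threshold: float = 650.0
    rounding: int = 4
    x_male_double_count: bool = False
    x_hwe_females_only: bool = True

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# per-locus assembly helpers
# ---------------------------------------------------------------------------

def diploid_genotype_counts(
    gt: GenotypeTable, locus: LocusDef, *, females_only: bool = False
) -> tuple[dict[tuple[str, str], int], int]:
    """Observed unordered genotype counts and the heterozygote count."""
    counts: dict[tuple[str, str], int] = {}
    het = 0
    samples = gt.females() if females_only else gt.samples
    for s in samples:
        tokens = gt.get(s, locus.name)
        if len(tokens) != 2:
            continue
        key = tuple(sorted(tokens))
        counts[key] = counts.get(key, 0) + 1
        if key[0] != key[1]:
            het += 1
    return counts, het


def stats_for_diploid_locus(gt: GenotypeTable, locus: LocusDef) -> LocusStats:
    freqs = compute_allele_frequencies(gt, locus)
    counts, het = diploid_genotype_counts(gt, locus)
    builder = snp_stats if locus.marker_type == SNP else autosomal_locus_stats
    return builder(locus.name, freqs, counts, het)


def stats_for_x_locus(
    gt: GenotypeTable, locus: LocusDef, *, x_male_double_count: bool = False
) -> XStats:
    freqs = compute_allele_frequencies(gt, locus, x_male_double_count=x_male_double_count)
    return mec_suite(freqs)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _round_frame(df: pd.DataFrame, digits: int) -> pd.DataFrame:
    return df.round(digits)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the report bundle into ``cfg.out_dir``.

    Any stage failure aborts with a stage-named error and removes files
    already written for this run.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "package": "strpopgen",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": [],
    }

    def emit(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    stage = "load_inputs"
    try:
        catalogue = load_locus_catalogue(cfg.catalogue_path)
        gt = read_genotype_table(cfg.genotype_path, catalogue)
        cov = CoverageTable.read_tsv(cfg.coverage_path)
        report: dict = {}

        # stage 1: frequencies -------------------------------------------
        stage = "frequencies"
        logger.info("stage %s", stage)
        freq_tables: dict[str, FrequencyTable] = {}
        for name, locus in gt.loci.items():
            freq_tables[name] = compute_allele_frequencies(
                gt, locus, x_male_double_count=cfg.x_male_double_count and locus.chrom_class == X
            )
        write_frequency_csv(freq_tables.values(), emit("frequencies.csv"))
        manifest["stages"].append(stage)

        # stage 2: forensic statistics -----------------------------------
        stage = "forensic_parameters"
        logger.info("stage %s", stage)
        a_str = [l for l in gt.loci.values() if l.chrom_class == AUTOSOMAL and l.marker_type == STR]
        a_snp = [l for l in gt.loci.values() if l.chrom_class == AUTOSOMAL and l.marker_type == SNP]
        x_str = [l for l in gt.loci.values() if l.chrom_class == X and l.marker_type == STR]
        y_loci = [l for l in gt.loci.values() if l.chrom_class == Y]
        y_str = [l for l in y_loci if l.marker_type == STR]

        astr_stats = [stats_for_diploid_locus(gt, l) for l in a_str]
        snp_stats_list = [stats_for_diploid_locus(gt, l) for l in a_snp]
        xstats = [
            stats_for_x_locus(gt, l, x_male_double_count=cfg.x_male_double_count)
            for l in x_str
        ]
        digits = cfg.rounding
        pd.DataFrame(
            [
                {
                    "locus": s.locus, "n_obs": s.n_obs, "Hobs": s.Hobs, "Hexp": s.Hexp,
                    "PIC": s.PIC, "MP": s.MP, "PD": s.PD, "PE": s.PE, "TPI": s.TPI,
                }
                for s in astr_stats
            ]
        ).pipe(_round_frame, digits).to_csv(emit("astr_stats.csv"), index=False)
        pd.DataFrame(
            [
                {
                    "locus": s.locus, "n_obs": s.n_obs, "Hobs": s.Hobs, "Hexp": s.Hexp,
                    "PIC": s.PIC, "MP": s.MP, "DP": s.DP, "PE": s.PE, "TPI": s.TPI,
                }
                for s in snp_stats_list
            ]
        ).pipe(_round_frame, digits).to_csv(emit("snp_stats.csv"), index=False)
        pd.DataFrame(
            [
                {
                    "locus": s.locus, "PD_M": s.PD_M, "PD_F": s.PD_F,
                    "MEC_Kruger": s.MEC_Kruger, "MEC_Kishida": s.MEC_Kishida,
                    "MEC_Desmarais": s.MEC_Desmarais,
                    "MEC_Desmarais_Duo": s.MEC_Desmarais_Duo,
                }
                for s in xstats
            ]
        ).pipe(_round_frame, digits).to_csv(emit("xstr_stats.csv"), index=False)

        y_rows = []
        for l in y_str:
            ft = freq_tables[l.name]
            y_rows.append(
                {"locus": l.name, "n_obs": ft.denominator,
                 "GD": gene_diversity(ft, ft.denominator)}
            )
        pd.DataFrame(y_rows).pipe(_round_frame, digits).to_csv(
            emit("ystr_stats.csv"), index=False
        )
        yh = assemble_y_haplotypes(gt, y_str)
        ystats = haplotype_diversity(yh)
        panel = {
            "A-STR": combine_panel(astr_stats).render(),
            "A-SNP": combine_panel(snp_stats_list).render(),
            "Y": {
                "n": ystats.n, "k": ystats.k,
                "HD": round(ystats.HD, digits), "DC": round(ystats.DC, digits),
                "unique_fraction": round(ystats.unique_fraction, digits),
            },
        }
        emit("panel_stats.json").write_text(json.dumps(panel, indent=2, sort_keys=True))
        report["panel"] = panel
        manifest["stages"].append(stage)

        # stage 3: HWE and LD --------------------------------------------
        stage = "equilibrium_tests"
        logger.info("stage %s", stage)
        hwe_rows = []
        diploid_classes = [
            ("A-STR", a_str), ("A-SNP", a_snp), ("X-STR", x_str),
        ]
        for label, loci in diploid_classes:
            if not loci:
                continue
            _, alpha_prime = bonferroni_plan(len(loci), cfg.alpha)
            for l in loci:
                females_only = l.chrom_class == X and cfg.x_hwe_females_only
                counts, _ = diploid_genotype_counts(gt, l, females_only=females_only)
                genos = [g for g, c in counts.items() for _ in range(c)]
                res = hwe_exact(
                    genos, steps=cfg.mc_steps, seed=_locus_seed(cfg.seed, l.name),
                    name=l.name,
                ).with_alpha(alpha_prime)
                hwe_rows.append((label, res))
        _write_results_tsv(
            emit("hwe.tsv"), [(f"{lbl}:{r.name}", r) for lbl, r in hwe_rows]
        )

        ld_rows = []
        ld_loci = a_str[: max(2, int((1 + np.sqrt(1 + 8 * cfg.max_ld_pairs)) // 2))]
        pairs = [
            (ld_loci[i], ld_loci[j])
            for i in range(len(ld_loci))
            for j in range(i + 1, len(ld_loci))
        ][: cfg.max_ld_pairs]
        if cfg.bonferroni_scope == "all-pairs":
            _, ld_alpha = bonferroni_plan(len(a_str), cfg.alpha, pairwise=True)
        else:
            ld_alpha = cfg.alpha / max(1, len(pairs))
        for la, lb in pairs:
            ga, gb = _paired_diploid(gt, la, lb)
            res = ld_pairwise(
                ga, gb, permutations=cfg.permutations,
                seed=_locus_seed(cfg.seed, la.name + "|" + lb.name),
                name=f"{la.name}|{lb.name}",
            ).with_alpha(ld_alpha)
            ld_rows.append((f"A-STR:{res.name}", res))
        _write_results_tsv(emit("ld.tsv"), ld_rows)
        manifest["stages"].append(stage)

        # stage 4: SB/LB comparison --------------------------------------
        stage = "sb_lb_comparison"
        logger.info("stage %s", stage)
        comparisons = []
        for l in (*a_str, *x_str, *y_str):
            alleles = set()
            ok = True
            for token in freq_tables[l.name].counts:
                try:
                    alleles.add(parse_bracket(token, l))
                except AlleleParseError:
                    ok = False  # LB-designation cells: no SB information
                    break
            if ok and alleles:
                comparisons.append(compare_locus(alleles))
        write_comparison_csv(comparisons, emit("sb_lb_comparison.csv"))
        write_panel_gain_json(panel_summary(comparisons), emit("panel_gain.json"))
        report["sb_lb"] = panel_summary(comparisons)
        manifest["stages"].append(stage)

        # stage 5: coverage QC -------------------------------------------
        stage = "coverage_qc"
        logger.info("stage %s", stage)
        summary = doc_summary(cov, threshold=cfg.coverage_threshold)
        summary.to_json(emit("coverage_summary.json"))
        report["coverage"] = summary
        manifest["stages"].append(stage)

        emit("manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        report["manifest"] = manifest
        return report
    except Exception as err:  # noqa: BLE001 - abort cleanly, stage-named
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err


def _locus_seed(seed: int, name: str) -> int:
    import hashlib

    h = int.from_bytes(hashlib.sha256(f"{seed}:{name}".encode()).digest()[:4], "big")
    return h % (2**31 - 1)


def _paired_diploid(gt: GenotypeTable, la: LocusDef, lb: LocusDef):
    ga, gb = [], []
    for s in gt.samples:
        ta, tb = gt.get(s, la.name), gt.get(s, lb.name)
        if len(ta) == 2 and len(tb) == 2:
            ga.append(tuple(ta))
            gb.append(tuple(tb))
    return ga, gb


def _write_results_tsv(path: Path, rows: Sequence[tuple[str, TestResult]]) -> None:
    pd.DataFrame(
        [
            {
                "name": label,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "method": r.method,
                "steps": r.steps,
                "seed": r.seed,
                "alpha_prime": r.alpha_prime,
                "significant": r.significant_after_bonferroni,
            }
            for label, r in rows
        ]
    ).to_csv(path, sep="\t", index=False)
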