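"""Allele-count and frequency tables with chromosome-aware denominators.

Denominators follow the observation model of a mixed-sex cohort: autosomal
loci contribute two allele observations per sample; X loci two per female and
one per male when sexes are pooled; Y loci ``copy_count`` observations per
male. Null (missing) calls are dropped from both numerator and denominator
and never form an allele class.

The study convention in which a male's single X allele is entered as a
homozygous diploid genotype (so the pooled X denominator counts males twice)
is available as ``x_male_double_count=True``; the haploid-aware pooled
denominator ``2*females + males`` is the default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .genotypes import GenotypeTable, ValidationError
from .loci import AUTOSOMAL, LocusDef, X, Y


@dataclass
class FrequencyTable:
    """Per-locus allele (or haplotype) counts and frequencies."""

    locus: str
    counts: dict[str, int]
    denominator: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.locus}: negative allele count")
        total = sum(self.counts.values())
        if total != self.denominator:
            raise ValueError(
                f"{self.locus}: counts sum to {total}, denominator {self.denominator}"
            )

    @property
    def alleles(self) -> list[str]:
        return list(self.counts)

    @property
    def freqs(self) -> dict[str, float]:
        return {a: c / self.denominator for a, c in self.counts.items()}

    def freq_array(self) -> np.ndarray:
        return np.array(list(self.counts.values()), dtype=float) / self.denominator

    @classmethod
    def from_freqs(
        cls, locus: str, freqs: Mapping[str, float], denominator: int
    ) -> "FrequencyTable":
        """Build from published frequencies; counts are rounded back from
        ``freq * denominator`` and must land on integers."""
        counts = {}
        for a, f in freqs.items():
            c = round(f * denominator)
            if abs(c - f * denominator) > 1e-6:
                raise ValueError(f"{locus}: freq {f} not a multiple of 1/{denominator}")
            counts[a] = int(c)
        return cls(locus, counts, denominator)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.locus,
                "allele": list(self.counts),
                "count": list(self.counts.values()),
                "frequency": [c / self.denominator for c in self.counts.values()],
                "denominator": self.denominator,
            }
        )


def write_frequency_csv(tables: Iterable[FrequencyTable], path: str | Path) -> None:
    frames = [t.to_frame() for t in tables]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_frequency_csv(path: str | Path) -> dict[str, FrequencyTable]:
    df = pd.read_csv(path, dtype={"allele": str})
    out: dict[str, FrequencyTable] = {}
    for locus, grp in df.groupby("locus", sort=False):
        denom = int(grp["denominator"].iloc[0])
        out[str(locus)] = FrequencyTable(
            str(locus), dict(zip(grp["allele"], grp["count"].astype(int))), denom
        )
    return out


def _locus_observations(gt: GenotypeTable, locus: LocusDef) -> list[str]:
    obs: list[str] = []
    for s in gt.samples:
        obs.extend(gt.get(s, locus.name))
    return obs


def compute_allele_frequencies(
    gt: GenotypeTable, locus: LocusDef, *, x_male_double_count: bool = False
) -> FrequencyTable:
    """Allele counts/frequencies at one locus.

    The denominator is the number of non-missing allele observations under
    the locus's ploidy model; samples with missing calls simply do not
    contribute. Raises :class:`ValidationError` on ploidy violations.
    """
    problems = gt.validate([locus.name])
    if problems:
        raise ValidationError(problems)
    counts: dict[str, int] = {}
    for s in gt.samples:
        tokens = gt.get(s, locus.name)
        if not tokens:
            continue
        weight = 1
        if (
            x_male_double_count
            and locus.chrom_class == X
            and gt.sex[s] == "M"
        ):
            weight = 2  # study convention: hemizygous X entered as homozygote
        for t in tokens:
            counts[t] = counts.get(t, 0) + weight
    counts = dict(sorted(counts.items()))
    return FrequencyTable(locus.name, counts, sum(counts.values()))


@dataclass
class YHaplotypeSet:
    """Ordered Y-marker allele tuples per male, with haplotype counts."""

    loci: list[str]
    haplotypes: dict[str, tuple[str, ...]]  # sample -> allele tuple

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    def counts(self) -> dict[tuple[str, ...], int]:
        out: dict[tuple[str, ...], int] = {}
        for h in self.haplotypes.values():
            out[h] = out.get(h, 0) + 1
        return out

    @property
    def k(self) -> int:
        return len(self.counts())


def assemble_y_haplotypes(gt: GenotypeTable, loci: Sequence[LocusDef]) -> YHaplotypeSet:
    """Build Y haplotypes over ``loci`` for all males.

    Multi-copy ("a/b") loci contribute their allele pair as an unordered
    (sorted) pair inside the tuple. Males missing any requested locus are
    dropped with a warning; Y calls in females raise.
    """
    for locus in loci:
        if locus.chrom_class != Y:
            raise ValueError(f"{locus.name} is not a Y locus")
    problems = gt.validate([l.name for l in loci])
    if problems:
        raise ValidationError(problems)
    haplotypes: dict[str, tuple[str, ...]] = {}
    for s in gt.males():
        parts: list[str] = []
        complete = True
        for locus in loci:
            tokens = gt.get(s, locus.name)
            if len(tokens) != locus.copy_count:
                complete = False
                break
            parts.append("/".join(sorted(tokens)))
        if complete:
            haplotypes[s] = tuple(parts)
        else:
            warnings.warn(f"male {s} dropped from Y haplotypes (missing calls)")
    return YHaplotypeSet(loci=[l.name for l in loci], haplotypes=haplotypes)


def _g_statistic(table: np.ndarray) -> float:
    """Likelihood-ratio (G) statistic of independence for a contingency table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def pool_sex_frequencies_check(
    gt: GenotypeTable,
    locus: LocusDef,
    *,
    permutations: int = 10000,
    seed: int | None = None,
) -> float:
    """Homogeneity test of male vs female allele spectra at an X locus.

    Returns the p-value of an exact (2x2 Fisher) or Monte-Carlo permutation
    test on the sex x allele count table; the caller pools the sexes when
    ``p > alpha``. Both sexes must contribute observations.
    """
    if locus.chrom_class != X:
        raise ValueError(f"{locus.name} is not an X locus")
    male_counts: dict[str, int] = {}
    female_counts: dict[str, int] = {}
    for s in gt.samples:
        target = male_counts if gt.sex[s] == "M" else female_counts
        for t in gt.get(s, locus.name):
            target[t] = target.get(t, 0) + 1
    if not male_counts or not female_counts:
        raise ValidationError([f"{locus.name}: both sexes required for homogeneity check"])
    alleles = sorted(set(male_counts) | set(female_counts))
    table = np.array(
        [
            [male_counts.get(a, 0) for a in alleles],
            [female_counts.get(a, 0) for a in alleles],
        ],
        dtype=int,
    )
    if len(alleles) == 1:
        return 1.0
    if len(alleles) == 2:
        return float(fisher_exact(table)[1])
    # Monte-Carlo permutation of sex labels over allele observations
    if seed is None:
        raise ValueError("seed required for the Monte-Carlo homogeneity test")
    rng = np.random.default_rng(seed)
    obs_stat = _g_statistic(table)
    pool = np.repeat(np.arange(len(alleles)), table.sum(axis=0))
    n_male = int(table[0].sum())
    exceed = 0
    for _ in range(permutations):
        rng.shuffle(pool)
        m = np.bincount(pool[:n_male], minlength=len(alleles))
        f = np.bincount(pool[n_male:], minlength=len(alleles))
        if _g_statistic(np.stack([m, f])) >= obs_stat - 1e-12:
            exceed += 1
    return (exceed + 1) / (permutations + 1)
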