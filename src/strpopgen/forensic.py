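"""Forensic identity and kinship parameters for STR/SNP population data.

Per-locus statistics follow the direct-counting conventions of standard
forensic population reports:

* unbiased gene diversity ``GD = n(1 - sum p_i^2)/(n - 1)`` (a.k.a. Hexp),
* polymorphism information content ``PIC = 1 - S2 - S2^2 + S4`` with
  ``Sr = sum p_i^r``,
* match probability ``MP = sum g_j^2`` over *observed* genotype frequencies,
  ``PD = 1 - MP`` (``DP`` for SNPs),
* power of exclusion ``PE = h^2 (1 - 2 h H^2)`` and typical paternity index
  ``TPI = 1/(2H)`` from the observed heterozygote proportion ``h`` (``H = 1-h``),
* X-marker mean exclusion chances (MEC) for the standard
  mother-daughter-alleged-father trio, the father-daughter duo, and the
  deficiency configuration in which the alleged father's mother is typed in
  his place; each closed form is the exact expectation over founder allele
  combinations (verified against enumeration in the test-suite),
* Y haplotype diversity ``HD = N(1 - sum p_i^2)/(N - 1)`` and discrimination
  capacity ``DC = k/N``.

Panel-wide combinations (CMP, CPD, CPE, CPI) accumulate in log space so that
products at the 1e-70 scale remain well-behaved, and render in the
``1 - x`` style used for combined discrimination/exclusion probabilities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .frequencies import FrequencyTable, YHaplotypeSet


def _as_probs(freqs: FrequencyTable | Sequence[float] | np.ndarray) -> np.ndarray:
    if isinstance(freqs, FrequencyTable):
        p = freqs.freq_array()
    else:
        p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(p < 0):
        raise ValueError("negative frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return p


def _power_sums(p: np.ndarray, upto: int = 5) -> list[float]:
    return [float(np.sum(p**r)) for r in range(upto + 1)]


# ---------------------------------------------------------------------------
# per-locus statistics
# ---------------------------------------------------------------------------

def gene_diversity(freqs: FrequencyTable | Sequence[float], n: int) -> float:
    """Unbiased gene diversity (Hexp) from allele frequencies and the number
    of allele observations ``n``."""
    if n < 2:
        raise ValueError("gene diversity undefined for n < 2")
    p = _as_probs(freqs)
    return float(n * (1.0 - np.sum(p**2)) / (n - 1))


def pic(freqs: FrequencyTable | Sequence[float]) -> float:
    """Polymorphism information content."""
    p = _as_probs(freqs)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - s2 - s2 * s2 + s4


def match_probability(genotype_counts: Mapping[object, int]) -> tuple[float, float]:
    """Match probability and power of discrimination from observed genotype
    counts (the probability that two individuals drawn with replacement from
    the sample share a genotype)."""
    counts = np.array(list(genotype_counts.values()), dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise ValueError("match probability needs at least one observed genotype")
    g = counts / counts.sum()
    mp = float(np.sum(g**2))
    return mp, 1.0 - mp


def pe_tpi(h: float) -> tuple[float, float]:
    """Power of exclusion and typical paternity index from the observed
    heterozygote proportion ``h``. ``TPI`` is ``inf`` when every sample is
    heterozygous."""
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"heterozygote proportion out of [0,1]: {h}")
    H = 1.0 - h
    pe = h * h * (1.0 - 2.0 * h * H * H)
    tpi = math.inf if H == 0.0 else 1.0 / (2.0 * H)
    return pe, tpi


@dataclass
class LocusStats:
    """Forensic parameter bundle for one autosomal (or SNP) locus."""

    locus: str
    n_obs: int
    Hobs: float
    Hexp: float
    PIC: float
    MP: float
    PD: float
    PE: float
    TPI: float

    @property
    def GD(self) -> float:
        return self.Hexp

    @property
    def DP(self) -> float:  # SNP synonym
        return self.PD


def autosomal_locus_stats(
    locus: str,
    freqs: FrequencyTable,
    genotype_counts: Mapping[object, int],
    het_count: int,
) -> LocusStats:
    """Assemble the per-locus bundle from a frequency table, observed
    genotype counts, and the number of heterozygous samples."""
    n_geno = sum(genotype_counts.values())
    if n_geno < 1:
        raise ValueError(f"{locus}: no genotypes")
    h = het_count / n_geno
    mp, pd_ = match_probability(genotype_counts)
    pe, tpi = pe_tpi(h)
    return LocusStats(
        locus=locus,
        n_obs=freqs.denominator,
        Hobs=h,
        Hexp=gene_diversity(freqs, freqs.denominator),
        PIC=pic(freqs),
        MP=mp,
        PD=pd_,
        PE=pe,
        TPI=tpi,
    )


def snp_stats(
    locus: str,
    freqs: FrequencyTable,
    genotype_counts: Mapping[object, int],
    het_count: int,
) -> LocusStats:
    """Same bundle restricted to a biallelic SNP locus (DP = PD)."""
    if len(freqs.counts) > 2:
        raise ValueError(f"{locus}: SNP locus with >2 alleles")
    return autosomal_locus_stats(locus, freqs, genotype_counts, het_count)


# ---------------------------------------------------------------------------
# X-marker statistics
# ---------------------------------------------------------------------------

@dataclass
class XStats:
    """X-marker discrimination and mean-exclusion-chance bundle."""

    locus: str
    PD_M: float
    PD_F: float
    MEC_Kruger: float
    MEC_Kishida: float
    MEC_Desmarais: float
    MEC_Desmarais_Duo: float


def x_discrimination(freqs: FrequencyTable | Sequence[float]) -> tuple[float, float]:
    """Power of discrimination in females and males from pooled X
    frequencies: males are hemizygous (``PD_M = 1 - S2``), female genotype
    frequencies follow HWE (``PD_F = 1 - (2 S2^2 - S4)``)."""
    p = _as_probs(freqs)
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    return 1.0 - (2.0 * s2 * s2 - s4), 1.0 - s2


def mec_kruger(freqs: FrequencyTable | Sequence[float]) -> float:
    """MEC in the deficiency configuration: mother and daughter typed, the
    alleged father unavailable and his mother typed in his place. Exact
    closed form of the founder-enumeration expectation."""
    p = _as_probs(freqs)
    _, _, s2, s3, s4, s5 = _power_sums(p, 5)
    return 1.0 - 2 * s2 + s3 + 2 * s4 - 3 * s5 - 2 * s2 * s2 + 3 * s2 * s3


def mec_trio(freqs: FrequencyTable | Sequence[float]) -> float:
    """MEC in the standard mother-daughter-alleged-father trio.

    The exact expectation over founder combinations reduces algebraically to
    the PIC form ``1 - S2 - S2^2 + S4``.
    """
    return pic(freqs)


def mec_duo(freqs: FrequencyTable | Sequence[float]) -> float:
    """MEC in the daughter-alleged-father duo (mother unavailable):
    ``1 - 2 S2 + S3``."""
    p = _as_probs(freqs)
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    return 1.0 - 2.0 * s2 + s3


def mec_suite(freqs: FrequencyTable, *, locus: str | None = None) -> XStats:
    """The X-marker statistics bundle from a pooled frequency table."""
    name = locus or (freqs.locus if isinstance(freqs, FrequencyTable) else "X")
    pd_f, pd_m = x_discrimination(freqs)
    trio = mec_trio(freqs)
    return XStats(
        locus=name,
        PD_M=pd_m,
        PD_F=pd_f,
        MEC_Kruger=mec_kruger(freqs),
        MEC_Kishida=trio,
        MEC_Desmarais=trio,
        MEC_Desmarais_Duo=mec_duo(freqs),
    )


# ---------------------------------------------------------------------------
# Y-marker statistics
# ---------------------------------------------------------------------------

@dataclass
class YStats:
    """Haplotype-level Y statistics."""

    n: int
    k: int
    HD: float
    DC: float
    unique_fraction: float


def haplotype_diversity(yh: YHaplotypeSet) -> YStats:
    """Haplotype diversity, discrimination capacity and the fraction of
    haplotypes observed exactly once."""
    counts = np.array(list(yh.counts().values()), dtype=float)
    n = int(counts.sum())
    if n < 2:
        raise ValueError("haplotype diversity undefined for N < 2")
    p = counts / n
    hd = n * (1.0 - float(np.sum(p**2))) / (n - 1)
    k = counts.size
    dc = k / n  # k / sum(p_i * N)
    unique = float(np.sum(counts == 1)) / k
    return YStats(n=n, k=k, HD=hd, DC=dc, unique_fraction=unique)


# ---------------------------------------------------------------------------
# panel combination
# ---------------------------------------------------------------------------

def _format_one_minus(ln_x: float) -> str:
    """Render ``1 - x`` with ``x = exp(ln_x)`` in scientific notation."""
    log10 = ln_x / math.log(10.0)
    exp10 = math.floor(log10)
    mantissa = 10 ** (log10 - exp10)
    return f"1-{mantissa:.4g}e{exp10:+d}"


@dataclass
class PanelStats:
    """Combined panel statistics, kept in log space."""

    n_loci: int
    ln_cmp: float  # ln of combined match probability, sum of ln(MP_l)
    ln_one_minus_cpe: float  # ln of prod(1 - PE_l)
    ln_cpi: float  # ln of prod(TPI_l)

    @property
    def CMP(self) -> float:
        return math.exp(self.ln_cmp)

    @property
    def CPD(self) -> float:
        return 1.0 - math.exp(self.ln_cmp)

    @property
    def CPE(self) -> float:
        return 1.0 - math.exp(self.ln_one_minus_cpe)

    @property
    def CPI(self) -> float:
        return math.exp(self.ln_cpi)

    def render(self) -> dict[str, str | float]:
        """Human-readable forms mirroring the ``1 - x`` report style."""
        return {
            "CMP": self.CMP,
            "CPD": _format_one_minus(self.ln_cmp),
            "CPE": _format_one_minus(self.ln_one_minus_cpe),
            "CPE_percent": 100.0 * self.CPE,
            "CPI": self.CPI,
            "log10_CMP": self.ln_cmp / math.log(10.0),
            "log10_CPI": self.ln_cpi / math.log(10.0),
        }


def combine_panel(stats: Sequence[LocusStats]) -> PanelStats:
    """Combine independent loci: ``CMP = prod MP``, ``CPD = 1 - CMP``,
    ``CPE = 1 - prod(1 - PE)``, ``CPI = prod TPI``."""
    if not stats:
        raise ValueError("combine_panel needs at least one locus")
    ln_cmp = 0.0
    ln_q = 0.0
    ln_cpi = 0.0
    for s in stats:
        if s.MP <= 0:
            raise ValueError(f"{s.locus}: non-positive MP")
        ln_cmp += math.log(s.MP)
        ln_q += math.log1p(-s.PE) if s.PE < 1.0 else -math.inf
        ln_cpi += math.log(s.TPI) if s.TPI > 0 else -math.inf
    return PanelStats(
        n_loci=len(stats), ln_cmp=ln_cmp, ln_one_minus_cpe=ln_q, ln_cpi=ln_cpi
    )
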