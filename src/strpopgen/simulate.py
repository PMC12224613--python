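"""Synthetic populations with the statistical structure the pipeline assumes.

The generator draws unrelated individuals: autosomal and female-X genotypes
are independent allele pairs from the locus spectrum (i.e. Hardy-Weinberg
equilibrium holds by construction), male X and Y calls are hemizygous
draws, and multi-copy "a/b" Y markers draw two alleles per male. Sequence-
allele diversity is layered on shared length classes by "decorating" a
length-based spectrum with repeat-region variant bracket strings and
flanking-region annotations. Per-locus coverage is log-normal, giving the
heavy-tailed depth profile typical of multiplex MPS panels.

Reproducibility: one global seed expands into independent per-locus streams
keyed by a stable hash of the locus name, so adding or removing a locus
never perturbs the draws of the others.

The full-panel fixture (:func:`make_panel_fixture`) mirrors the surveyed
kit's shape — 66 A-STRs, 29 X-STRs, 75 Y-STRs, 132 A-SNPs, 3 Y-SNPs typed
on 50 males and 50 females — and injects the published novel-variant
bracket strings verbatim as the sequence vocabulary of the loci they belong
to. The marker name list is a synthetic stand-in assembled from the loci
the survey names plus standard forensic markers; class counts, not the
exact kit inventory, are what it reproduces.
"""
from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTable
from .genotypes import GenotypeTable
from .loci import AUTOSOMAL, LocusDef, SNP, STR, X, Y
from .reported_variants import (
    MULTICOPY_Y,
    PANEL_COMPOSITION,
    REPORTED_VARIANTS,
    reported_locus_def,
)


def locus_stream(seed: int, locus_name: str) -> np.random.Generator:
    """Independent per-locus RNG stream from one global seed.

    The spawn key is a stable 32-bit hash of the locus name, so streams do
    not depend on catalogue order or size.
    """
    h = int.from_bytes(hashlib.sha256(locus_name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(h,)))


@dataclass
class SimConfig:
    """Configuration of one synthetic population draw."""

    loci: dict[str, LocusDef]
    spectra: dict[str, dict[str, float]]
    n_males: int = 50
    n_females: int = 50
    seed: int = 0
    #: per-locus (log-mean, log-sd) of the log-normal coverage model
    coverage: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in self.loci:
            if name not in self.spectra:
                raise ValueError(f"no spectrum for locus {name}")
        for name, spec in self.spectra.items():
            if name not in self.loci:
                raise ValueError(f"spectrum for unknown locus {name}")
            total = sum(spec.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name}: spectrum sums to {total}")


def _draw(rng: np.random.Generator, tokens: list[str], probs: np.ndarray, size: int) -> list[str]:
    idx = rng.choice(len(tokens), size=size, p=probs)
    return [tokens[i] for i in idx]


def simulate_population(cfg: SimConfig) -> tuple[GenotypeTable, CoverageTable, dict]:
    """Draw a population; returns genotypes, coverage, and the truth record
    (every generating frequency and coverage parameter, plus the seed)."""
    samples = [f"M{i+1:03d}" for i in range(cfg.n_males)] + [
        f"F{i+1:03d}" for i in range(cfg.n_females)
    ]
    sex = {s: ("M" if s.startswith("M") else "F") for s in samples}
    gt = GenotypeTable(samples=samples, sex=sex, loci=dict(cfg.loci))
    cov_rows = []
    for name, locus in cfg.loci.items():
        rng = locus_stream(cfg.seed, name)
        spec = cfg.spectra[name]
        tokens = list(spec)
        probs = np.array(list(spec.values()), dtype=float)
        probs = probs / probs.sum()
        for s in samples:
            n_calls = locus.expected_calls(sex[s])
            if n_calls:
                gt.set(s, name, _draw(rng, tokens, probs, n_calls))
        mu, sigma = cfg.coverage.get(name, (np.log(5000.0), 1.0))
        reads = np.round(rng.lognormal(mean=mu, sigma=sigma, size=len(samples))).astype(int)
        for s, r in zip(samples, reads):
            cov_rows.append({"locus": name, "sample": s, "reads": int(r)})
    cov = CoverageTable(pd.DataFrame(cov_rows, columns=["locus", "sample", "reads"]))
    truth = {
        "seed": cfg.seed,
        "n_males": cfg.n_males,
        "n_females": cfg.n_females,
        "spectra": {k: dict(v) for k, v in cfg.spectra.items()},
        "coverage": {k: list(v) for k, v in cfg.coverage.items()},
    }
    return gt, cov, truth


# ---------------------------------------------------------------------------
# spectrum construction
# ---------------------------------------------------------------------------

_VARIANT_SUB = {"A": "G", "C": "T", "G": "A", "T": "C"}


def _variant_unit(motif: str, pos: int) -> str:
    return motif[:pos] + _VARIANT_SUB[motif[pos]] + motif[pos + 1 :]


def decorate_spectrum(
    motif: str,
    lb_freqs: Mapping[int, float],
    rng: np.random.Generator,
    *,
    rr_variant_prob: float = 0.3,
    fr_variant_prob: float = 0.15,
    chrom: str = "chr1",
) -> dict[str, float]:
    """Layer sequence diversity over a length-based spectrum.

    Each length class ``u`` gets a reference bracket string ``[MOTIF]u``;
    with probability ``rr_variant_prob`` the class gains a repeat-region
    variant (a compound structure of the same total length) and with
    probability ``fr_variant_prob`` a flanking-SNP-annotated copy. Class
    mass is split among its sequence alleles.
    """
    out: dict[str, float] = {}
    for units, f in lb_freqs.items():
        ref = f"[{motif}]{units}"
        members = [ref]
        if units >= 3 and rng.random() < rr_variant_prob:
            split = int(rng.integers(1, units - 1))
            members.append(f"[{motif}]{split} [{_variant_unit(motif, 1)}]1 [{motif}]{units - split - 1}")
        if rng.random() < fr_variant_prob:
            pos = int(rng.integers(1_000_000, 9_999_999))
            members.append(f"{ref} {{up:SNP:GRCh38-{chrom}:{pos}:{_VARIANT_SUB[motif[0]]}}}")
        weights = rng.dirichlet(np.ones(len(members)) * 5.0)
        for m, w in zip(members, weights):
            out[m] = out.get(m, 0.0) + f * float(w)
    total = sum(out.values())
    return {k: v / total for k, v in out.items()}


def dirichlet_lb_spectrum(
    rng: np.random.Generator,
    *,
    n_alleles: int = 8,
    concentration: float = 1.5,
    min_units: int = 8,
) -> dict[int, float]:
    """A length-based allele spectrum from a symmetric Dirichlet draw."""
    probs = rng.dirichlet(np.full(n_alleles, concentration))
    return {min_units + i: float(p) for i, p in enumerate(probs)}


# ---------------------------------------------------------------------------
# full-panel fixture
# ---------------------------------------------------------------------------

_NAMED_ASTR = [
    "D1S1656", "D1S1677", "D1S1627", "D1GATA113", "D2S441", "D2S1338", "D2S1360",
    "D3S1358", "D3S1744", "D3S3045", "D3S3053", "D3S4529", "D4S2364", "D4S2408",
    "D5S818", "D5S2800", "D6S474", "D6S477", "D6S1017", "D7S820", "D7S1517",
    "D7S3048", "D8S1115", "D8S1132", "D8S1179", "D9S925", "D9S1122", "D9S2157",
    "D10S2325", "D11S2368", "D11S4463", "D12S391", "D13S317", "D13S325",
    "D14S608", "D14S1434", "D15S659", "D16S539", "D17S974", "D17S1290",
    "D17S1301", "D18S51", "D18S853", "D20S470", "D20S482", "D20S1082",
    "D21S11", "D21S1270", "D21S2055", "D22GATA198B", "vWA", "TPOX", "TH01",
    "CSF1PO", "FGA", "Penta D", "Penta E", "D5S2500", "D6S1043", "D10S1248",
    "D12ATA63", "D19S433", "D22S1045", "D2S1776", "D3S1745", "D4S2366",
]
_NAMED_XSTR = [
    "DXS101", "DXS6789", "DXS6800", "DXS6803", "DXS6809", "DXS7132", "DXS7133",
    "DXS7423", "DXS7424", "DXS8377", "DXS8378", "DXS9895", "DXS9902", "DXS981",
    "DXS10074", "DXS10079", "DXS10103", "DXS10135", "DXS10146", "DXS10148",
    "GATA165B12", "GATA172D05", "GATA31E08", "HPRTB", "DXS10101", "DXS10134",
    "DXS6807", "DXS9898", "DXS10075",
]
_NAMED_YSTR = [
    "DYS19", "DYS385a/b", "DYS388", "DYS389I", "DYS389II", "DYS390", "DYS391",
    "DYS392", "DYS393", "DYS434", "DYS435", "DYS437", "DYS438", "DYS439",
    "DYS448", "DYS450", "DYS453", "DYS454", "DYS455", "DYS456", "DYS458",
    "DYS460", "DYS472", "DYS476", "DYS481", "DYS485", "DYS502", "DYS511",
    "DYS512", "DYS513", "DYS518", "DYS520", "DYS527a/b", "DYS530", "DYS531",
    "DYS533", "DYS538", "DYS541", "DYS549", "DYS552", "DYS565", "DYS568",
    "DYS570", "DYS571", "DYS572", "DYS573", "DYS576", "DYS578", "DYS585",
    "DYS587", "DYS590", "DYS613", "DYS616", "DYS617", "DYS626", "DYS627",
    "DYS630", "DYS635", "DYS638", "DYS640", "DYS643", "DYS644", "DYS645",
    "DYS710", "DYS713", "DYS720", "DYS722", "DYF387S1a/b", "Y-GATA-H4",
    "DYS389B", "DYS449", "DYS505", "DYS522", "DYS508", "DYS632",
]
_NAMED_SNP = ["rs1736442", "rs1109037", "rs576261", "rs740910", "rs9956753",
              "rs61561022", "rs11910883"]

_MOTIFS = ["TCTA", "TATC", "AGAT", "AAAG", "GATA", "CTTT", "TAGA", "ATAG"]


def _filler_allele(reported_motif: str) -> str:
    """A top-up reference allele built from the first bracketed unit of a
    reported motif string; its high repeat count keeps it distinct from
    every reported allele."""
    m = re.search(r"\[([ACGT]+)\]", reported_motif)
    unit = m.group(1) if m else "TCTA"
    return f"[{unit}]99"


def panel_catalogue() -> dict[str, LocusDef]:
    """Synthetic full-panel locus catalogue with the surveyed class counts
    (66/29/75 STRs + 132 A-SNPs + 3 Y-SNPs)."""
    reported_names = {v.locus for v in REPORTED_VARIANTS}
    out: dict[str, LocusDef] = {}

    def add(name: str, chrom: str, marker: str) -> None:
        if name in reported_names:
            out[name] = reported_locus_def(name)
            return
        motif = None if marker == SNP else (3 if name in ("D22GATA198B",) else 4)
        if name in ("Penta D", "Penta E"):
            motif = 5
        out[name] = LocusDef(
            name=name,
            chrom_class=chrom,
            motif_len=motif,
            copy_count=2 if name in MULTICOPY_Y else 1,
            marker_type=marker,
        )

    for name in _NAMED_ASTR[: PANEL_COMPOSITION["A-STR"]]:
        add(name, AUTOSOMAL, STR)
    for name in _NAMED_XSTR[: PANEL_COMPOSITION["X-STR"]]:
        add(name, X, STR)
    for name in _NAMED_YSTR[: PANEL_COMPOSITION["Y-STR"]]:
        add(name, Y, STR)
    snp_names = list(_NAMED_SNP)
    i = 1
    while len(snp_names) < PANEL_COMPOSITION["A-SNP"]:
        cand = f"rs9{900000 + i}"
        if cand not in snp_names:
            snp_names.append(cand)
        i += 1
    for name in snp_names:
        add(name, AUTOSOMAL, SNP)
    for j in range(PANEL_COMPOSITION["Y-SNP"]):
        add(f"Y-SNP-{j+1}", Y, SNP)
    assert len(out) == sum(PANEL_COMPOSITION.values())
    return out


def panel_spectra(catalogue: Mapping[str, LocusDef], seed: int) -> dict[str, dict[str, float]]:
    """Per-locus spectra for the full panel.

    Loci with published novel-variant rows get those bracket strings
    verbatim at their printed frequencies, topped up with a reference
    allele; other STRs get decorated Dirichlet spectra; SNPs biallelic.
    """
    reported: dict[str, list] = {}
    for v in REPORTED_VARIANTS:
        reported.setdefault(v.locus, []).append(v)
    spectra: dict[str, dict[str, float]] = {}
    for name, locus in catalogue.items():
        rng = locus_stream(seed, "spectrum:" + name)
        if locus.marker_type == SNP:
            p = float(rng.uniform(0.15, 0.85))
            ref, alt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
            spectra[name] = {str(ref): p, str(alt): 1.0 - p}
            continue
        if name in reported:
            rows = reported[name]
            spec = {r.motif: r.frequency for r in rows}
            rest = 1.0 - sum(spec.values())
            spec[_filler_allele(rows[0].motif)] = rest
            spectra[name] = spec
            continue
        motif = _MOTIFS[
            int.from_bytes(hashlib.sha256(name.encode()).digest()[:2], "big") % len(_MOTIFS)
        ]
        if locus.motif_len == 3:
            motif = motif[:3]
        elif locus.motif_len == 5:
            motif = motif + motif[0]
        lb = dirichlet_lb_spectrum(rng, n_alleles=int(rng.integers(5, 12)))
        spectra[name] = decorate_spectrum(motif, lb, rng)
    return spectra


def panel_coverage_params(catalogue: Mapping[str, LocusDef], seed: int) -> dict[str, tuple[float, float]]:
    """Heavy-tailed per-locus log-normal coverage parameters; the named
    extreme loci (DYS616 low, DYS385a/b very high) anchor the spread."""
    out: dict[str, tuple[float, float]] = {}
    for name in catalogue:
        rng = locus_stream(seed, "coverage:" + name)
        mu = float(rng.normal(np.log(6000.0), 0.9))
        out[name] = (mu, 0.6)
    if "DYS616" in out:
        out["DYS616"] = (float(np.log(486.0)), 0.3)
    if "DYS385a/b" in out:
        out["DYS385a/b"] = (float(np.log(145175.0)), 0.3)
    return out


def make_panel_fixture(seed: int) -> tuple[SimConfig, GenotypeTable, CoverageTable, dict]:
    """The full-panel synthetic cohort: 50 males + 50 females across the
    surveyed panel shape, published bracket strings injected verbatim."""
    catalogue = panel_catalogue()
    cfg = SimConfig(
        loci=catalogue,
        spectra=panel_spectra(catalogue, seed),
        n_males=50,
        n_females=50,
        seed=seed,
        coverage=panel_coverage_params(catalogue, seed),
    )
    gt, cov, truth = simulate_population(cfg)
    return cfg, gt, cov, truth


def population_with_injected_counts(
    rows: Sequence, *, n_males: int = 50, n_females: int = 50
) -> GenotypeTable:
    """A deterministic cohort in which each reported allele appears exactly
    its printed number of times.

    Used to check that frequency computation reproduces printed
    count/frequency pairs under each chromosome class's denominator.
    Injected alleles are placed in females first for X loci, so the male
    double-count convention cannot inflate an injected count.
    """
    loci = {}
    by_locus: dict[str, list] = {}
    for r in rows:
        loci[r.locus] = reported_locus_def(r.locus)
        by_locus.setdefault(r.locus, []).append(r)
    samples = [f"M{i+1:03d}" for i in range(n_males)] + [
        f"F{i+1:03d}" for i in range(n_females)
    ]
    sex = {s: ("M" if s.startswith("M") else "F") for s in samples}
    gt = GenotypeTable(samples=samples, sex=sex, loci=loci)
    for name, locus_rows in by_locus.items():
        locus = loci[name]
        tokens: list[str] = []
        for r in locus_rows:
            tokens.extend([r.motif] * r.count)
        filler = _filler_allele(locus_rows[0].motif)
        if locus.chrom_class == AUTOSOMAL:
            slots = [(s, 2) for s in samples]
        elif locus.chrom_class == X:
            # females first: injected alleles land on female chromosomes
            slots = [(s, 2) for s in samples if sex[s] == "F"] + [
                (s, 1) for s in samples if sex[s] == "M"
            ]
        else:
            slots = [(s, locus.copy_count) for s in samples if sex[s] == "M"]
        total = sum(k for _, k in slots)
        if len(tokens) > total:
            raise ValueError(f"{name}: more injected alleles than chromosomes")
        tokens = tokens + [filler] * (total - len(tokens))
        pos = 0
        for s, k in slots:
            gt.set(s, name, tokens[pos : pos + k])
            pos += k
    return gt


def write_truth_json(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
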