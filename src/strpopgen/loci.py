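"""Marker (locus) definitions for a mixed STR/SNP forensic panel.

A locus is described by its chromosome class (autosomal, X or Y), its marker
type (STR or SNP), the canonical repeat-unit length for STRs, and the number
of allele copies contributed per chromosome. Almost all markers contribute a
single copy; a few Y markers (e.g. DYS385a/b, DYF387S1a/b, DYS527a/b) are
amplified from two paralogous sites and yield two alleles per male.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

AUTOSOMAL = "autosomal"
X = "X"
Y = "Y"
CHROM_CLASSES = (AUTOSOMAL, X, Y)

STR = "STR"
SNP = "SNP"
MARKER_TYPES = (STR, SNP)


@dataclass(frozen=True)
class LocusDef:
    """Identity and conventions for one marker.

    Parameters
    ----------
    name
        Marker identifier, e.g. ``"D8S1132"`` or ``"rs576261"``.
    chrom_class
        One of ``"autosomal"``, ``"X"``, ``"Y"``.
    motif_len
        Canonical repeat-unit length in nucleotides (2-5) for STRs; ``None``
        for SNPs.
    copy_count
        Alleles contributed per chromosome: 1, or 2 for multi-copy "a/b" Y
        markers.
    marker_type
        ``"STR"`` or ``"SNP"``.
    """

    name: str
    chrom_class: str
    motif_len: int | None = 4
    copy_count: int = 1
    marker_type: str = STR

    def __post_init__(self) -> None:
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(f"{self.name}: unknown chrom_class {self.chrom_class!r}")
        if self.marker_type not in MARKER_TYPES:
            raise ValueError(f"{self.name}: unknown marker_type {self.marker_type!r}")
        if self.marker_type == STR:
            if self.motif_len not in (2, 3, 4, 5):
                raise ValueError(
                    f"{self.name}: STR motif_len must be 2-5, got {self.motif_len}"
                )
        if self.copy_count not in (1, 2):
            raise ValueError(f"{self.name}: copy_count must be 1 or 2")
        if self.copy_count == 2 and self.chrom_class != Y:
            raise ValueError(f"{self.name}: multi-copy loci are Y markers")

    @property
    def is_multicopy(self) -> bool:
        return self.copy_count == 2

    def expected_calls(self, sex: str) -> int:
        """Number of allele calls expected for a sample of the given sex."""
        if self.chrom_class == AUTOSOMAL:
            return 2
        if self.chrom_class == X:
            return 2 if sex == "F" else 1
        # Y
        return 0 if sex == "F" else self.copy_count


_CATALOGUE_COLUMNS = ["name", "chrom_class", "motif_len", "copy_count", "marker_type"]


def write_locus_catalogue(loci: Iterable[LocusDef], path: str | Path) -> None:
    """Write a locus catalogue TSV (columns: name, chrom_class, motif_len,
    copy_count, marker_type)."""
    rows = [
        {
            "name": l.name,
            "chrom_class": l.chrom_class,
            "motif_len": "" if l.motif_len is None else l.motif_len,
            "copy_count": l.copy_count,
            "marker_type": l.marker_type,
        }
        for l in loci
    ]
    pd.DataFrame(rows, columns=_CATALOGUE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_locus_catalogue(path: str | Path) -> dict[str, LocusDef]:
    """Read a locus catalogue TSV into an ordered name -> LocusDef mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str})
    missing = set(_CATALOGUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"locus catalogue missing columns: {sorted(missing)}")
    out: dict[str, LocusDef] = {}
    for row in df.itertuples(index=False):
        motif = row.motif_len
        motif_len = None if pd.isna(motif) or motif == "" else int(motif)
        locus = LocusDef(
            name=row.name,
            chrom_class=row.chrom_class,
            motif_len=motif_len,
            copy_count=int(row.copy_count),
            marker_type=row.marker_type,
        )
        if locus.name in out:
            raise ValueError(f"duplicate locus {locus.name} in catalogue")
        out[locus.name] = locus
    return out
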