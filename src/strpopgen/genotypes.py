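"""Sample x locus genotype tables with chromosome-aware ploidy validation.

The table holds, per (sample, locus), a tuple of allele tokens. Tokens are
either full bracketed SB strings (see :mod:`strpopgen.nomenclature`), bare LB
length designations (``"14.1"``), or SNP base calls (``"A"``). Expected call
counts follow the chromosome class: autosomal loci carry two calls per
sample; X loci two in females and one in males; Y loci one (or two, for
multi-copy "a/b" markers) in males and none in females. A missing call (empty
cell) is allowed anywhere and is excluded from both numerator and denominator
of downstream frequency tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .loci import AUTOSOMAL, LocusDef, X, Y

SEXES = ("M", "F")


class ValidationError(ValueError):
    """A genotype table violates its ploidy/sex contract."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass
class GenotypeTable:
    """Allele calls for a cohort.

    ``calls[(sample, locus_name)]`` is a tuple of allele tokens (possibly
    empty for a dropped-out marker). Absent keys mean the same as empty
    tuples.
    """

    samples: list[str]
    sex: dict[str, str]
    loci: dict[str, LocusDef]
    calls: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.samples:
            if self.sex.get(s) not in SEXES:
                raise ValidationError([f"sample {s}: sex must be M or F, got {self.sex.get(s)!r}"])

    def get(self, sample: str, locus: str) -> tuple[str, ...]:
        return self.calls.get((sample, locus), ())

    def set(self, sample: str, locus: str, tokens: Sequence[str]) -> None:
        self.calls[(sample, locus)] = tuple(tokens)

    def n_males(self) -> int:
        return sum(1 for s in self.samples if self.sex[s] == "M")

    def n_females(self) -> int:
        return sum(1 for s in self.samples if self.sex[s] == "F")

    def males(self) -> list[str]:
        return [s for s in self.samples if self.sex[s] == "M"]

    def females(self) -> list[str]:
        return [s for s in self.samples if self.sex[s] == "F"]

    def validate(self, loci: Iterable[str] | None = None) -> list[str]:
        """Return per-sample ploidy problems (empty when the table conforms).

        Missing calls are never a problem; a *wrong number* of calls, or any
        Y call in a female, is.
        """
        problems = []
        names = list(loci) if loci is not None else list(self.loci)
        for name in names:
            locus = self.loci[name]
            for s in self.samples:
                tokens = self.get(s, name)
                if not tokens:
                    continue
                expected = locus.expected_calls(self.sex[s])
                if expected == 0:
                    problems.append(f"sample {s}: female carries calls at Y locus {name}")
                elif len(tokens) != expected:
                    problems.append(
                        f"sample {s}: locus {name} expects {expected} call(s), got {len(tokens)}"
                    )
        return problems

    def validate_or_raise(self, loci: Iterable[str] | None = None) -> None:
        problems = self.validate(loci)
        if problems:
            raise ValidationError(problems)

    def drop_sample(self, sample: str) -> "GenotypeTable":
        """A copy of the table without ``sample``."""
        return GenotypeTable(
            samples=[s for s in self.samples if s != sample],
            sex={s: x for s, x in self.sex.items() if s != sample},
            loci=self.loci,
            calls={k: v for k, v in self.calls.items() if k[0] != sample},
        )

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row: dict[str, str] = {"sample": s, "sex": self.sex[s]}
            for name in self.loci:
                row[name] = "/".join(self.get(s, name))
            rows.append(row)
        return pd.DataFrame(rows, columns=["sample", "sex", *self.loci])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_genotype_table(
    path: str | Path, catalogue: Mapping[str, LocusDef], *, validate: bool = True
) -> GenotypeTable:
    """Read the genotype TSV dialect (columns: sample, sex, one per locus;
    diploid cells ``"A1/A2"``, hemizygous single token, empty = missing)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return genotype_table_from_frame(df, catalogue, validate=validate)


def read_genotype_xlsx(
    path: str | Path, catalogue: Mapping[str, LocusDef], *, validate: bool = True
) -> GenotypeTable:
    """Best-effort adapter for spreadsheet genotype reports using the same
    column layout as the TSV dialect (first sheet, header row)."""
    df = pd.read_excel(path, dtype=str).fillna("")
    return genotype_table_from_frame(df, catalogue, validate=validate)


def genotype_table_from_frame(
    df: pd.DataFrame, catalogue: Mapping[str, LocusDef], *, validate: bool = True
) -> GenotypeTable:
    for col in ("sample", "sex"):
        if col not in df.columns:
            raise ValidationError([f"genotype table missing column {col!r}"])
    locus_cols = [c for c in df.columns if c in catalogue]
    unknown = [c for c in df.columns if c not in catalogue and c not in ("sample", "sex")]
    if unknown:
        raise ValidationError([f"unknown locus column(s): {unknown}"])
    gt = GenotypeTable(
        samples=list(df["sample"]),
        sex=dict(zip(df["sample"], df["sex"])),
        loci={name: catalogue[name] for name in locus_cols},
    )
    # plain-tuple iteration: locus names like "DYF387S1a/b" are not valid
    # namedtuple fields
    col_idx = {c: i for i, c in enumerate(df.columns)}
    for row in df.itertuples(index=False, name=None):
        sample = row[col_idx["sample"]]
        for name in locus_cols:
            cell = str(row[col_idx[name]]).strip()
            if cell:
                gt.set(sample, name, tuple(t.strip() for t in cell.split("/")))
    if validate:
        gt.validate_or_raise()
    return gt
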