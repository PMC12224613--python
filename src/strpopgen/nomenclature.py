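"""Bracketed repeat nomenclature for sequence-based STR alleles.

Sequence-based (SB) STR alleles are written in the bracketed form recommended
for forensic sequence nomenclature, e.g.::

    [TCTA]13 TCTG [TCTA]1
    [AAAG]4 N6 [AAAG]12 N27 [AAGG]4
    tatatatatgtctgt[CTAT]8 [CTAC]2 [CTAT]3

Tokens are:

* ``[SEQ]n``   -- a repeat block: ``n`` copies of the uppercase unit ``SEQ``;
* ``SEQ``      -- an uppercase run: an interruption / partial repeat, counted
  once;
* ``Nk``       -- a spacer of ``k`` undisplayed nucleotides between repeat
  stretches (excluded from the length designation);
* lowercase runs -- flanking sequence shown for context, excluded from the
  repeat region;
* an optional trailing ``{...}`` group carrying flanking-region (FR) variant
  annotations, ``side:kind:position:observed`` separated by ``;`` (e.g.
  ``{up:SNP:GRCh38-chr2:68011829:C}``).

The length designation (the CE-compatible allele name) is computed from the
repeat-region length: all bracketed blocks plus uppercase interruptions count,
lowercase flanks and ``N`` spacers do not; ``units = L // motif_len`` with a
``.remainder`` suffix when ``L % motif_len != 0``.

Two SB alleles are identical only if their block structure *and* their FR
variant annotations agree; alleles that share a length designation but differ
in sequence are distinct SB alleles collapsing to one length-based (LB)
allele.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .loci import LocusDef


class NomenclatureError(ValueError):
    """Base class for allele-string problems."""


class AlleleParseError(NomenclatureError):
    """Raised when an allele string cannot be tokenised."""


BRACKETED = "bracketed"
INTERRUPTION = "interruption"
SPACER = "spacer"
FLANK = "flank"

_UPPER = re.compile(r"[ACGT]+\Z")
_LOWER = re.compile(r"[acgt]+\Z")


@dataclass(frozen=True)
class RepeatBlock:
    """One token of a bracketed allele string."""

    token_kind: str
    seq: str = ""
    count: int = 1
    spacer_len: int = 0

    def __post_init__(self) -> None:
        if self.token_kind == BRACKETED:
            if not self.seq or not _UPPER.match(self.seq):
                raise AlleleParseError(f"bracketed block needs uppercase seq: {self.seq!r}")
            if self.count < 1:
                raise AlleleParseError(f"bracketed count must be >=1: {self.count}")
        elif self.token_kind == INTERRUPTION:
            if not self.seq or not _UPPER.match(self.seq):
                raise AlleleParseError(f"interruption needs uppercase seq: {self.seq!r}")
        elif self.token_kind == FLANK:
            if not self.seq or not _LOWER.match(self.seq):
                raise AlleleParseError(f"flank run must be lowercase: {self.seq!r}")
        elif self.token_kind == SPACER:
            if self.spacer_len < 1:
                raise AlleleParseError(f"spacer length must be >=1: {self.spacer_len}")
        else:
            raise AlleleParseError(f"unknown token kind {self.token_kind!r}")

    @property
    def repeat_region_len(self) -> int:
        """Nucleotides this token contributes to the length designation."""
        if self.token_kind == BRACKETED:
            return len(self.seq) * self.count
        if self.token_kind == INTERRUPTION:
            return len(self.seq)
        return 0

    def render(self) -> str:
        if self.token_kind == BRACKETED:
            return f"[{self.seq}]{self.count}"
        if self.token_kind == SPACER:
            return f"N{self.spacer_len}"
        return self.seq


_POSITION = re.compile(r"(?P<build>[A-Za-z0-9_.]+)-(?P<chrom>[Cc]hr[0-9XYM]+):\s?(?P<coord>\d+)\Z")
_FV_KINDS = ("SNP", "insertion", "deletion")
_FV_SIDES = {"up": "upstream", "dn": "downstream"}
_FV_SIDES_INV = {v: k for k, v in _FV_SIDES.items()}


@dataclass(frozen=True)
class FlankVariant:
    """A flanking-region variant attached to an SB allele.

    ``position`` is a build+chromosome+coordinate string such as
    ``"GRCh38-chr2:68011829"``.
    """

    position: str
    kind: str
    observed: str
    side: str

    def __post_init__(self) -> None:
        if self.kind not in _FV_KINDS:
            raise NomenclatureError(f"unknown flank-variant kind {self.kind!r}")
        if self.side not in ("upstream", "downstream"):
            raise NomenclatureError(f"unknown flank-variant side {self.side!r}")
        self.parse_position()

    def parse_position(self) -> tuple[str, str, int]:
        m = _POSITION.match(self.position)
        if not m:
            raise NomenclatureError(f"malformed variant position {self.position!r}")
        coord = int(m.group("coord"))
        if coord <= 0:
            raise NomenclatureError(f"non-positive coordinate in {self.position!r}")
        return m.group("build"), m.group("chrom"), coord

    def render(self) -> str:
        return f"{_FV_SIDES_INV[self.side]}:{self.kind}:{self.position}:{self.observed}"

    @classmethod
    def from_string(cls, text: str) -> "FlankVariant":
        parts = text.strip().split(":")
        if len(parts) < 4:
            raise AlleleParseError(f"malformed flank-variant annotation {text!r}")
        side, kind = parts[0], parts[1]
        observed = parts[-1]
        position = ":".join(parts[2:-1])
        if side not in _FV_SIDES:
            raise AlleleParseError(f"flank-variant side must be up/dn: {text!r}")
        return cls(position=position, kind=kind, observed=observed, side=_FV_SIDES[side])


@dataclass(frozen=True, order=True)
class Designation:
    """Repeat-count allele name: ``units`` full repeats plus ``remainder`` nt."""

    units: int
    remainder: int = 0

    def __post_init__(self) -> None:
        if self.units < 0 or self.remainder < 0:
            raise NomenclatureError("designation parts must be non-negative")

    def __str__(self) -> str:
        return str(self.units) if self.remainder == 0 else f"{self.units}.{self.remainder}"

    @classmethod
    def from_string(cls, text: str) -> "Designation":
        text = text.strip()
        if "." in text:
            units, remainder = text.split(".", 1)
            return cls(int(units), int(remainder))
        return cls(int(text))


# master tokenizer: brackets, spacers, letter runs
_TOKEN = re.compile(
    r"""
    \[(?P<motif>[^\]]*)\](?P<count>\d*)     # [SEQ]n
  | N(?P<spacer>\d+)                        # Nk spacer
  | (?P<letters>[A-Za-z]+)                  # interruption or flank run
  | (?P<space>\s+)
  | (?P<bad>.)
    """,
    re.VERBOSE,
)


@dataclass(frozen=True)
class SequenceAllele:
    """A parsed sequence-based STR allele: block structure + FR variants."""

    locus: LocusDef
    blocks: tuple[RepeatBlock, ...]
    flank_variants: tuple[FlankVariant, ...] = ()
    raw: str = field(default="", compare=False)

    @property
    def repeat_region_len(self) -> int:
        return sum(b.repeat_region_len for b in self.blocks)

    @property
    def designation(self) -> Designation:
        return designation_from_bracket(self)

    def canonical(self) -> str:
        """Canonical rendering: single space between tokens, ``[SEQ]n``
        brackets, FR annotations in a trailing ``{...}`` group."""
        body = " ".join(b.render() for b in self.blocks)
        if self.flank_variants:
            fv = "; ".join(v.render() for v in self.flank_variants)
            return f"{body} {{{fv}}}"
        return body

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()


def parse_bracket(raw: str, locus: LocusDef) -> SequenceAllele:
    """Parse a bracketed allele string for ``locus``.

    Raises :class:`AlleleParseError` naming the offending token on malformed
    brackets (missing count, empty motif), mixed-case letter runs, or unknown
    characters.
    """
    if raw is None or not str(raw).strip():
        raise AlleleParseError("empty allele string")
    text = str(raw).strip()

    flank_variants: list[FlankVariant] = []
    if "{" in text:
        if not text.endswith("}"):
            raise AlleleParseError(f"unterminated flank-variant group in {raw!r}")
        body, _, fv_part = text.partition("{")
        text = body.strip()
        fv_part = fv_part[:-1]
        for item in fv_part.split(";"):
            if item.strip():
                flank_variants.append(FlankVariant.from_string(item))

    blocks: list[RepeatBlock] = []
    prev_letters_case: str | None = None  # case of an immediately preceding letter run
    for m in _TOKEN.finditer(text):
        if m.group("space"):
            prev_letters_case = None
            continue
        if m.group("bad") is not None:
            raise AlleleParseError(f"unknown character {m.group('bad')!r} in {raw!r}")
        if m.group("motif") is not None:
            motif, count = m.group("motif"), m.group("count")
            if not motif:
                raise AlleleParseError(f"empty motif in token '[]{count}' of {raw!r}")
            if not _UPPER.match(motif):
                raise AlleleParseError(f"motif must be uppercase ACGT: '[{motif}]' in {raw!r}")
            if not count:
                raise AlleleParseError(f"bracket without repeat count: '[{motif}]' in {raw!r}")
            blocks.append(RepeatBlock(BRACKETED, seq=motif, count=int(count)))
            prev_letters_case = None
        elif m.group("spacer") is not None:
            blocks.append(RepeatBlock(SPACER, spacer_len=int(m.group("spacer"))))
            prev_letters_case = None
        else:
            letters = m.group("letters")
            if _UPPER.match(letters):
                case = "upper"
                block = RepeatBlock(INTERRUPTION, seq=letters)
            elif _LOWER.match(letters):
                case = "lower"
                block = RepeatBlock(FLANK, seq=letters)
            else:
                raise AlleleParseError(f"mixed-case or non-ACGT token {letters!r} in {raw!r}")
            if prev_letters_case is not None and prev_letters_case != case:
                # e.g. "TCta": an upper run glued to a lower run is ambiguous
                raise AlleleParseError(f"mixed-case token near {letters!r} in {raw!r}")
            blocks.append(block)
            prev_letters_case = case
    if not blocks:
        raise AlleleParseError(f"no tokens found in {raw!r}")
    return SequenceAllele(
        locus=locus, blocks=tuple(blocks), flank_variants=tuple(flank_variants), raw=str(raw)
    )


def designation_from_bracket(allele: SequenceAllele) -> Designation:
    """Length designation of a parsed STR allele.

    Counts bracketed blocks and uppercase interruptions; lowercase flanks and
    ``N`` spacers are excluded. Returns ``floor(L/m)`` units with ``L mod m``
    as the remainder.
    """
    m = allele.locus.motif_len
    if m is None:
        raise NomenclatureError(
            f"{allele.locus.name}: motif_len unset; designation undefined for SNP loci"
        )
    L = allele.repeat_region_len
    return Designation(L // m, L % m)


def collapse_to_length(
    alleles: Iterable[SequenceAllele],
) -> dict[Designation, set[SequenceAllele]]:
    """Partition SB alleles of one locus by their length designation.

    This is the SB -> LB collapse: each key is one LB allele, each value the
    set of SB alleles sharing that length.
    """
    alleles = list(alleles)
    if not alleles:
        return {}
    locus_names = {a.locus.name for a in alleles}
    if len(locus_names) > 1:
        raise NomenclatureError(f"collapse_to_length mixes loci: {sorted(locus_names)}")
    out: dict[Designation, set[SequenceAllele]] = {}
    for a in alleles:
        out.setdefault(a.designation, set()).add(a)
    return out


def designation_discordance(
    printed: str, allele: SequenceAllele
) -> tuple[Designation, Designation, bool]:
    """Compare a printed designation with the one computed from the bracket.

    Returns ``(printed, computed, discordant)``. Printed designations that do
    not follow the length rule (CE bin-compatibility namings, platform
    conventions) are flagged rather than overridden.
    """
    printed_d = Designation.from_string(printed)
    computed = designation_from_bracket(allele)
    return printed_d, computed, printed_d != computed
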