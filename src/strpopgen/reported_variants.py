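"""Published novel repeat-region variant alleles for the 306-marker panel.

A published MPS population survey of this four-in-one forensic panel
(100 unrelated Han Chinese individuals, 50 male / 50 female; 66 A-STRs,
29 X-STRs, 75 Y-STRs, 132 A-SNPs, 3 Y-SNPs) reports a table of novel
repeat-region variant alleles with their bracketed motif structures,
printed length designations, observed counts and frequencies. Those rows
are transcribed here verbatim (typesetting continuation lines re-joined;
one physically duplicated pair of D17S1290 rows kept once) and serve two
purposes:

* they are the sequence-allele vocabulary injected into the synthetic
  population generator, so the pipeline exercises real bracket strings;
* the reproduction tests re-derive designations and frequencies from them.

Printed designations that do not follow the ISFG length rule are expected
for some rows (CE bin-compatibility namings and typesetting garbles; the
survey itself reports such platform discordances at other loci); they are
flagged, not repaired.
"""
from __future__ import annotations

from dataclasses import dataclass

from .loci import AUTOSOMAL, LocusDef, STR, X, Y


@dataclass(frozen=True)
class ReportedVariant:
    locus: str
    printed_designation: str
    motif: str
    count: int
    frequency: float


#: Canonical motif length per reported locus (tetranucleotide unless noted).
REPORTED_MOTIF_LEN: dict[str, int] = {
    "D18S853": 3,
    "DYS645": 5,
    "DYS587": 5,
    "DYS644": 5,
}

#: Multi-copy ("a/b") Y markers: two alleles per male.
MULTICOPY_Y = ("DYS385a/b", "DYF387S1a/b", "DYS527a/b")

_REPORTED_CLASS: dict[str, str] = {}


def reported_locus_def(name: str) -> LocusDef:
    """LocusDef for a locus appearing in the reported-variant table."""
    if name.startswith("DX"):
        chrom = X
    elif name.startswith("DY"):
        chrom = Y
    else:
        chrom = AUTOSOMAL
    return LocusDef(
        name=name,
        chrom_class=chrom,
        motif_len=REPORTED_MOTIF_LEN.get(name, 4),
        copy_count=2 if name in MULTICOPY_Y else 1,
        marker_type=STR,
    )


def _v(locus: str, printed: str, motif: str, count: int, freq: float) -> ReportedVariant:
    return ReportedVariant(locus, printed, motif, count, freq)


REPORTED_VARIANTS: list[ReportedVariant] = [
    _v("D11S2368", "18", "[TATC]3 [TGTC]5 [TATC]10", 1, 0.005),
    _v("D11S2368", "19", "CATC [TATC]2 [TGTC]2 [TATC]14", 1, 0.005),
    _v("D11S2368", "21", "[TATC]3 [TGTC]3 [TATC]15", 2, 0.01),
    _v("D11S4463", "12", "[TGTC]1 [TGTC]1 [TATC]10", 1, 0.005),
    _v("D11S4463", "13", "[TGTC]1 [TGTC]1 [TATC]11", 2, 0.01),
    _v("D11S4463", "14", "[TGTC]1 [TGTC]1 [TATC]12", 1, 0.005),
    _v("D13S325", "17", "[TCTA]7 TCA [TCTA]10", 2, 0.01),
    _v("D13S325", "18", "[TCTA]7 TCA [TCTA]11", 2, 0.01),
    _v("D13S325", "18", "[TCTA]9 TCA [TCTA]9", 4, 0.02),
    _v("D13S325", "19", "[TCTA]10 TCA [TCTA]9", 6, 0.03),
    _v("D13S325", "19", "[TCTA]11 TCA [TCTA]8", 1, 0.005),
    _v("D13S325", "19", "[TCTA]8 TCA [TCTA]11", 1, 0.005),
    _v("D13S325", "20", "[TCTA]8 TCTG [TCTA]1 TCA [TCTA]10", 1, 0.005),
    _v("D13S325", "22", "[TCTA]10 TCA [TCCA]1 [TCTA]11", 1, 0.005),
    _v("D13S325", "23", "[TCTA]4 [TATA]1 [TCTA]9 TCA [TCTA]9", 1, 0.005),
    _v("D13S325", "24", "[TCTA]11 TCA [TCTA]13", 1, 0.005),
    _v("D13S325", "24", "[TCTA]12 TCA [TCTA]12", 1, 0.005),
    _v("D13S325", "24", "[TCTA]13 TCA [TCTA]11", 2, 0.01),
    _v("D13S325", "25", "[TCTA]14 TCA [TCTA]11", 1, 0.005),
    _v("D8S1179", "19", "[TCTA]2 [TCTG]1 [TCTA]16", 1, 0.005),
    _v("D15S659", "13", "[TATC]7 [TACC]1 [TATC]5", 1, 0.005),
    _v("D15S659", "14", "[TATC]8 [TACC]1 [TATC]5", 1, 0.005),
    _v("D15S659", "16", "[TATC]16", 1, 0.005),
    _v("D1S1677", "14", "[TTCC]1 TTCT [TTCC]12", 1, 0.005),
    _v("D20S470", "8", "[AGGA]8", 1, 0.005),
    _v("D20S482", "12", "[AGAT]8 AGTT [AGAT]3", 1, 0.005),
    _v("D17S1290", "13", "[AGAT]4 GATG [ATAG]15", 1, 0.005),
    _v("D17S1290", "15.2", "[AGAT]4 GATG [ATAGATAT]3 [ATAG]8 AT [ATAG]3", 1, 0.005),
    _v("D18S51", "17.1", "[AGAA]5 A [AGAA]12", 1, 0.005),
    _v("D18S853", "11", "[ATA]10 AAA", 1, 0.005),
    _v("D14S1434", "13.3", "[CTGT]3 [CTAT]2 CAT [CTAT]8", 1, 0.005),
    _v("D7S3048", "16", "[TATC]9 [TACC]7", 1, 0.005),
    _v("D7S3048", "18", "[TATC]12 [TACC]6", 1, 0.005),
    _v("D7S3048", "20", "[TATC]13 [TACC]7", 2, 0.01),
    _v("D7S3048", "21", "[TATC]11 [TACC]8 [CACC]2", 1, 0.005),
    _v("D7S3048", "21", "[TATC]12 [TACC]7 [CACC]2", 4, 0.02),
    _v("D7S3048", "21", "[TATC]10 [TACC]8 [CACC]3", 1, 0.005),
    _v("D7S3048", "22", "[TATC]14 [TACC]8", 1, 0.005),
    _v("D7S3048", "23", "[TATC]12 [TACC]6 [CACC]1 [TACC]2 [CACC]2", 1, 0.005),
    _v("D7S3048", "25", "[TATC]14 [TACC]9 [CACC]2", 1, 0.005),
    _v("D7S3048", "26", "[TATC]15 [TACC]9 [CACC]2", 1, 0.005),
    _v("D3S1744", "16", "[ATAG]2 ATG [ATAG]13 AG [ATAG]1", 1, 0.005),
    _v("DYS527a/b", "18", "[GAAA]11 [GGAA]7", 1, 0.01),
    _v("DYS527a/b", "22", "[GAAA]14 [GGAA]8", 1, 0.01),
    _v("DYS527a/b", "25", "[GAAA]18 [GGAA]7", 1, 0.01),
    _v("DYS458", "21", "[GAAG]1 [GAAA]20", 1, 0.02),
    _v("DYS518", "38", "[AAAG]3 [GAAG]1 [AAAG]13 [GGAG]1 [AAAG]4 N6 [AAAG]12 N27 [AAGG]4", 2, 0.04),
    _v("DYS518", "41", "[AAAG]3 [GAAG]1 [AAAG]12 [GGAG]1 [AAAG]4 N6 [AAAG]16 N27 [AAGG]4", 1, 0.02),
    _v("DYS518", "46", "[AAAG]3 [GAAG]1 [AAAG]16 [GGAG]1 [AAAG]4 [GAAG]1 AG [AAAG]17 N27 [AAGG]4", 1, 0.02),
    _v("DYS518", "47", "[AAAG]3 [GAAG]1 [AAAG]18 [GGAG]1 [AAAG]4 [GAAG]1 AG [AAAG]16 N27 [AAGG]4", 1, 0.02),
    _v("DYS645", "6", "[TGTTT]6", 1, 0.02),
    _v("DYS645", "11", "[TGTTT]11", 2, 0.04),
    _v("D8S1132", "14.1", "[TCTA]13 TCTG [TCTA]1", 3, 0.015),
    _v("D8S1132", "19", "[TCTA]8 TCA [TCTA]11", 1, 0.005),
    _v("D8S1132", "19", "[TCTA]7 TCA [TCTA]10 [TCTG]1 [TCTA]1", 1, 0.005),
    _v("D8S1132", "20", "[TCTA]10 TCA [TCTA]8 TCTG [TCTA]1", 1, 0.005),
    _v("D8S1132", "20", "[TCTA]9 TCA [TCTA]9 TCTG [TCTA]1", 1, 0.005),
    _v("D8S1132", "21.3", "[TCTA]8 TCA [TCTA]3 TCA [TCTA]8 [TCTG]1 [TCTA]1", 1, 0.005),
    _v("D21S1270", "10.3", "[ATAG]3 ATG [ATAG]1 ATG [ATAG]1 ATG [ATAG]5", 1, 0.005),
    _v("D7S1517", "15", "[CTTT]2 [GTTT]1 [CTTT]2 [GTTT]3 [CTTT]7", 2, 0.01),
    _v("D7S1517", "17", "[CTTT]2 [GTTT]1 [CTTT]2 [GTTT]3 [CTTT]9", 1, 0.005),
    _v("D7S1517", "19", "[CTTT]2 [GTTT]1 [CTTT]2 [GTTT]4 [CTTT]10", 1, 0.005),
    _v("D7S1517", "20", "[CTTT]2 [GTTT]1 [CTTT]2 [GTTT]2 [CTTT]13", 4, 0.02),
    _v("D7S1517", "23", "[CTTT]2 [GTTT]1 [CTTT]2 [GTTT]5 [CTTT]13", 3, 0.015),
    _v("D7S1517", "25", "[CTTT]2 [GTTT]1 [CTTT]2 [GTTT]5 [CTTT]15", 1, 0.005),
    _v(
        "D7S1517",
        "26",
        "[CTTT]2 [GTTT]1 [CTTT]2 [GTTT]1 [CTTT]2 [GTTT]1 [CTTC]1 [CTTT]1 "
        "[GTTT]1 [CTTT]2 [GTTT]1 [CTTT]2 [GTTT]1 [CTTT]8",
        1,
        0.005,
    ),
    _v(
        "D7S1517",
        "27",
        "[CTTT]2 [GTTT]1 [CTTT]2 [GTTT]1 [CTTT]2 [GTTT]1 [CTTC]1 [CTTT]1 "
        "[GTTT]1 [CTTT]2 [GTTT]1 [CTTT]2 [GTTT]1 [CTTT]9",
        4,
        0.02,
    ),
    _v("DYS710", "30.2", "[AAAG]16 [AG]11 [AAAG]9", 1, 0.02),
    _v("DYS710", "32", "[AAAG]16 [AG]14 [AAAG]9", 3, 0.06),
    _v("DYS710", "33", "[AAAG]16 [AG]14 [AAAG]10", 1, 0.02),
    _v("DYS710", "33.2", "[AAAG]17 [AG]11 [AAAG]11", 2, 0.04),
    _v("DYS710", "34", "[AAAG]15 [AG]12 [AAAG]13", 4, 0.08),
    _v("DYS710", "34", "[AAAG]17 [AG]12 [AAAG]11", 2, 0.04),
    _v("DYS710", "34.2", "[AAAG]13 [AG]13 [AAAG]15", 1, 0.02),
    _v("DYS710", "34.2", "[AAAG]18 [AG]13 [AAAG]10", 2, 0.04),
    _v("DYS710", "35", "[AAAG]16 [AG]12 [AAAG]13", 1, 0.02),
    _v("DYS710", "36.2", "[AAAG]19 [AG]13 [AAAG]11", 1, 0.02),
    _v("DYS710", "36.2", "[AAAG]17 [AG]17 [AAAG]11", 2, 0.04),
    _v("DYS710", "37", "[AAAG]16 [AG]16 [AAAG]13", 1, 0.02),
    _v("DYS710", "37", "[AAAG]18 [AG]12 [AAAG]13", 1, 0.02),
    _v("DYS710", "37.2", "[AAAG]17 [AG]15 [AAAG]13", 1, 0.02),
    _v("DYS710", "39", "[AAAG]19 [AG]13 [AAAG]14", 1, 0.02),
    _v("DYS710", "40", "[AAAG]20 [AG]16 [AAAG]12", 1, 0.02),
    _v("DYS710", "40.2", "[AAAG]20 [AG]13 [AAAG]14", 2, 0.04),
    _v("DYS710", "40.2", "[AAAG]18 [AG]21 [AAAG]12", 1, 0.02),
    _v("DYS710", "41", "[AAAG]21 [AG]14 [AAAG]13", 1, 0.02),
    _v("DYS710", "42", "[AAAG]22 [AG]16 [AAAG]12", 1, 0.02),
    _v(
        "DYS587",
        "23",
        "[ATACA]17 [GTACA]1 [ATACA]1 [GTACA]1 [ATACA]1 [GTACA]1 [ATACA]1",
        2,
        0.04,
    ),
    _v("DYS626", "30", "[AAAG]21 [AGAA]2 AGAG [GAAG]3 [AAAG]3", 1, 0.02),
    _v("DYS644", "23.4", "TTTTT [TTTTA]11 [TTTA]1 [TTTTA]11", 1, 0.02),
    _v(
        "DYF387S1a/b",
        "37.3",
        "[AAAG]3 [GTAG]1 [GAAG]4 [AAAG]2 [GAAG]1 [AAAG]2 [GAAG]11 [AAAG]3 AAG [AAAG]10",
        2,
        0.02,
    ),
    _v(
        "DYF387S1a/b",
        "38",
        "[AAAG]3 [GTAG]1 [GAAG]3 AAAA [AAAG]2 [GAAG]1 [AAAG]2 [GAAG]9 [AAAG]16",
        5,
        0.05,
    ),
    _v(
        "DYF387S1a/b",
        "39",
        "[AAAG]3 [GTAG]1 [GAAG]3 GAAA [AAAG]2 [GAAG]1 [AAAG]2 [GAAG]9 [AAAG]17",
        3,
        0.03,
    ),
    _v("DXS10074", "20", "[AGAA]16 [AGAG]1 [AGAA]3", 1, 0.005),
    _v("DXS10135", "20", "[AAGA]3 G [AAAG]1 GA [AAGA]15 AAGC [AAAG]1", 1, 0.005),
    _v("DXS10135", "25", "[AAGA]3 G [AAAG]1 GA [AAGA]19 AAGG [AAGA]1 [AAAG]1", 1, 0.005),
]


#: Panel composition of the surveyed kit (marker counts per class).
PANEL_COMPOSITION = {
    "A-STR": 66,
    "X-STR": 29,
    "Y-STR": 75,
    "A-SNP": 132,
    "Y-SNP": 3,
}

#: Reported per-class mean depth-of-coverage extremes (reads), used by the
#: coverage QC reproduction checks: lowest and highest per-locus means.
REPORTED_DOC_EXTREMES = {"DYS616": 486.0, "DYS385a/b": 145175.0}
REPORTED_DOC_THRESHOLD = 650.0
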