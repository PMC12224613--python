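# Methods

This note documents the models, conventions and numerical choices behind
`strpopgen`, and what the synthetic cohort does and does not emulate.

## Sequence-allele nomenclature

A sequence-based (SB) allele is an ordered token list: repeat blocks
`[SEQ]n` (n ≥ 1, uppercase unit), uppercase interruption runs, `Nk` spacers
(k undisplayed nucleotides between repeat stretches of long compound
markers), and lowercase flanking context. An optional trailing `{...}`
group carries flanking-region (FR) variant annotations
(`side:kind:position:observed`, e.g. `up:SNP:GRCh38-chr2:68011829:C`).
Equality of SB alleles is over locus, block structure **and** FR
annotations — two alleles identical in the repeat region (RR) but differing
by a flanking SNP are distinct SB alleles. This is what drives FR-sourced
unique-allele gains in the SB/LB comparison.

**Length designation.** The CE-compatible name is derived from the
repeat-region length L: bracketed blocks and uppercase interruptions count;
lowercase flanks and `N` spacers do not; the designation is
`floor(L/m).(L mod m)` for canonical motif length m. The inclusion of
explicit interruptions and the exclusion of spacers are both forced by
published compound alleles (a 1-nt insertion yields x.1; a spacer-bearing
45-unit structure names as 38). Published tables are not perfectly
self-consistent here: some printed designations follow CE bin conventions
in which a fixed interruption is absorbed into the reference ladder (a
`[TCTA]a TCA [TCTA]b` structure printed as a+b rather than a+b+0.75 units),
and a few rows are typesetting garbles. No function of the bracket string
alone can reproduce both conventions, so the parser computes the length
rule and stores any printed designation verbatim alongside it, flagging
discordance rather than guessing intent — mirroring the cross-platform
nomenclature discordances that MPS studies themselves report.

## Frequency tables and denominators

Allele counts are direct; denominators follow the observation model:
autosomal 2 per sample; X pooled across sexes as 2·(#females) + #males;
Y `copy_count` per male (multi-copy `a/b` markers contribute an unordered
pair). Null calls are dropped from numerator and denominator and never form
an allele class. Frequencies are kept exact internally and rounded to 4
decimals only in output tables.

An explicit option `x_male_double_count=True` reproduces the convention of
diploid-oriented forensic software in which a male's single X allele is
entered as a homozygote (denominator 2N). The surveyed study's printed X
frequencies follow that convention (count 1 → 0.005 with 50 males and 50
females), so the reproduction tests enable it for X loci; the haploid-aware
denominator remains the package default because it is the statistically
correct pooled count.

Pooling the sexes at X loci is the default analysis choice; a homogeneity
check (`pool_sex_frequencies_check`: Fisher exact for two alleles,
seeded permutation G-test otherwise) is available but does not gate.

## Forensic parameters

Let S_r = Σ p_i^r over allele frequencies p.

* Gene diversity (unbiased Hexp): n(1 − S₂)/(n − 1), n = allele
  observations.
* PIC = 1 − S₂ − S₂² + S₄.
* Match probability uses **observed** genotype frequencies (MP = Σ g²,
  PD = 1 − MP), not HWE expectations — the convention of the standard
  forensic parameter calculators. PE and TPI likewise come from the
  observed heterozygote proportion h (H = 1 − h): PE = h²(1 − 2hH²),
  TPI = 1/(2H) (infinite when every sample is heterozygous).
* X discrimination: PD_M = 1 − S₂ (hemizygous males);
  PD_F = 1 − (2S₂² − S₄) (HWE female genotypes).
* Mean exclusion chances for X markers are defined operationally as the
  probability of excluding a random non-father under each observation
  model, with founders drawn from the pooled frequencies:
  - standard mother–daughter–alleged-father trio (X obligately transmitted
    to daughters). The exact expectation reduces algebraically to the PIC
    form 1 − S₂ − S₂² + S₄; the two published trio parameterisations
    (Kishida-style and Desmarais-style) therefore coincide here and are
    reported as equal.
  - father–daughter duo (mother unavailable): 1 − 2S₂ + S₃.
  - deficiency configuration: the alleged father is unavailable and his
    mother is typed in his place; exclusion requires both her alleles to
    miss the possible-paternal set, giving
    1 − 2S₂ + S₃ + 2S₄ − 3S₅ − 2S₂² + 3S₂S₃.
  Each closed form is gated by an exact enumeration oracle (≤ 1e−10 over a
  0.05-grid of spectra up to five alleles) in the test-suite. The exact
  pedigree meant by "deficiency" varies between software conventions; the
  grandmother-substitution scenario implemented here is the natural
  X-transmission deficiency case and is documented as a choice, not an
  inevitability.
* Y statistics: HD = N(1 − Σp²)/(N − 1) over haplotype frequencies,
  DC = k/N, plus the fraction of haplotypes seen once. Note that on the
  configuration N = 50, k = 49 with 48 singletons these formulas give
  HD = 0.99918 and 48/49 = 97.96% unique; published roundings of 0.9996 and
  97.92% for that same configuration are not consistent with the formulas
  and are not reproduced.
* Combined values accumulate ln MP, ln(1 − PE) and ln TPI, so CMP at the
  10⁻⁷⁰ scale never underflows intermediate products; CPD/CPE render as
  `1-x` with x in scientific notation.

## Equilibrium testing

**HWE.** The exact conditional test: given allele counts c_i, a genotype
array {n_ij} has probability n!·2^h·Πc_i!/((2n)!·Πn_ij!) (h =
heterozygotes). The p-value is the mass of arrays no more probable than the
one observed (relative tolerance 1e−9 on log-probabilities for ties).
Problems with ≤ 4 alleles and ≤ 15 samples are enumerated exhaustively
(recursion over heterozygote cells; the enumeration's total mass is
asserted to be 1); larger ones are sampled by shuffling the allele vector
into pairs — vectorised over seeded batches — with the add-one rule
(exceed + 1)/(steps + 1), so a Monte-Carlo p is never exactly 0 and is
bit-for-bit reproducible given (seed, steps). X-locus HWE uses females only
by default (male hemizygotes carry no HWE information); a pooled option
exists. Monomorphic loci return p = 1 with method tag `degenerate`.
No Markov-chain sampler is used: batched shuffling covers panel-sized
problems comfortably.

**LD.** For unphased diploid pairs, two-locus haplotype frequencies are
fitted by EM over (gA, gB) genotype-class counts (phase is ambiguous only
for double heterozygotes, which admit two resolutions; the EM starts from
linkage equilibrium and stops when the log-likelihood gain is < 1e−8 or
after 1000 iterations). The statistic is the likelihood ratio
2(LL_fit − LL_independence); the null is built by permuting one locus's
genotypes across individuals, which preserves both marginal spectra.
Haploid (Y) pairs use the G statistic on the haplotype contingency table
with the same permutation scheme. Both use the add-one rule.

**Bonferroni.** Corrected levels are α/n for per-locus tests and
α/C(n,2) for pairwise scopes (66 → 2145, 29 → 406, 132 → 8646). LD testing
is configurable between all-pairs and tested-pairs scopes; all-pairs is the
default denominator because that is how panel-wide corrected levels are
conventionally printed, even when the physically interesting pairs are the
same-chromosome ones.

## SB/LB accounting

Per locus, the SB allele set is collapsed by designation; n_lb = number of
classes, n_sb = set size, gain = (n_sb − n_lb)/n_lb. The source label
inspects within-class variation: RR_only if block structures differ
somewhere but FR lists never do, FR_only for the converse, both/none
otherwise; single-allele loci are `none`. Panel totals are emitted under
two conventions — the ratio of summed totals and the mean of per-locus
percentages — because published headline gains do not state which is used
(and for the surveyed panel the two differ: 1837/1198 − 1 = 53.3% vs a
printed 58.18%); neither is silently preferred.

## Coverage QC

DoC of a locus = valid reads summed per sample, averaged over samples.
The summary flags loci with mean below a threshold (default 650×,
configurable) and reports max/min (integer-rounded for the headline
figure; ratio undefined if the minimum is 0). Run-level quality metrics
(Q30 etc.) are pass-through metadata: no read-level data is in scope.

## Synthetic cohort

The generator draws unrelated individuals — autosomal and female-X
genotypes as independent allele pairs (HWE holds exactly), hemizygous
male-X/Y draws, two draws at multi-copy Y markers. Spectra are symmetric-
Dirichlet length distributions (5–12 alleles, concentration 1.5 — typical
of tetranucleotide forensic STRs) decorated with same-length RR variant
structures (probability 0.3 per class) and flanking-SNP copies
(probability 0.15); loci with published novel-variant rows instead carry
those bracket strings verbatim at their printed frequencies, topped up
with a reference allele. Coverage is log-normal per locus (log-mean drawn
N(ln 6000, 0.9), log-sd 0.6; the documented extreme loci are anchored near
their published means), which reproduces the ~300× max/min spread of real
multiplex panels. One global seed expands into per-locus streams keyed by
a stable hash of the locus name, so edits to the panel never perturb other
loci and fixed-seed runs are byte-identical.

Not emulated: kinship/mutation structure (individuals are unrelated by
construction), stutter and other read-level artefacts, genotyping error,
locus dropout beyond explicit nulls, and real linkage (loci are simulated
independently — which is precisely what makes the generator a valid null
for HWE/LD calibration; the generator and the tests share no shortcuts).
Passing calibration on this cohort shows the tests are correct under their
null, not that real data meet that null. The marker name list mirrors the
surveyed panel's class counts (66/29/75/132/3) using the loci the survey
names plus standard forensic markers as fill-ins; it is a synthetic
stand-in, not the kit's exact inventory.

## Numerical and design notes

* Probability comparisons in exact tests use relative log-tolerances
  (1e−9) so ties are counted as "no more probable".
* EM and panel combinations guard logs with 1e−300 floors / log1p.
* Frequencies must sum to 1 within 1e−9; spectra are validated at
  configuration time; a seed is mandatory for every stochastic stage.
* Analysis problem sizes: the equilibrium driver uses 5000 Monte-Carlo
  steps per HWE locus and 199 permutations over a 15-pair LD subset;
  calibration experiments use 1000 HWE replicates (1999 steps) and 500 LD
  replicates (99 permutations) at the study's own cohort size of 100.
  These sizes give Monte-Carlo standard errors well below the effects
  being checked.
* File formats are plain UTF-8 TSV/CSV/JSON; a thin openpyxl-based
  ingester accepts spreadsheet genotype reports laid out like the TSV
  dialect. Proprietary report schemas are not parsed.
* Known limitations: no kinship likelihood-ratio casework engine (only
  population-level parameters); no read-level simulation; no external
  allele-database lookups; designation reproduction is limited by the
  printed-table inconsistencies described above.
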