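"""Exact Hardy-Weinberg tests and pairwise linkage-disequilibrium tests.

The HWE test is the exact conditional test: given the observed allele
counts, the probability of a diploid genotype array is

    P(array | allele counts) = n! * 2^h * prod_i c_i! / ((2n)! * prod_{i<=j} n_ij!)

with ``h`` heterozygous individuals, allele counts ``c_i`` and genotype
counts ``n_ij``. The p-value is the total probability of arrays no more
probable than the observed one. Small problems (<=4 alleles and <=15
samples) are fully enumerated; otherwise the null is sampled by seeded
Monte-Carlo shuffling of the allele vector into pairs.

The LD test for unphased diploid data fits two-locus haplotype frequencies
by EM, takes the likelihood-ratio statistic against the product of allele
frequencies, and builds the null by permuting one locus's genotypes across
individuals. Haploid (Y) data use a permutation test on the haplotype
contingency table with the G statistic. Permutation p-values use the
add-one rule and can never be exactly zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy.special import gammaln

_LOG2 = math.log(2.0)
_PTOL = 1e-9  # relative tolerance when comparing array probabilities


@dataclass
class TestResult:
    """Outcome of one HWE or LD test."""

    name: str
    statistic: float
    p_value: float
    method: str
    steps: int
    seed: int | None
    alpha_prime: float | None = None

    @property
    def significant_after_bonferroni(self) -> bool | None:
        if self.alpha_prime is None:
            return None
        return self.p_value < self.alpha_prime

    def with_alpha(self, alpha_prime: float) -> "TestResult":
        return TestResult(
            self.name, self.statistic, self.p_value, self.method, self.steps, self.seed,
            alpha_prime,
        )


def bonferroni_plan(n: int, alpha: float = 0.05, *, pairwise: bool = False) -> tuple[int, float]:
    """Number of tests and the Bonferroni-corrected level.

    ``pairwise=True`` plans all ``n(n-1)/2`` locus pairs; otherwise ``n``
    single-locus tests.
    """
    if n < 1:
        raise ValueError("need at least one locus")
    count = n * (n - 1) // 2 if pairwise else n
    if count < 1:
        raise ValueError("no tests to plan")
    return count, alpha / count


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def _encode_genotypes(genotypes: Sequence[tuple[Hashable, Hashable]]):
    alleles = sorted({a for g in genotypes for a in g}, key=str)
    index = {a: i for i, a in enumerate(alleles)}
    pairs = np.array([[index[a], index[b]] for a, b in genotypes], dtype=np.int64)
    return alleles, np.sort(pairs, axis=1)


def _log_array_prob_const(c: np.ndarray, n: int) -> float:
    """Terms of log P(array | allele counts) shared by every array."""
    return float(gammaln(n + 1) + gammaln(c + 1).sum() - gammaln(2 * n + 1))


def _log_array_prob(n_ij: np.ndarray, const: float) -> float:
    het = n_ij.sum() - np.trace(n_ij)
    return const + het * _LOG2 - float(gammaln(n_ij + 1).sum())


def _enumerate_hwe(c: np.ndarray, const: float):
    """Yield (log-probability,) over all genotype arrays with allele counts c."""
    k = len(c)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    out: list[float] = []
    n_ij = np.zeros((k, k), dtype=np.int64)

    def rec(idx: int, rem: np.ndarray) -> None:
        if idx == len(pairs):
            if np.all(rem % 2 == 0):
                for i in range(k):
                    n_ij[i, i] = rem[i] // 2
                out.append(_log_array_prob(n_ij, const))
                for i in range(k):
                    n_ij[i, i] = 0
            return
        i, j = pairs[idx]
        top = min(rem[i], rem[j])
        for x in range(top + 1):
            n_ij[i, j] = x
            rem[i] -= x
            rem[j] -= x
            rec(idx + 1, rem)
            rem[i] += x
            rem[j] += x
        n_ij[pairs[idx][0], pairs[idx][1]] = 0

    rec(0, c.copy())
    return np.array(out)


def hwe_exact(
    genotypes: Sequence[tuple[Hashable, Hashable]],
    *,
    steps: int = 100_000,
    seed: int | None = None,
    method: str | None = None,
    name: str = "locus",
) -> TestResult:
    """Exact HWE test conditioning on allele counts.

    ``genotypes`` is one unordered allele pair per diploid sample (X loci:
    females only, or pooled diploids, per the caller). ``method`` may force
    ``"enumeration"`` or ``"monte-carlo"``; by default problems with <=4
    alleles and <=15 samples are enumerated, larger ones sampled with
    ``steps`` seeded shuffles.
    """
    n = len(genotypes)
    if n < 2:
        raise ValueError("HWE test needs at least 2 samples")
    alleles, pairs = _encode_genotypes(genotypes)
    k = len(alleles)
    if k == 1:
        return TestResult(name, 0.0, 1.0, "degenerate", 0, seed)
    flat = pairs.ravel()
    c = np.bincount(flat, minlength=k)
    const = _log_array_prob_const(c, n)
    obs = np.zeros((k, k), dtype=np.int64)
    np.add.at(obs, (pairs[:, 0], pairs[:, 1]), 1)
    log_obs = _log_array_prob(obs, const)
    cutoff = log_obs + _PTOL * abs(log_obs)

    if method is None:
        method = "enumeration" if (k <= 4 and n <= 15) else "monte-carlo"

    if method == "enumeration":
        logps = _enumerate_hwe(c, const)
        total = float(np.exp(logps).sum())
        if abs(total - 1.0) > 1e-8:
            raise AssertionError(f"enumeration mass {total} != 1")
        p = float(np.exp(logps[logps <= cutoff]).sum())
        return TestResult(name, log_obs, min(p, 1.0), "enumeration", len(logps), seed)

    if seed is None:
        raise ValueError("seed required for the Monte-Carlo HWE test")
    rng = np.random.default_rng(seed)
    # shuffle the allele vector into pairs, in batches to bound memory
    exceed = 0
    k2 = k * k
    remaining = steps
    batch = max(1, min(steps, 20_000_000 // max(1, 2 * n * k)))
    while remaining > 0:
        b = min(batch, remaining)
        remaining -= b
        mat = rng.permuted(np.broadcast_to(flat, (b, 2 * n)), axis=1)
        x = mat[:, 0::2]
        y = mat[:, 1::2]
        lo = np.minimum(x, y)
        hi = np.maximum(x, y)
        het = (x != y).sum(axis=1)
        codes = lo * k + hi + (np.arange(b)[:, None] * k2)
        counts = np.bincount(codes.ravel(), minlength=b * k2).reshape(b, k2)
        logp = const + het * _LOG2 - gammaln(counts + 1).sum(axis=1)
        exceed += int(np.sum(logp <= cutoff))
    p = (exceed + 1) / (steps + 1)
    return TestResult(name, log_obs, p, "monte-carlo", steps, seed)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def em_haplotype_frequencies(
    pairs_a: np.ndarray,
    pairs_b: np.ndarray,
    ka: int,
    kb: int,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, float, float]:
    """EM estimate of two-locus haplotype frequencies from unphased diploid
    codes; returns ``(hap_freqs[ka, kb], loglik_fitted, loglik_independent)``.

    Phase is ambiguous only for double heterozygotes, which admit two
    resolutions; the EM starts from linkage equilibrium.
    """
    n = pairs_a.shape[0]
    # collapse individuals into (gA, gB) classes
    ga = pairs_a[:, 0] * ka + pairs_a[:, 1]
    gb = pairs_b[:, 0] * kb + pairs_b[:, 1]
    combo, counts = np.unique(ga * (kb * kb) + gb, return_counts=True)
    # expand each class into its phasings
    X: list[int] = []  # haplotype id of (a1,b1)
    Y: list[int] = []  # haplotype id of (a2,b2)
    CLS: list[int] = []
    COEF: list[float] = []
    for ci, code in enumerate(combo):
        gac, gbc = divmod(int(code), kb * kb)
        a1, a2 = divmod(gac, ka)
        b1, b2 = divmod(gbc, kb)
        phasings = [((a1, b1), (a2, b2))]
        if a1 != a2 and b1 != b2:
            phasings.append(((a1, b2), (a2, b1)))
        for (x, y) in phasings:
            hx = x[0] * kb + x[1]
            hy = y[0] * kb + y[1]
            X.append(hx)
            Y.append(hy)
            CLS.append(ci)
            COEF.append(1.0 if hx == hy else 2.0)
    Xa = np.array(X)
    Ya = np.array(Y)
    CLSa = np.array(CLS)
    COEFa = np.array(COEF)
    ncls = len(combo)
    w_cls = counts.astype(float)

    pa = np.bincount(pairs_a.ravel(), minlength=ka).astype(float) / (2 * n)
    pb = np.bincount(pairs_b.ravel(), minlength=kb).astype(float) / (2 * n)
    h = np.outer(pa, pb).ravel()

    def loglik(hf: np.ndarray) -> float:
        t = COEFa * hf[Xa] * hf[Ya]
        cp = np.bincount(CLSa, weights=t, minlength=ncls)
        return float(np.sum(w_cls * np.log(np.maximum(cp, 1e-300))))

    ll0 = loglik(h)
    prev = -math.inf
    for _ in range(max_iter):
        t = COEFa * h[Xa] * h[Ya]
        cp = np.bincount(CLSa, weights=t, minlength=ncls)
        cur = float(np.sum(w_cls * np.log(np.maximum(cp, 1e-300))))
        if cur - prev < tol:
            break
        prev = cur
        w = t * w_cls[CLSa] / np.maximum(cp[CLSa], 1e-300)
        hap = np.bincount(Xa, weights=w, minlength=ka * kb) + np.bincount(
            Ya, weights=w, minlength=ka * kb
        )
        h = hap / (2 * n)
    ll = loglik(h)
    return h.reshape(ka, kb), ll, ll0


def _diploid_lr(pairs_a: np.ndarray, pairs_b: np.ndarray, ka: int, kb: int) -> float:
    _, ll, ll0 = em_haplotype_frequencies(pairs_a, pairs_b, ka, kb)
    return max(0.0, 2.0 * (ll - ll0))


def _g_stat_codes(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> float:
    table = np.bincount(a * kb + b, minlength=ka * kb).reshape(ka, kb).astype(float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def ld_pairwise(
    genos_a: Sequence,
    genos_b: Sequence,
    *,
    permutations: int = 999,
    seed: int | None = None,
    name: str = "pair",
) -> TestResult:
    """Pairwise LD test between two loci typed on the same individuals.

    Diploid data (2-tuples per sample at both loci): EM likelihood-ratio
    statistic with a permutation null built by shuffling one locus's
    genotypes across individuals. Haploid data (single tokens): G statistic
    on the haplotype contingency table, permutation null. ``p = (exceedances
    + 1) / (permutations + 1)``.
    """
    if len(genos_a) != len(genos_b):
        raise ValueError("loci typed on different numbers of individuals")
    if len(genos_a) < 2:
        raise ValueError("LD test needs at least 2 individuals")
    first = genos_a[0]
    diploid = isinstance(first, (tuple, list)) and len(first) == 2
    if seed is None:
        raise ValueError("seed required for the permutation LD test")
    rng = np.random.default_rng(seed)

    if diploid:
        alleles_a, pairs_a = _encode_genotypes(genos_a)
        alleles_b, pairs_b = _encode_genotypes(genos_b)
        ka, kb = len(alleles_a), len(alleles_b)
        if ka == 1 or kb == 1:
            return TestResult(name, 0.0, 1.0, "degenerate", 0, seed)
        obs = _diploid_lr(pairs_a, pairs_b, ka, kb)
        exceed = 0
        for _ in range(permutations):
            perm = rng.permutation(len(genos_a))
            if _diploid_lr(pairs_a, pairs_b[perm], ka, kb) >= obs - 1e-12:
                exceed += 1
        p = (exceed + 1) / (permutations + 1)
        return TestResult(name, obs, p, "em-permutation", permutations, seed)

    # haploid
    alleles_a = sorted(set(genos_a), key=str)
    alleles_b = sorted(set(genos_b), key=str)
    ka, kb = len(alleles_a), len(alleles_b)
    if ka == 1 or kb == 1:
        return TestResult(name, 0.0, 1.0, "degenerate", 0, seed)
    ia = {a: i for i, a in enumerate(alleles_a)}
    ib = {b: i for i, b in enumerate(alleles_b)}
    a = np.array([ia[g] for g in genos_a])
    b = np.array([ib[g] for g in genos_b])
    obs = _g_stat_codes(a, b, ka, kb)
    exceed = 0
    for _ in range(permutations):
        if _g_stat_codes(a, rng.permutation(b), ka, kb) >= obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return TestResult(name, obs, p, "g-permutation", permutations, seed)
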