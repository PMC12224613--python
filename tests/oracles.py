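"""Independent brute-force oracles used by the test-suite.

Everything here is deliberately naive — enumeration, O(n^2) pairwise
comparison, grid search — and shares no code with the implementation paths
it checks.
"""
from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


# ---------------------------------------------------------------------------
# forensic parameter oracles
# ---------------------------------------------------------------------------

def pic_double_sum(p) -> float:
    """PIC via the explicit double sum 1 - sum p_i^2 - sum_{i!=j} p_i^2 p_j^2."""
    p = list(p)
    s2 = sum(x * x for x in p)
    cross = sum(
        p[i] ** 2 * p[j] ** 2
        for i in range(len(p))
        for j in range(len(p))
        if i != j
    )
    return 1.0 - s2 - cross


def mp_pairwise(genotypes) -> float:
    """Match probability as the fraction of ordered sample pairs (drawn with
    replacement) sharing a genotype."""
    n = len(genotypes)
    matches = sum(1 for a in genotypes for b in genotypes if a == b)
    return matches / (n * n)


def pdf_enumeration(p) -> float:
    """Female X power of discrimination by enumeration over ordered genotype
    pairs under HWE."""
    k = len(p)
    match = 0.0
    for a1 in range(k):
        for a2 in range(k):
            for b1 in range(k):
                for b2 in range(k):
                    if {a1, a2} == {b1, b2}:
                        match += p[a1] * p[a2] * p[b1] * p[b2]
    return 1.0 - match


def mec_enumeration(p, scenario: str) -> float:
    """Exact MEC by summation over founder allele combinations.

    Trio: mother (m, o) under HWE transmits m; true father contributes f;
    the daughter is (m, f). The possible paternal alleles are {m, f} when
    the mother carries both daughter alleles (o == f, m != f), else {f}.
    A random non-father (haploid allele) is excluded with probability
    1 - sum of possible-paternal frequencies; in the deficiency scenario
    the alleged father's mother is typed instead and is excluded only if
    neither of her two alleles is possible-paternal (squared miss).
    Duo: no mother; daughter (a, b) admits paternal {a, b}.
    """
    k = len(p)
    total = 0.0
    if scenario == "duo":
        for a in range(k):
            for b in range(k):
                miss = 1.0 - sum(p[i] for i in {a, b})
                total += p[a] * p[b] * miss
        return total
    power = 2 if scenario == "deficiency" else 1
    for m in range(k):
        for o in range(k):
            for f in range(k):
                poss = {m, f} if (o == f and m != f) else {f}
                miss = 1.0 - sum(p[i] for i in poss)
                total += p[m] * p[o] * p[f] * miss**power
    return total


def frequency_grid(max_len: int = 5, step: float = 0.05):
    """All frequency vectors of length <= max_len on a `step` grid."""
    units = round(1 / step)
    for k in range(1, max_len + 1):
        for cuts in itertools.combinations(range(1, units), k - 1):
            parts = np.diff([0, *cuts, units])
            yield (parts * step).tolist()


# ---------------------------------------------------------------------------
# partition / classification oracles
# ---------------------------------------------------------------------------

def partition_pairwise(alleles):
    """Partition alleles into designation classes by O(n^2) pairwise equality
    of computed designations (no hashing on the tested key)."""
    alleles = list(alleles)
    classes: list[list] = []
    for a in alleles:
        for cls in classes:
            if cls[0].designation == a.designation:
                cls.append(a)
                break
        else:
            classes.append([a])
    return classes


def sblb_classify_pairwise(alleles) -> str:
    """Variation-source classification by exhaustive pairwise comparison
    within designation classes."""
    rr = fr = False
    for cls in partition_pairwise(alleles):
        for a, b in itertools.combinations(cls, 2):
            if a.blocks != b.blocks:
                rr = True
            if a.flank_variants != b.flank_variants:
                fr = True
    n_sb = len(set(alleles))
    n_lb = len(partition_pairwise(set(alleles)))
    if n_sb == n_lb:
        return "none"
    if rr and fr:
        return "both"
    return "RR_only" if rr else "FR_only"


def haplotype_counts_pairwise(tuples):
    """Haplotype counts via hash-free pairwise comparison."""
    tuples = list(tuples)
    used = [False] * len(tuples)
    counts = []
    for i, t in enumerate(tuples):
        if used[i]:
            continue
        c = 0
        for j in range(i, len(tuples)):
            if not used[j] and tuples[j] == t:
                used[j] = True
                c += 1
        counts.append(c)
    return sorted(counts)


# ---------------------------------------------------------------------------
# exact-test oracles
# ---------------------------------------------------------------------------

def hwe_pairing_enumeration(genotypes) -> float:
    """Exact HWE p-value by enumerating every pairing of the allele multiset.

    Recursively matches the first remaining allele with each other remaining
    allele; each complete pairing is equally likely under the null. The
    p-value is the fraction of pairings whose genotype array is no more
    probable than the observed one (array probability measured by how many
    pairings produce it).
    """
    alleles = [a for g in genotypes for a in g]

    # alleles treated as distinguishable positions, so every complete pairing
    # carries equal weight and array probabilities come out exact
    arrays2 = Counter()

    def rec2(remaining, acc):
        if not remaining:
            arrays2[frozenset(Counter(acc).items())] += 1
            return
        first = remaining[0]
        for i in range(1, len(remaining)):
            rec2(
                remaining[1:i] + remaining[i + 1 :],
                acc + [tuple(sorted((first, remaining[i])))],
            )

    rec2(alleles, [])
    total = sum(arrays2.values())
    obs_key = frozenset(Counter(tuple(sorted(g)) for g in genotypes).items())
    obs_prob = arrays2[obs_key] / total
    p = sum(c for key, c in arrays2.items() if c / total <= obs_prob * (1 + 1e-12))
    return p / total


def contingency_g_enumeration(table) -> float:
    """Exact permutation p-value of the G statistic for a 2-row contingency
    table, by enumerating assignments of column-labelled observations to the
    two rows (hypergeometric weights)."""
    table = np.asarray(table, dtype=int)
    col = table.sum(axis=0)
    n_top = int(table[0].sum())

    def g_stat(t):
        t = np.asarray(t, dtype=float)
        e = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        mask = t > 0
        return 2.0 * float(np.sum(t[mask] * np.log(t[mask] / e[mask])))

    obs = g_stat(table)
    total_ways = math.comb(int(col.sum()), n_top)
    p = 0.0
    ranges = [range(0, c + 1) for c in col]
    for top in itertools.product(*ranges):
        if sum(top) != n_top:
            continue
        ways = math.prod(math.comb(int(c), int(t)) for c, t in zip(col, top))
        t = np.stack([np.array(top), col - np.array(top)])
        if g_stat(t) >= obs - 1e-12:
            p += ways / total_ways
    return p


def em_loglik_grid_2x2(pairs_a, pairs_b, points: int = 200_001):
    """Maximum log-likelihood for two biallelic loci by grid search over the
    single free haplotype frequency (allele margins fixed at their MLEs)."""
    pa = np.mean([sum(1 for x in g if x == 0) for g in pairs_a]) / 2
    pb = np.mean([sum(1 for x in g if x == 0) for g in pairs_b]) / 2
    lo = max(0.0, pa + pb - 1.0)
    hi = min(pa, pb)
    grid = np.linspace(lo, hi, points)
    h11 = grid
    h12 = pa - h11
    h21 = pb - h11
    h22 = 1 - pa - pb + h11
    H = np.stack([h11, h12, h21, h22])  # indexed by 2*a + b
    ll = np.zeros(points)
    for ga, gb in zip(pairs_a, pairs_b):
        a1, a2 = ga
        b1, b2 = gb
        phasings = [((a1, b1), (a2, b2))]
        if a1 != a2 and b1 != b2:
            phasings.append(((a1, b2), (a2, b1)))
        prob = np.zeros(points)
        for (x, y) in phasings:
            hx = H[2 * x[0] + x[1]]
            hy = H[2 * y[0] + y[1]]
            coef = 1.0 if x == y else 2.0
            prob = prob + coef * hx * hy
        ll += np.log(np.maximum(prob, 1e-300))
    best = int(np.argmax(ll))
    return float(ll[best]), float(grid[best])
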