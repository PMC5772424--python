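"""Independent brute-force implementations used as oracles in tests.

Everything here is deliberately written from the textbook definitions with
plain Python loops, sharing no code with the package implementations.
"""

from __future__ import annotations

import itertools
import math

MISSING = -1


def locus_column(data, locus):
    """List of (a1, a2) genotype tuples at one locus."""
    return [tuple(int(a) for a in data.alleles[i, locus])
            for i in range(data.n_individuals)]


def naive_khrm(genotypes):
    """(K, H, R, M) from a list of genotype tuples (textbook definitions)."""
    copies = [a for g in genotypes for a in g if a != MISSING]
    n = len(copies)
    distinct = sorted(set(copies))
    k = len(distinct)
    r = distinct[-1] - distinct[0]
    sum_p2 = sum((copies.count(a) / n) ** 2 for a in distinct)
    h = (n / (n - 1)) * (1 - sum_p2) if n >= 2 else 0.0
    return k, h, r, k / (r + 1)


def naive_fst_wc(genos_a, genos_b):
    """Two-deme multi-locus Weir–Cockerham theta.

    ``genos_a``/``genos_b``: per-locus lists of genotype tuples.  Only
    individuals typed on both copies enter (genotype-level statistic).
    """
    num = 0.0
    den = 0.0
    for ga, gb in zip(genos_a, genos_b):
        ga = [g for g in ga if MISSING not in g]
        gb = [g for g in gb if MISSING not in g]
        n1, n2 = len(ga), len(gb)
        if n1 == 0 or n2 == 0:
            continue
        r = 2
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
        if nbar <= 1 or nc <= 0:
            continue
        alleles = sorted({a for g in ga + gb for a in g})
        for al in alleles:
            p1 = sum(g.count(al) for g in ga) / (2 * n1)
            p2 = sum(g.count(al) for g in gb) / (2 * n2)
            h1 = sum(1 for g in ga if g.count(al) == 1) / n1
            h2 = sum(1 for g in gb if g.count(al) == 1) / n2
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                     - hbar / 4) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                       - (2 * nbar - 1) / (4 * nbar) * hbar)
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den if den != 0 else 0.0


def naive_mtdna(seqs):
    """(H, S, pi) from a list of equal-length strings, by enumeration."""
    h = len(set(seqs))
    length = len(seqs[0])
    s = sum(1 for j in range(length) if len({sq[j] for sq in seqs}) > 1)
    pairs = list(itertools.combinations(seqs, 2))
    pi = (sum(sum(x != y for x, y in zip(a, b)) for a, b in pairs)
          / len(pairs))
    return h, s, pi


def tavare_segsites_pmf(n: int, theta: float, s_max: int):
    """P(S = s) for the number of segregating sites in a sample of n under
    the constant-size coalescent (Tavare 1984), s = 0..s_max.

    ``theta`` is on the scale E[S] = theta * sum_{i=1}^{n-1} 1/i.
    """
    pmf = []
    for s in range(s_max + 1):
        total = 0.0
        for i in range(2, n + 1):
            total += ((-1) ** i * math.comb(n - 1, i - 1)
                      * (i - 1) / (theta + i - 1)
                      * (theta / (theta + i - 1)) ** s)
        pmf.append(total)
    return pmf
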