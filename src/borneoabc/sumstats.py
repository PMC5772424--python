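"""Summary statistics for microsatellite genotypes and mtDNA alignments.

Microsatellite panel (per locus, then mean and SD across loci):

* ``K`` — number of distinct alleles;
* ``H`` — unbiased expected heterozygosity, ``(n/(n-1)) (1 - sum p_i^2)``
  with ``n`` the number of gene copies;
* ``R`` — allelic size range in repeat units (max - min);
* ``M`` — the Garza–Williamson ratio ``K / (R + 1)``, depressed by
  bottlenecks.

For multi-deme data, per-deme means of the same four quantities and
pairwise Weir–Cockerham F_ST (variance components, multi-locus
ratio-of-sums, negative estimates reported as computed) are appended.
Heterozygosity and allele counts use every typed gene copy; F_ST, being a
genotype-level statistic, uses individuals typed on both copies at a locus.
The mtDNA panel is the haplotype count ``H``, the number of segregating
sites ``S`` and the mean number of pairwise differences ``pi``.

The column layout is fixed by a manifest so observed and simulated vectors
align exactly.  The per-dataset scan is one numba kernel — reference-table
construction calls it millions of times.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit

from .datasets import MISSING, GenotypeDataset, HaplotypeDataset

MICROSAT_STAT_NAMES = ("K", "H", "R", "M")


class EmptyGroupError(ValueError):
    pass


def microsat_layout(deme_names: tuple[str, ...] | None = None
                    ) -> tuple[str, ...]:
    """Column manifest for the microsatellite summary vector."""
    cols = [f"{s}_{agg}" for s in MICROSAT_STAT_NAMES for agg in ("mean", "sd")]
    if deme_names:
        for d in deme_names:
            cols += [f"{s}_mean_{d}" for s in MICROSAT_STAT_NAMES]
        for i in range(len(deme_names)):
            for j in range(i + 1, len(deme_names)):
                cols.append(f"FST_{deme_names[i]}_{deme_names[j]}")
    return tuple(cols)


@njit(cache=True)
def _panel_kernel(alleles, group_ids, n_groups):  # pragma: no cover
    """One pass over a genotype array.

    Returns per-locus pooled (L, 4) and per-group (G, L, 4) K/H/R/M, the
    number of typed copies per group and locus (G, L), and Weir–Cockerham
    variance-component sums (G, G) accumulated over loci and alleles
    (upper triangle: numerator a, lower triangle: denominator a+b+c).
    """
    n, n_loci, _ = alleles.shape
    pooled = np.zeros((n_loci, 4))
    per_g = np.zeros((n_groups, n_loci, 4))
    copies = np.zeros((n_groups, n_loci), dtype=np.int64)
    fst = np.zeros((n_groups, n_groups))
    for l in range(n_loci):
        lo = 1 << 30
        hi = -(1 << 30)
        for i in range(n):
            for c in range(2):
                a = alleles[i, l, c]
                if a != MISSING:
                    if a < lo:
                        lo = a
                    if a > hi:
                        hi = a
        if hi < lo:
            continue
        width = hi - lo + 1
        ccnt = np.zeros((n_groups, width))
        fcnt = np.zeros((n_groups, width))
        hcnt = np.zeros((n_groups, width))
        ncomp = np.zeros(n_groups)
        for i in range(n):
            g = group_ids[i]
            a1 = alleles[i, l, 0]
            a2 = alleles[i, l, 1]
            if a1 != MISSING:
                ccnt[g, a1 - lo] += 1.0
                copies[g, l] += 1
            if a2 != MISSING:
                ccnt[g, a2 - lo] += 1.0
                copies[g, l] += 1
            if a1 != MISSING and a2 != MISSING:
                ncomp[g] += 1.0
                fcnt[g, a1 - lo] += 1.0
                fcnt[g, a2 - lo] += 1.0
                if a1 != a2:
                    hcnt[g, a1 - lo] += 1.0
                    hcnt[g, a2 - lo] += 1.0
        # pooled and per-group diversity stats
        for g in range(n_groups + 1):
            k = 0
            amin = width
            amax = -1
            tot = 0.0
            ss = 0.0
            for al in range(width):
                cval = ccnt[:, al].sum() if g == n_groups else ccnt[g, al]
                if cval > 0:
                    k += 1
                    if al < amin:
                        amin = al
                    if al > amax:
                        amax = al
                    tot += cval
                    ss += cval * cval
            if k == 0:
                continue
            rng_ = float(amax - amin)
            het = 0.0
            if tot >= 2:
                het = (tot / (tot - 1.0)) * (1.0 - ss / (tot * tot))
            row = (float(k), het, rng_, k / (rng_ + 1.0))
            if g == n_groups:
                for s in range(4):
                    pooled[l, s] = row[s]
            else:
                for s in range(4):
                    per_g[g, l, s] = row[s]
        # pairwise Weir-Cockerham components
        for gi in range(n_groups):
            for gj in range(gi + 1, n_groups):
                n1 = ncomp[gi]
                n2 = ncomp[gj]
                if n1 == 0.0 or n2 == 0.0:
                    continue
                nbar = (n1 + n2) / 2.0
                nc = n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)
                if nbar <= 1.0 or nc <= 0.0:
                    continue
                for al in range(width):
                    p1 = fcnt[gi, al] / (2.0 * n1)
                    p2 = fcnt[gj, al] / (2.0 * n2)
                    h1 = hcnt[gi, al] / n1
                    h2 = hcnt[gj, al] / n2
                    pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
                    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
                    hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
                    a = (nbar / nc) * (s2 - (pbar * (1.0 - pbar)
                                             - s2 / 2.0 - hbar / 4.0)
                                       / (nbar - 1.0))
                    b = (nbar / (nbar - 1.0)) * (
                        pbar * (1.0 - pbar) - s2 / 2.0
                        - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
                    c = hbar / 2.0
                    fst[gi, gj] += a
                    fst[gj, gi] += a + b + c
    return pooled, per_g, copies, fst


def _group_ids(data: GenotypeDataset) -> tuple[np.ndarray, tuple[str, ...]]:
    pops = data.pop_names
    lookup = {p: i for i, p in enumerate(pops)}
    ids = np.array([lookup[str(p)] for p in data.pop_labels], dtype=np.int64)
    return ids, pops


def pairwise_fst(data: GenotypeDataset, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir–Cockerham F_ST between two demes."""
    ids, pops = _group_ids(data)
    for p in (pop_a, pop_b):
        if p not in pops:
            raise EmptyGroupError(f"empty group {p!r}")
    _, _, _, fst = _panel_kernel(data.alleles, ids, len(pops))
    gi, gj = pops.index(pop_a), pops.index(pop_b)
    if gi > gj:
        gi, gj = gj, gi
    den = fst[gj, gi]
    return float(fst[gi, gj] / den) if den != 0.0 else 0.0


def microsat_sumstats(data: GenotypeDataset,
                      grouping: str = "auto") -> pd.Series:
    """Summary vector for a microsatellite dataset.

    ``grouping='pooled'`` returns the 8 pooled statistics only;
    ``'per-deme'`` appends per-deme means and pairwise F_ST;
    ``'auto'`` picks per-deme when the dataset has more than one label.
    """
    ids, pops = _group_ids(data)
    if grouping == "auto":
        grouping = "per-deme" if len(pops) > 1 else "pooled"
    if grouping not in ("pooled", "per-deme"):
        raise ValueError(f"unknown grouping {grouping!r}")
    use_demes = grouping == "per-deme"

    pooled, per_g, copies, fst = _panel_kernel(data.alleles, ids, len(pops))
    if np.any(copies.sum(axis=0) < 2):
        locus = int(np.argmin(copies.sum(axis=0)))
        raise EmptyGroupError(
            f"locus {data.locus_names[locus]}: fewer than 2 typed copies")
    if use_demes and np.any(copies < 2):
        g, locus = np.unravel_index(int(np.argmin(copies)), copies.shape)
        raise EmptyGroupError(
            f"locus {data.locus_names[locus]}, group {pops[g]!r}: fewer "
            "than 2 typed copies")

    values = []
    for si in range(4):
        values.append(pooled[:, si].mean())
        values.append(pooled[:, si].std(ddof=1) if data.n_loci > 1 else 0.0)
    if use_demes:
        for gi in range(len(pops)):
            values.extend(per_g[gi].mean(axis=0))
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                den = fst[j, i]
                values.append(fst[i, j] / den if den != 0.0 else 0.0)
    names = microsat_layout(pops if use_demes else None)
    return pd.Series(values, index=names, dtype=float)


MTDNA_LAYOUT = ("H_hap", "S_sites", "pi")


def mtdna_sumstats(data: HaplotypeDataset) -> pd.Series:
    """(H, S, pi) for a haploid alignment."""
    n = data.n_sequences
    if n < 2:
        raise ValueError("need at least 2 sequences")
    mat = data.matrix
    h = np.unique(mat, axis=0).shape[0]
    poly = np.any(mat != mat[0], axis=0)
    s = int(poly.sum())
    pi = 0.0
    if s:
        sub = mat[:, poly]
        npairs = n * (n - 1) / 2.0
        diffs = 0.0
        for col in sub.T:
            _, cnt = np.unique(col, return_counts=True)
            diffs += (n * n - int(cnt @ cnt)) / 2.0
        pi = diffs / npairs
    return pd.Series([float(h), float(s), pi], index=MTDNA_LAYOUT)


def is_zero_diversity(data: HaplotypeDataset) -> bool:
    """True iff the sample carries a single haplotype (S = 0, pi = 0)."""
    if data.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    return bool(np.all(data.matrix == data.matrix[0]))
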