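"""Structured-coalescent simulation with microsatellite and mtDNA mutations.

The genealogy sampler is a continuous-time Kingman coalescent over the
piecewise-exponential demographies produced by :mod:`borneoabc.demography`.
Within each epoch the coalescence waiting time has a closed form (time
rescaling of an exponential clock), so no time discretization is involved.
Demes of equal size are supported before a merge event, matching the
fragmentation models (ACS/RIS).

Mutations are superimposed on the genealogy afterwards:

* microsatellites follow the generalized stepwise mutation model (GSM):
  mutation counts are Poisson in branch length, each mutation moves the
  allele by ``±k`` repeat units with ``k`` geometric,
  ``P(k) = (1 - p_gsm) p_gsm^(k-1)`` (``p_gsm = 0`` is the strict SMM);
  allele sizes are unbounded;
* mtDNA sequences evolve under infinite sites: every mutation hits a fresh
  site, and a sample sequence carries the mutations on its root path.

The hot loops are numba-jitted; all randomness is drawn from a caller-owned
:class:`numpy.random.Generator`, so runs are reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .datasets import ANCESTRAL_ALLELE, GenotypeDataset, HaplotypeDataset
from .demography import DemographyRealization, ModelParams, build_demography

#: pair coalescence rate in a deme of (diploid) size N is 1/(2N) for
#: autosomal gene copies …
DIPLOID_PAIR_FACTOR = 2.0
#: … and 1/(f N) for mitochondrial lineages.  The default f = 1 corresponds
#: to simulating the mtDNA locus in a population of N/2 females with
#: standard diploid rate scaling (pair rate 1/(2 * N/2) = 1/N); smaller
#: values give a faster mitochondrial clock.
DEFAULT_FEMALE_SCALE = 1.0

MTDNA_LENGTH = 630


class NonCoalescingDemographyError(RuntimeError):
    pass


@dataclass(frozen=True)
class SampleConfig:
    """How many copies to sample where.

    ``groups`` maps a group label to a number of *individuals* (diploid) or
    *sequences* (haploid).  ``group_demes`` assigns each group to a deme of
    the demography; for unstructured models every group sits in deme 0 and
    the labels are a bookkeeping device (they define the statistical groups
    used by the summary statistics).
    """

    groups: tuple[tuple[str, int], ...]
    ploidy: str = "autosomal-diploid"  # or "mitochondrial-haploid"
    n_loci: int = 1
    group_demes: tuple[int, ...] = ()

    def __post_init__(self):
        if self.ploidy not in ("autosomal-diploid", "mitochondrial-haploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        if any(c < 1 for _, c in self.groups):
            raise ValueError("all group counts must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.group_demes and len(self.group_demes) != len(self.groups):
            raise ValueError("group_demes length mismatch")

    @property
    def copies_per_group(self) -> tuple[int, ...]:
        mult = 2 if self.ploidy == "autosomal-diploid" else 1
        return tuple(mult * c for _, c in self.groups)

    @property
    def n_copies(self) -> int:
        return sum(self.copies_per_group)

    def tip_demes(self) -> np.ndarray:
        demes = self.group_demes or tuple(0 for _ in self.groups)
        out = np.concatenate([
            np.full(c, d, dtype=np.int64)
            for c, d in zip(self.copies_per_group, demes)])
        return out


@dataclass
class Genealogy:
    """A coalescent tree: node ``i < n`` are tips (time 0); internal nodes
    are numbered in coalescence order, so ``parent[i] > i`` everywhere and
    node times are non-decreasing in node id."""

    parent: np.ndarray  # int32, length 2n-1, parent[root] == -1
    node_time: np.ndarray  # float64, length 2n-1
    n_samples: int

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_samples - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[-1]) if self.n_samples > 1 else 0.0

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        nb = self.n_nodes - 1
        return self.node_time[self.parent[:nb]] - self.node_time[:nb]

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum()) if self.n_samples > 1 else 0.0

    def validate(self) -> None:
        n = self.n_samples
        if n == 1:
            return
        assert np.all(self.node_time[:n] == 0.0)
        assert np.all(self.node_time[n:] > 0.0)
        assert np.all(np.diff(self.node_time[n:]) >= 0.0)
        assert self.parent[-1] == -1
        assert np.all(self.parent[:-1] > np.arange(self.n_nodes - 1))


@dataclass(frozen=True)
class MutationConfig:
    """Per-locus mutation settings.

    ``mu`` is the mutation rate per locus (microsatellite) or per sequence
    (mtDNA) per generation; ``p_gsm`` the geometric multistep parameter;
    ``sequence_length`` is bookkeeping for FASTA output only.
    """

    mu: float
    p_gsm: float = 0.0
    sequence_length: int = MTDNA_LENGTH

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not 0.0 <= self.p_gsm < 1.0:
            raise ValueError("p_gsm must be in [0, 1)")


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _coalesce(n, deme0, ep_t0, ep_c, ep_alpha, ep_d,
              exps, u_deme, u_i, u_j, parent, node_time):  # pragma: no cover
    max_d = 8
    members = np.empty((max_d, n), dtype=np.int32)
    kd = np.zeros(max_d, dtype=np.int64)
    for i in range(n):
        d = deme0[i]
        members[d, kd[d]] = i
        kd[d] += 1
        parent[i] = -1
        node_time[i] = 0.0
    nep = ep_t0.shape[0]
    e = 0
    cur_d = ep_d[0]
    s_pairs = 0.0
    for d in range(max_d):
        s_pairs += kd[d] * (kd[d] - 1) / 2.0
    k = n
    t = 0.0
    ev = 0
    next_node = n
    need = exps[0]
    while k > 1:
        if e >= nep:
            return -1  # lineages stranded: demography never coalesces them
        if ep_d[e] < cur_d:
            for d in range(1, max_d):
                for m in range(kd[d]):
                    members[0, kd[0]] = members[d, m]
                    kd[0] += 1
                kd[d] = 0
            cur_d = ep_d[e]
            s_pairs = kd[0] * (kd[0] - 1) / 2.0
        t0 = ep_t0[e]
        c0 = ep_c[e]
        al = ep_alpha[e]
        t1 = ep_t0[e + 1] if e + 1 < nep else np.inf
        if s_pairs <= 0.0:
            if t1 == np.inf:
                return -1
            t = t1
            e += 1
            continue
        rate0 = s_pairs / c0
        x = t - t0
        if al == 0.0:
            avail = rate0 * (t1 - t)
            if need >= avail:
                need -= avail
                t = t1
                e += 1
                continue
            dt = need / rate0
        else:
            g = np.exp(al * x)
            if t1 == np.inf:
                g1 = np.inf if al > 0.0 else 0.0
            else:
                g1 = np.exp(al * (t1 - t0))
            aval = rate0 / al * (g1 - g)
            if need >= aval:
                need -= aval
                t = t1
                e += 1
                continue
            dt = np.log(g + need * al / rate0) / al - x
        t += dt
        if cur_d == 1:
            d = 0
        else:
            r = u_deme[ev] * s_pairs
            acc = 0.0
            d = 0
            for dd in range(max_d):
                acc += kd[dd] * (kd[dd] - 1) / 2.0
                if r < acc:
                    d = dd
                    break
        kdd = kd[d]
        i1 = np.int64(u_i[ev] * kdd)
        if i1 >= kdd:
            i1 = kdd - 1
        i2 = np.int64(u_j[ev] * (kdd - 1))
        if i2 >= kdd - 1:
            i2 = kdd - 2
        if i2 >= i1:
            i2 += 1
        c1 = members[d, i1]
        c2 = members[d, i2]
        pnode = next_node
        next_node += 1
        parent[c1] = pnode
        parent[c2] = pnode
        node_time[pnode] = t
        parent[pnode] = -1
        members[d, i1] = pnode
        members[d, i2] = members[d, kdd - 1]
        kd[d] = kdd - 1
        s_pairs -= kdd - 1
        k -= 1
        ev += 1
        if k > 1:
            need = exps[ev]
    return ev


@njit(cache=True)
def _accumulate_root_paths(parent, values):  # pragma: no cover
    # values[i] holds the per-branch contribution; on return it holds the
    # sum along the path from the root down to node i.  Relies on
    # parent[i] > i (coalescence ordering).
    for i in range(values.shape[0] - 2, -1, -1):
        values[i] += values[parent[i]]


@njit(cache=True)
def _leaves_below(parent, n_samples, n_nodes):  # pragma: no cover
    counts = np.zeros(n_nodes, dtype=np.int64)
    counts[:n_samples] = 1
    for i in range(n_nodes - 1):
        counts[parent[i]] += counts[i]
    return counts


# ---------------------------------------------------------------------------
# public operations

def simulate_genealogy(demog: DemographyRealization, sample: SampleConfig,
                       rng: np.random.Generator,
                       female_scale: float = DEFAULT_FEMALE_SCALE) -> Genealogy:
    """Simulate one genealogy for ``sample`` under ``demog``.

    With ``k`` lineages in a deme of diploid size ``N(t)`` the total
    coalescence rate is ``k(k-1)/(4N(t))`` for autosomal copies and
    ``k(k-1)/(2 N_f(t))`` with ``N_f = female_scale * N`` for mitochondrial
    lineages.
    """
    n = sample.n_copies
    tip_demes = sample.tip_demes()
    if tip_demes.max(initial=0) >= demog.epochs[0].n_demes:
        raise ValueError(
            f"sample places lineages in deme {int(tip_demes.max())} but the "
            f"demography has {demog.epochs[0].n_demes} demes at t=0")
    parent = np.full(2 * n - 1, -1, dtype=np.int32)
    node_time = np.zeros(2 * n - 1, dtype=np.float64)
    if n == 1:
        return Genealogy(parent, node_time, 1)
    factor = (DIPLOID_PAIR_FACTOR if sample.ploidy == "autosomal-diploid"
              else female_scale)
    ep_t0, ep_c, ep_al, ep_d = demog.kernel_epochs(factor)
    exps = rng.exponential(size=n - 1)
    u = rng.random((3, n - 1))
    nev = _coalesce(n, tip_demes, ep_t0, ep_c, ep_al, ep_d,
                    exps, u[0], u[1], u[2], parent, node_time)
    if nev != n - 1:
        raise NonCoalescingDemographyError(
            f"{demog.model_id}: lineages stranded in demes that never merge")
    return Genealogy(parent, node_time, n)


def mutate_microsat(tree: Genealogy, cfg: MutationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """GSM mutations on a genealogy -> allele size offset per tip.

    The ancestral allele is offset 0; tips carry the signed sum of the
    geometric step sizes on their root path.
    """
    n = tree.n_samples
    if n == 1 or cfg.mu == 0.0:
        return np.zeros(n, dtype=np.int64)
    lengths = tree.branch_lengths()
    counts = rng.poisson(cfg.mu * lengths)
    total = int(counts.sum())
    steps = np.zeros(tree.n_nodes, dtype=np.int64)
    if total:
        signs = rng.integers(0, 2, size=total) * 2 - 1
        mags = rng.geometric(1.0 - cfg.p_gsm, size=total)
        branch_of = np.repeat(np.arange(len(counts)), counts)
        steps[:-1] = np.bincount(branch_of, weights=signs * mags,
                                 minlength=len(counts)).astype(np.int64)
    _accumulate_root_paths(tree.parent, steps)
    return steps[:n]


def mutate_sequence(tree: Genealogy, cfg: MutationConfig,
                    rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Infinite-sites mutations -> (site incidence matrix, branch of site).

    Returns a boolean matrix of shape ``(n_samples, S)`` whose row is the
    set of derived sites carried by that tip, plus the per-site branch
    index (useful for diagnostics).  ``cfg.mu`` is the per-sequence rate.
    """
    n = tree.n_samples
    if n == 1 or cfg.mu == 0.0:
        return np.zeros((n, 0), dtype=bool), np.zeros(0, dtype=np.int64)
    lengths = tree.branch_lengths()
    counts = rng.poisson(cfg.mu * lengths)
    total = int(counts.sum())
    if total == 0:
        return np.zeros((n, 0), dtype=bool), np.zeros(0, dtype=np.int64)
    site_branch = np.repeat(np.arange(len(counts)), counts)
    # tips below each branch, via one root-path accumulation per mutated branch
    mutated = np.flatnonzero(counts)
    incidence = np.zeros((n, total), dtype=bool)
    for b in mutated:
        marker = np.zeros(tree.n_nodes, dtype=np.int64)
        marker[b] = 1
        _accumulate_root_paths(tree.parent, marker)
        below = marker[:n] > 0
        incidence[:, site_branch == b] = below[:, None]
    return incidence, site_branch


def haplotypes_from_incidence(incidence: np.ndarray,
                              sequence_length: int,
                              rng: np.random.Generator,
                              ids: tuple[str, ...] = ()) -> HaplotypeDataset:
    """Materialize an infinite-sites incidence matrix as DNA sequences.

    Derived sites are placed at distinct positions drawn without replacement
    along a monomorphic ancestral sequence.
    """
    n, n_sites = incidence.shape
    if n_sites > sequence_length:
        raise ValueError(
            f"{n_sites} segregating sites exceed the sequence length "
            f"{sequence_length}")
    mat = np.full((n, sequence_length), "A", dtype="<U1")
    if n_sites:
        positions = rng.choice(sequence_length, size=n_sites, replace=False)
        for j, pos in enumerate(positions):
            mat[incidence[:, j], pos] = "T"
    return HaplotypeDataset(mat, ids)


def count_haplotypes(incidence: np.ndarray) -> int:
    if incidence.shape[1] == 0:
        return 1
    return np.unique(incidence, axis=0).shape[0]


def simulate_dataset(model_id: str, params: ModelParams, sample: SampleConfig,
                     rng: np.random.Generator,
                     female_scale: float = DEFAULT_FEMALE_SCALE,
                     locus_rate_cv: float = 0.0,
                     demog: DemographyRealization | None = None,
                     ) -> GenotypeDataset | HaplotypeDataset:
    """Simulate a full multi-locus dataset under one parameter draw.

    One independent genealogy is simulated per locus.  All loci share the
    drawn mean mutation rate; with ``locus_rate_cv > 0`` per-locus rates get
    an optional gamma scatter around that mean (off by default).
    """
    if demog is None:
        demog = build_demography(model_id, params)
    if sample.ploidy == "mitochondrial-haploid":
        tree = simulate_genealogy(demog, sample, rng, female_scale)
        incidence, _ = mutate_sequence(tree, MutationConfig(params.mu), rng)
        return haplotypes_from_incidence(incidence, MTDNA_LENGTH, rng)

    rates = np.full(sample.n_loci, params.mu)
    if locus_rate_cv > 0.0:
        shape = 1.0 / locus_rate_cv ** 2
        rates = params.mu * rng.gamma(shape, 1.0 / shape, size=sample.n_loci)
    n_ind = sum(c for _, c in sample.groups)
    alleles = np.empty((n_ind, sample.n_loci, 2), dtype=np.int32)
    for locus in range(sample.n_loci):
        tree = simulate_genealogy(demog, sample, rng, female_scale)
        tips = mutate_microsat(tree, MutationConfig(rates[locus], params.p_gsm),
                               rng)
        sizes = ANCESTRAL_ALLELE + tips
        alleles[:, locus, 0] = sizes[0::2]
        alleles[:, locus, 1] = sizes[1::2]
    labels = np.concatenate([np.full(c, name)
                             for name, c in sample.groups])
    locus_names = tuple(f"locus{j + 1:02d}" for j in range(sample.n_loci))
    return GenotypeDataset(alleles, labels, locus_names)


def leaves_below(tree: Genealogy) -> np.ndarray:
    """Number of sampled tips below each node (tips themselves count 1)."""
    return _leaves_below(tree.parent, tree.n_samples, tree.n_nodes)
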