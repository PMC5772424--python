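"""In-memory containers for microsatellite genotypes and mtDNA haplotypes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: sentinel for a missing allele (written as 0 in Genepop files)
MISSING = -1
#: allele size (repeat units) assigned to the ancestral state by the simulator
ANCESTRAL_ALLELE = 200


@dataclass
class GenotypeDataset:
    """Diploid microsatellite genotypes with population labels.

    ``alleles`` has shape ``(n_individuals, n_loci, 2)`` and holds integer
    allele sizes in repeat units (``MISSING`` for a missing allele).
    """

    alleles: np.ndarray
    pop_labels: np.ndarray  # str per individual
    locus_names: tuple[str, ...]
    individual_ids: tuple[str, ...] = ()

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n, L, 2)")
        self.pop_labels = np.asarray(self.pop_labels)
        if len(self.pop_labels) != self.alleles.shape[0]:
            raise ValueError("pop_labels length mismatch")
        if len(self.locus_names) != self.alleles.shape[1]:
            raise ValueError("locus_names length mismatch")
        if not self.individual_ids:
            self.individual_ids = tuple(
                f"{p}_{i:03d}" for i, p in enumerate(self.pop_labels))

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def pop_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(str(p))
        return tuple(seen)

    def pop_indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.pop_labels == name)


@dataclass
class HaplotypeDataset:
    """A haploid alignment (equal-length sequences) as a character matrix."""

    matrix: np.ndarray  # (n_sequences, length), dtype '<U1' or uint8
    ids: tuple[str, ...] = ()

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if not self.ids:
            self.ids = tuple(f"seq{i:03d}" for i in range(self.matrix.shape[0]))

    @classmethod
    def from_sequences(cls, seqs: list[str], ids: tuple[str, ...] = ()
                       ) -> "HaplotypeDataset":
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(
                f"ragged alignment: sequence lengths {sorted(lengths)}")
        mat = np.array([list(s.upper()) for s in seqs])
        return cls(mat, ids)

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.matrix]
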