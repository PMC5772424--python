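"""Synthetic pseudo-observed datasets with the structure of the Sabah data.

The real genotypes behind the original analysis (224 elephants at 18
microsatellite loci from four Sabah regions, plus 630 bp of mtDNA from 60 of
them) are not publicly deposited, so pipeline-level work runs on synthetic
stand-ins of exactly that shape, simulated under a known (recorded) model
and parameter draw.  A truth sidecar accompanies every generated dataset so
it can be re-simulated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as bio
from .coalescent import MTDNA_LENGTH, SampleConfig, simulate_dataset
from .demography import (ModelParams, ModelSpec, STRUCTURED_MODELS,
                         draw_params)

DEFAULT_DEME_NAMES = ("LowerKinabatangan", "NorthKinabatangan",
                      "CentralForest", "Tabin")


@dataclass(frozen=True)
class DatasetShape:
    """Sampling layout of the study: individuals per deme, loci, mtDNA."""

    individuals_per_deme: tuple[int, ...] = (56, 56, 56, 56)
    n_loci: int = 18
    mtdna_n: int = 60
    mtdna_length: int = MTDNA_LENGTH
    deme_names: tuple[str, ...] = DEFAULT_DEME_NAMES

    def __post_init__(self):
        if len(self.individuals_per_deme) != len(self.deme_names):
            raise ValueError("deme count mismatch")
        if any(c < 1 for c in self.individuals_per_deme) or self.n_loci < 1:
            raise ValueError("counts must be positive")
        if not 2 <= self.mtdna_n <= self.n_individuals:
            raise ValueError("mtDNA sample must be 2..n_individuals")

    @property
    def n_individuals(self) -> int:
        return sum(self.individuals_per_deme)

    def microsat_sample(self, structured: bool) -> SampleConfig:
        demes = (tuple(range(len(self.deme_names))) if structured
                 else tuple(0 for _ in self.deme_names))
        return SampleConfig(
            groups=tuple(zip(self.deme_names, self.individuals_per_deme)),
            ploidy="autosomal-diploid", n_loci=self.n_loci,
            group_demes=demes)


def sample_configs_for(specs: dict[str, ModelSpec], shape: DatasetShape
                       ) -> dict[str, SampleConfig]:
    """Per-model sampling layouts sharing one statistical-group structure."""
    return {mid: shape.microsat_sample(mid in STRUCTURED_MODELS)
            for mid in specs}


def generate_observed_like(spec: ModelSpec, shape: DatasetShape, seed: int,
                           outdir, params: ModelParams | None = None,
                           missing_rate: float = 0.0) -> dict:
    """Simulate one microsatellite + mtDNA dataset and write it to disk.

    Writes Genepop (3-digit), FASTA, and a YAML truth sidecar (model, full
    parameter vector, seed, shape).  The mtDNA individuals are a subsample
    of the genotyped ones.  Returns the sidecar mapping.
    """
    # separate streams so a sidecar (explicit params + seed) re-simulates
    # the identical dataset whether or not the draw step ran
    mid = spec.model_id
    if params is None:
        params = draw_params(spec, np.random.default_rng([seed, 0]))
    rng = np.random.default_rng([seed, 1])
    sample = shape.microsat_sample(mid in STRUCTURED_MODELS)
    geno = simulate_dataset(mid, params, sample, rng)
    if missing_rate > 0.0:
        mask = rng.random(geno.alleles.shape) < missing_rate
        geno.alleles[mask] = -1
    mt_sample = SampleConfig(groups=(("mtDNA", shape.mtdna_n),),
                             ploidy="mitochondrial-haploid")
    mt_params = params
    hap = simulate_dataset(mid, mt_params, mt_sample, rng)
    chosen = np.sort(rng.choice(shape.n_individuals, size=shape.mtdna_n,
                                replace=False))
    hap.ids = tuple(geno.individual_ids[i] for i in chosen)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bio.write_genepop(geno, outdir / "microsat.gen",
                      title=f"synthetic {mid} dataset")
    bio.write_fasta(hap, outdir / "mtdna.fasta")
    sidecar = {
        "model": mid,
        "seed": int(seed),
        "params": {k: float(v) for k, v in params.as_dict().items()},
        "shape": {
            "individuals_per_deme": list(shape.individuals_per_deme),
            "n_loci": shape.n_loci,
            "mtdna_n": shape.mtdna_n,
            "mtdna_length": shape.mtdna_length,
            "deme_names": list(shape.deme_names),
        },
        "missing_rate": missing_rate,
        "mtdna_individuals": list(hap.ids),
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return sidecar


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def make_fixture_suite(seed: int, outdir) -> dict:
    """Tiny edge-case datasets for unit tests, with a checksum manifest.

    Includes a multi-deme dataset, a single-deme one, one with a
    monomorphic locus, and one with missing genotypes (<=10 individuals,
    3 loci each).
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .datasets import GenotypeDataset

    def random_geno(n, n_loci, pops, mono_locus=None, missing=0.0):
        alleles = 200 + rng.integers(-3, 4, size=(n, n_loci, 2)).astype(
            np.int32)
        if mono_locus is not None:
            alleles[:, mono_locus, :] = 200
        if missing:
            mask = rng.random(alleles.shape) < missing
            alleles[mask] = -1
            alleles[0] = 200  # keep every locus typed at least once
        return GenotypeDataset(alleles, np.asarray(pops),
                               tuple(f"loc{j}" for j in range(n_loci)))

    fixtures = {
        "two_demes.gen": random_geno(8, 3, ["A"] * 4 + ["B"] * 4),
        "single_deme.gen": random_geno(6, 3, ["A"] * 6),
        "monomorphic.gen": random_geno(10, 3, ["A"] * 5 + ["B"] * 5,
                                       mono_locus=1),
        "missing.gen": random_geno(10, 3, ["A"] * 5 + ["B"] * 5, missing=0.2),
    }
    manifest = {}
    for name, data in fixtures.items():
        path = outdir / name
        bio.write_genepop(data, path, title=f"fixture {name}")
        manifest[name] = _checksum(path)
    (outdir / "MANIFEST.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
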