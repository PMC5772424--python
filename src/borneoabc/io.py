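"""File formats and run provenance.

Observed data come in as Genepop (microsatellites) and FASTA (mtDNA);
reference tables, summary vectors and reports go out as tab-separated text
with a comment header that embeds the seed and a configuration hash, so any
artifact can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datasets import MISSING, GenotypeDataset, HaplotypeDataset
from .inference import ReferenceTable


class GenepopFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Genepop

def read_genepop(path) -> GenotypeDataset:
    """Parse a Genepop file (2- or 3-digit allele dialect).

    Allele code 0 denotes a missing allele and maps to ``MISSING``.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopFormatError("empty Genepop file")
    # locus names: one per line, or comma-separated on one line
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if not locus_names:
        raise GenepopFormatError("no locus names before the first 'pop'")
    alleles: list[list[tuple[int, int]]] = []
    labels: list[str] = []
    ids: list[str] = []
    pop_no = 0
    block_count = 0
    while i < len(lines):
        if lines[i].strip().lower() == "pop":
            if pop_no and block_count == 0:
                raise GenepopFormatError(f"empty pop block #{pop_no}")
            pop_no += 1
            block_count = 0
            i += 1
            continue
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if pop_no == 0:
            raise GenepopFormatError(
                f"line {i + 1}: individual record before any 'pop'")
        if "," not in line:
            raise GenepopFormatError(
                f"line {i + 1}: expected 'id , genotypes', got {line!r}")
        ind_id, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise GenepopFormatError(
                f"line {i + 1}: {len(tokens)} genotypes for "
                f"{len(locus_names)} loci")
        row = []
        for tok in tokens:
            if len(tok) == 4:
                digits = 2
            elif len(tok) == 6:
                digits = 3
            else:
                raise GenepopFormatError(
                    f"line {i + 1}: genotype token {tok!r} is neither 4 nor "
                    "6 digits")
            try:
                a1 = int(tok[:digits])
                a2 = int(tok[digits:])
            except ValueError as err:
                raise GenepopFormatError(
                    f"line {i + 1}: non-numeric genotype {tok!r}") from err
            row.append((a1 if a1 else MISSING, a2 if a2 else MISSING))
        alleles.append(row)
        labels.append(f"pop{pop_no}")
        ids.append(ind_id.strip())
        block_count += 1
        i += 1
    if pop_no == 0:
        raise GenepopFormatError("no 'pop' blocks found")
    if block_count == 0:
        raise GenepopFormatError(f"empty pop block #{pop_no}")
    arr = np.array(alleles, dtype=np.int32)
    return GenotypeDataset(arr, np.array(labels), tuple(locus_names),
                           tuple(ids))


def write_genepop(data: GenotypeDataset, path, title: str = "borneoabc",
                  pop_names: tuple[str, ...] | None = None) -> None:
    """Write a Genepop file in the 3-digit allele dialect."""
    valid = data.alleles[data.alleles != MISSING]
    if valid.size and (valid.min() < 1 or valid.max() > 999):
        raise ValueError(
            f"allele sizes {valid.min()}..{valid.max()} do not fit the "
            "3-digit Genepop dialect (1..999)")
    out = [title]
    out.extend(data.locus_names)
    for pop in (pop_names or data.pop_names):
        idx = data.pop_indices(pop)
        out.append("pop")
        for k in idx:
            toks = []
            for locus in range(data.n_loci):
                a1, a2 = data.alleles[k, locus]
                toks.append(f"{max(a1, 0):03d}{max(a2, 0):03d}")
            out.append(f"{data.individual_ids[k]} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> HaplotypeDataset:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return HaplotypeDataset.from_sequences(
        [str(r.seq) for r in records], tuple(r.id for r in records))


def write_fasta(data: HaplotypeDataset, path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="")
               for s, i in zip(data.sequences(), data.ids)]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# provenance + delimited tables

def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in sorted(meta.items()))


def write_table(frame: pd.DataFrame, path, meta: dict | None = None,
                index: bool = False) -> None:
    """TSV with a '#'-comment provenance header."""
    with open(path, "w") as fh:
        if meta:
            fh.write(_header_lines(meta))
        frame.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


PARAM_PREFIX = "param:"
STAT_PREFIX = "stat:"


def write_reference_table(table: ReferenceTable, path,
                          append: bool = False) -> None:
    """Reference table as TSV: a `model` column plus `param:`/`stat:`
    prefixed columns (the header manifest).  ``append=True`` adds rows
    without a header — the chunked streaming path."""
    frame = pd.concat(
        [pd.Series(table.models, name="model"),
         table.params.add_prefix(PARAM_PREFIX),
         table.stats.add_prefix(STAT_PREFIX)], axis=1)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write(_header_lines(table.meta))
        frame.to_csv(fh, sep="\t", index=False, header=not append)


def read_reference_table(path) -> ReferenceTable:
    frame = pd.read_csv(path, sep="\t", comment="#")
    params = frame[[c for c in frame if c.startswith(PARAM_PREFIX)]].rename(
        columns=lambda c: c[len(PARAM_PREFIX):])
    stats = frame[[c for c in frame if c.startswith(STAT_PREFIX)]].rename(
        columns=lambda c: c[len(STAT_PREFIX):])
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    return ReferenceTable(frame["model"].to_numpy(), params, stats, meta)
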