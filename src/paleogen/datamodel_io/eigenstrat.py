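"""EIGENSTRAT triple (.geno/.snp/.ind) reader and writer.

Only the dense text .geno dialect is supported (one row per SNP, one digit
per individual, 9 = missing); packed binary variants are out of scope.

EIGENSTRAT has no standard slot for per-individual ploidy/class, ancestral
alleles or ascertainment tags, so the writer also emits an optional sidecar
``<prefix>.meta.tsv``; the reader consumes it when present so that
write -> read is an identity on all panel fields.  The triple itself remains
fully standard and usable without the sidecar.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from ..errors import (
    AlleleError,
    DimensionMismatchError,
    DuplicateSNPError,
    FormatError,
)
from .types import MISSING, BASES, GenotypePanel, Individual, SNPRecord

__all__ = ["read_eigenstrat", "write_eigenstrat"]

_GENO_MAP = {"0": 0, "1": 1, "2": 2, "9": MISSING}
_GENO_CHAR = {0: "0", 1: "1", 2: "2", MISSING: "9"}


def write_eigenstrat(panel: GenotypePanel, prefix: str | os.PathLike) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.snp", "w") as fh:
        for s in panel.snps:
            fh.write(
                f"{s.id}\t{s.chromosome}\t0.0\t{s.position}\t{s.ref_allele}\t{s.alt_allele}\n"
            )
    with open(f"{prefix}.ind", "w") as fh:
        for ind in panel.individuals:
            fh.write(f"{ind.id}\tU\t{ind.population}\n")
    with open(f"{prefix}.geno", "w") as fh:
        for m in range(panel.n_snps):
            fh.write("".join(_GENO_CHAR[int(g)] for g in panel.genotypes[:, m]) + "\n")
    _write_meta(panel, prefix)


def _write_meta(panel: GenotypePanel, prefix: Path) -> None:
    with open(f"{prefix}.meta.tsv", "w") as fh:
        fh.write("#kind\tid\tfield1\tfield2\n")
        for ind in panel.individuals:
            fh.write(f"IND\t{ind.id}\t{ind.sample_class}\t{ind.ploidy}\n")
        for s in panel.snps:
            anc = s.ancestral_allele or "."
            tags = ",".join(sorted(s.ascertainment_tags)) or "."
            fh.write(f"SNP\t{s.id}\t{anc}\t{tags}\n")


def read_eigenstrat(prefix: str | os.PathLike) -> GenotypePanel:
    prefix = Path(prefix)
    snps = _read_snp(f"{prefix}.snp")
    individuals = _read_ind(f"{prefix}.ind")
    meta_path = Path(f"{prefix}.meta.tsv")
    if meta_path.exists():
        snps, individuals = _apply_meta(meta_path, snps, individuals)
    genotypes = _read_geno(f"{prefix}.geno", len(individuals), len(snps))
    return GenotypePanel(snps, individuals, genotypes)


def _read_snp(path: str) -> list[SNPRecord]:
    snps: list[SNPRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            sid, chrom, _gpos, pos, ref, alt = fields[:6]
            if sid in seen:
                raise DuplicateSNPError(f"{path}:{lineno}: duplicate SNP id {sid!r}")
            seen.add(sid)
            if ref not in BASES or alt not in BASES:
                raise AlleleError(f"{path}:{lineno}: unparseable alleles {ref}/{alt}")
            try:
                snps.append(SNPRecord(sid, chrom, int(pos), ref, alt))
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from e
    return snps


def _read_ind(path: str) -> list[Individual]:
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            individuals.append(Individual(fields[0], fields[2]))
    return individuals


def _apply_meta(path: Path, snps, individuals):
    ind_meta: dict[str, tuple[str, int]] = {}
    snp_meta: dict[str, tuple[str | None, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            kind, key, f1, f2 = line.rstrip("\n").split("\t")
            if kind == "IND":
                ind_meta[key] = (f1, int(f2))
            elif kind == "SNP":
                anc = None if f1 == "." else f1
                tags = frozenset() if f2 == "." else frozenset(f2.split(","))
                snp_meta[key] = (anc, tags)
    individuals = [
        Individual(i.id, i.population, *ind_meta[i.id]) if i.id in ind_meta else i
        for i in individuals
    ]
    snps = [
        s.with_(ancestral_allele=snp_meta[s.id][0], ascertainment_tags=snp_meta[s.id][1])
        if s.id in snp_meta
        else s
        for s in snps
    ]
    return snps, individuals


def _read_geno(path: str, n_ind: int, n_snp: int) -> np.ndarray:
    genotypes = np.full((n_ind, n_snp), MISSING, dtype=np.int8)
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            row = line.strip()
            if not row:
                continue
            if n_rows >= n_snp:
                raise DimensionMismatchError(
                    f"{path}: more genotype rows than SNPs ({n_snp})"
                )
            if len(row) != n_ind:
                raise DimensionMismatchError(
                    f"{path}:{lineno}: {len(row)} columns but {n_ind} individuals"
                )
            try:
                genotypes[:, n_rows] = [_GENO_MAP[c] for c in row]
            except KeyError as e:
                raise FormatError(f"{path}:{lineno}: bad genotype char {e}") from e
            n_rows += 1
    if n_rows != n_snp:
        raise DimensionMismatchError(
            f"{path}: {n_rows} genotype rows but {n_snp} SNPs in .snp"
        )
    return genotypes
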