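"""VCF reader/writer for the bi-allelic SNP subset of a panel.

Reading goes through cyvcf2; records that are not bi-allelic SNPs with a GT
field are skipped and counted.  Per-sample population/class/ploidy and
per-site ancestral alleles and ascertainment tags travel in standard VCF
slots (##SAMPLE header lines, INFO AA and ASC), so write -> read is an
identity on panel content.
"""

from __future__ import annotations

import logging
import os
import re
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from ..errors import DuplicateSNPError, FormatError
from .types import MISSING, BASES, GenotypePanel, Individual, SNPRecord

__all__ = ["read_vcf", "write_vcf"]

log = logging.getLogger(__name__)

_SAMPLE_RE = re.compile(
    r"##SAMPLE=<ID=(?P<id>[^,>]+),Population=(?P<pop>[^,>]+),"
    r"Class=(?P<cls>[^,>]+),Ploidy=(?P<ploidy>[12])>"
)


def write_vcf(panel: GenotypePanel, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    chroms = []
    for s in panel.snps:
        if s.chromosome not in chroms:
            chroms.append(s.chromosome)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write(
            '##INFO=<ID=ASC,Number=.,Type=String,Description="Ascertainment panel tags">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        for ind in panel.individuals:
            fh.write(
                f"##SAMPLE=<ID={ind.id},Population={ind.population},"
                f"Class={ind.sample_class},Ploidy={ind.ploidy}>\n"
            )
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += [ind.id for ind in panel.individuals]
        fh.write("\t".join(header) + "\n")
        for m, s in enumerate(panel.snps):
            info_parts = []
            if s.ancestral_allele is not None:
                info_parts.append(f"AA={s.ancestral_allele}")
            if s.ascertainment_tags:
                info_parts.append("ASC=" + ",".join(sorted(s.ascertainment_tags)))
            info = ";".join(info_parts) or "."
            row = [s.chromosome, str(s.position), s.id, s.ref_allele, s.alt_allele,
                   ".", "PASS", info, "GT"]
            for i, ind in enumerate(panel.individuals):
                g = int(panel.genotypes[i, m])
                row.append(_format_gt(g, ind.ploidy))
            fh.write("\t".join(row) + "\n")


def _format_gt(g: int, ploidy: int) -> str:
    if ploidy == 1:
        return "." if g == MISSING else str(g)
    if g == MISSING:
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[g]


def read_vcf(path: str | os.PathLike) -> GenotypePanel:
    path = str(path)
    vcf = VCF(path)
    sample_meta = {
        m.group("id"): (m.group("pop"), m.group("cls"), int(m.group("ploidy")))
        for m in _SAMPLE_RE.finditer(vcf.raw_header)
    }
    individuals = []
    for sid in vcf.samples:
        pop, cls, ploidy = sample_meta.get(sid, (sid, "modern", 2))
        individuals.append(Individual(sid, pop, cls, ploidy))

    snps: list[SNPRecord] = []
    columns: list[np.ndarray] = []
    seen_ids: set[str] = set()
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.REF not in BASES or var.ALT[0] not in BASES:
            n_skipped += 1
            continue
        sid = var.ID or f"{var.CHROM}_{var.POS}"
        if sid in seen_ids:
            raise DuplicateSNPError(f"{path}: duplicate SNP id {sid!r}")
        seen_ids.add(sid)
        aa = var.INFO.get("AA")
        asc = var.INFO.get("ASC")
        tags = frozenset(asc.split(",")) if asc else frozenset()
        snps.append(
            SNPRecord(sid, var.CHROM, var.POS, var.REF, var.ALT[0],
                      ancestral_allele=aa, ascertainment_tags=tags)
        )
        col = np.empty(len(individuals), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            if individuals[i].ploidy == 1:
                alleles = alleles[:1]
            if not alleles or any(a < 0 for a in alleles):
                col[i] = MISSING
            else:
                col[i] = sum(1 for a in alleles if a == 1)
        columns.append(col)
    vcf.close()
    if n_skipped:
        log.info("read_vcf(%s): skipped %d non-bi-allelic-SNP records", path, n_skipped)
    genotypes = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    try:
        return GenotypePanel(snps, individuals, genotypes)
    except Exception as e:  # re-badge invariant failures as format errors
        raise FormatError(f"{path}: {e}") from e
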