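"""Domain types and readers/writers for the standard formats the pipeline touches."""

from .bedmask import apply_region_mask, read_bed, snp_covered
from .eigenstrat import read_eigenstrat, write_eigenstrat
from .freqtable import read_frequency_table, write_frequency_table
from .pileupio import read_pileup, write_pileup
from .types import (
    MISSING,
    BlockPartition,
    FrequencyPanel,
    GenotypePanel,
    Individual,
    PileupSite,
    SNPRecord,
    assign_blocks,
)
from .vcfio import read_vcf, write_vcf

__all__ = [
    "MISSING",
    "SNPRecord",
    "Individual",
    "GenotypePanel",
    "FrequencyPanel",
    "PileupSite",
    "BlockPartition",
    "assign_blocks",
    "read_genotypes",
    "write_genotypes",
    "read_eigenstrat",
    "write_eigenstrat",
    "read_vcf",
    "write_vcf",
    "read_frequency_table",
    "write_frequency_table",
    "read_bed",
    "snp_covered",
    "apply_region_mask",
    "read_pileup",
    "write_pileup",
]


def read_genotypes(path, format: str = "eigenstrat") -> GenotypePanel:
    """Dispatch to the EIGENSTRAT or VCF reader."""
    if format == "eigenstrat":
        return read_eigenstrat(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(panel: GenotypePanel, path, format: str = "eigenstrat") -> None:
    """Dispatch to the EIGENSTRAT or VCF writer."""
    if format == "eigenstrat":
        write_eigenstrat(panel, path)
    elif format == "vcf":
        write_vcf(panel, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
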