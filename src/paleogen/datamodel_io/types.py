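"""Core domain types: SNPs, individuals, genotype and frequency panels,
pileup sites and the 5 Mb jackknife block partition."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ..errors import ValidationError

__all__ = [
    "MISSING",
    "BASES",
    "SNPRecord",
    "Individual",
    "GenotypePanel",
    "FrequencyPanel",
    "PileupSite",
    "BlockPartition",
    "assign_blocks",
]

#: Sentinel for a missing genotype, regardless of source format.
MISSING: int = -1

BASES = frozenset("ACGT")

_TRANSITION_PAIRS = (frozenset("CT"), frozenset("GA"))


@dataclass(frozen=True)
class SNPRecord:
    """A bi-allelic SNP with 1-based coordinates.

    ``ancestral_allele`` is ``None`` when unknown; ``ascertainment_tags``
    records the discovery panel(s) of the SNP for ascertainment filters.
    """

    id: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    ancestral_allele: str | None = None
    ascertainment_tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.position < 1:
            raise ValidationError(f"SNP {self.id}: position must be >= 1")
        for name in ("ref_allele", "alt_allele"):
            a = getattr(self, name)
            if a not in BASES:
                raise ValidationError(f"SNP {self.id}: {name} {a!r} not in ACGT")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"SNP {self.id}: ref and alt alleles are equal")
        if self.ancestral_allele is not None and self.ancestral_allele not in BASES:
            raise ValidationError(
                f"SNP {self.id}: ancestral allele {self.ancestral_allele!r} invalid"
            )
        object.__setattr__(self, "ascertainment_tags", frozenset(self.ascertainment_tags))

    @property
    def allele_pair(self) -> frozenset[str]:
        return frozenset((self.ref_allele, self.alt_allele))

    @property
    def is_transition(self) -> bool:
        """True iff {ref, alt} is {C,T} or {G,A}."""
        return self.allele_pair in _TRANSITION_PAIRS

    def with_(self, **kw) -> "SNPRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class Individual:
    id: str
    population: str
    sample_class: str = "modern"  # modern | ancient | archaic
    ploidy: int = 2

    def __post_init__(self):
        if self.sample_class not in ("modern", "ancient", "archaic"):
            raise ValidationError(f"individual {self.id}: bad class {self.sample_class!r}")
        if self.ploidy not in (1, 2):
            raise ValidationError(f"individual {self.id}: ploidy must be 1 or 2")


class GenotypePanel:
    """Individuals x SNPs matrix of alt-allele counts.

    Genotypes are stored as int8: 0/1/2 counts of the alt allele, with
    :data:`MISSING` (-1) for no-calls.  Haploid rows carry only {0,1,missing}.
    """

    def __init__(
        self,
        snps: Sequence[SNPRecord],
        individuals: Sequence[Individual],
        genotypes: np.ndarray,
    ):
        self.snps = list(snps)
        self.individuals = list(individuals)
        g = np.asarray(genotypes, dtype=np.int8)
        if g.shape != (len(self.individuals), len(self.snps)):
            raise ValidationError(
                f"genotype matrix shape {g.shape} != "
                f"({len(self.individuals)}, {len(self.snps)})"
            )
        self.genotypes = g
        self._validate()

    def _validate(self):
        g = self.genotypes
        if g.size and ((g < MISSING) | (g > 2)).any():
            raise ValidationError("genotypes must be in {0,1,2} or missing (-1)")
        for i, ind in enumerate(self.individuals):
            if ind.ploidy == 1 and g.size and (g[i] > 1).any():
                raise ValidationError(
                    f"haploid individual {ind.id} carries genotype 2"
                )
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            from ..errors import DuplicateSNPError

            raise DuplicateSNPError("duplicate SNP ids in panel")

    # -- basic queries -------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def individual_index(self, ind_id: str) -> int:
        for i, ind in enumerate(self.individuals):
            if ind.id == ind_id:
                return i
        raise KeyError(f"no individual {ind_id!r} in panel")

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.snps], dtype=np.int64)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps], dtype=object)

    def ploidies(self) -> np.ndarray:
        return np.array([ind.ploidy for ind in self.individuals], dtype=np.int8)

    # -- structural edits (all return new panels) ----------------------

    def subset_snps(self, index: Iterable[int] | np.ndarray) -> "GenotypePanel":
        idx = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        snps = [self.snps[int(i)] for i in idx]
        return GenotypePanel(snps, self.individuals, self.genotypes[:, idx])

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.individual_index(i) for i in ids]
        inds = [self.individuals[i] for i in idx]
        return GenotypePanel(self.snps, inds, self.genotypes[idx, :])

    def with_individual(
        self, individual: Individual, genotypes: np.ndarray
    ) -> "GenotypePanel":
        g = np.vstack([self.genotypes, np.asarray(genotypes, dtype=np.int8)[None, :]])
        return GenotypePanel(self.snps, [*self.individuals, individual], g)

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(self.snps, self.individuals, self.genotypes.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.individuals == other.individuals
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:
        return f"<GenotypePanel {self.n_individuals} individuals x {self.n_snps} SNPs>"


class FrequencyPanel:
    """Population-level derived (or alt) allele counts over observed chromosomes."""

    def __init__(
        self,
        snps: Sequence[SNPRecord],
        populations: Sequence[str],
        derived_count: np.ndarray,
        total_count: np.ndarray,
    ):
        self.snps = list(snps)
        self.populations = list(populations)
        d = np.asarray(derived_count, dtype=np.int64)
        t = np.asarray(total_count, dtype=np.int64)
        shape = (len(self.populations), len(self.snps))
        if d.shape != shape or t.shape != shape:
            raise ValidationError(
                f"count matrices must have shape {shape}; got {d.shape}, {t.shape}"
            )
        if t.size and (t < 0).any():
            raise ValidationError("total counts must be >= 0")
        bad = np.argwhere(d > t) if d.size else np.empty((0, 2), int)
        if len(bad):
            p, m = bad[0]
            raise ValidationError(
                f"derived count exceeds total at population "
                f"{self.populations[p]!r}, SNP {self.snps[m].id!r} "
                f"({d[p, m]} > {t[p, m]})"
            )
        if d.size and (d < 0).any():
            raise ValidationError("derived counts must be >= 0")
        self.derived_count = d
        self.total_count = t

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def population_index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"no population {pop!r} in panel") from None

    def freq(self, population: str | None = None) -> np.ndarray:
        """Derived-allele frequencies; NaN where no chromosomes observed."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.derived_count / self.total_count
        f = np.where(self.total_count > 0, f, np.nan)
        if population is None:
            return f
        return f[self.population_index(population)]

    def counts(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.population_index(population)
        return self.derived_count[i], self.total_count[i]

    def subset_snps(self, index) -> "FrequencyPanel":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        snps = [self.snps[int(i)] for i in idx]
        return FrequencyPanel(
            snps, self.populations, self.derived_count[:, idx], self.total_count[:, idx]
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrequencyPanel):
            return NotImplemented
        return (
            self.snps == other.snps
            and self.populations == other.populations
            and np.array_equal(self.derived_count, other.derived_count)
            and np.array_equal(self.total_count, other.total_count)
        )

    def __repr__(self) -> str:
        return f"<FrequencyPanel {len(self.populations)} populations x {self.n_snps} SNPs>"


@dataclass
class PileupSite:
    """One site of a text pileup: the reads covering it with their qualities."""

    chromosome: str
    position: int
    ref: str
    reads: list[tuple[str, int, int]]  # (base, base quality, mapping quality)
    gap_distance: int = 10**9
    in_repeat: bool = False

    def __post_init__(self):
        for base, bq, mq in self.reads:
            if base not in "ACGTN":
                raise ValidationError(f"pileup base {base!r} not in ACGTN")
            if bq < 0 or mq < 0:
                raise ValidationError("qualities must be >= 0")

    @property
    def depth(self) -> int:
        return len(self.reads)


class BlockPartition:
    """Assignment of SNPs to contiguous genomic blocks for the jackknife.

    Blocks are per-chromosome half-open windows [k*W+1, (k+1)*W+1) in
    1-based coordinates; block ids are consecutive integers over occupied
    windows in SNP order.
    """

    def __init__(self, window: int, block_of: np.ndarray):
        self.window = int(window)
        self.block_of = np.asarray(block_of, dtype=np.int64)

    @property
    def n_blocks(self) -> int:
        return int(self.block_of.max()) + 1 if self.block_of.size else 0

    def __len__(self) -> int:
        return len(self.block_of)


def assign_blocks(snps: Sequence[SNPRecord], window: int = 5_000_000) -> BlockPartition:
    """Partition SNPs (sorted by chromosome, then position) into windows.

    Raises :class:`ValidationError` on unsorted input (positions decreasing
    within a chromosome, or a chromosome seen in two separate runs).
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    block_of = np.empty(len(snps), dtype=np.int64)
    seen_chroms: set[str] = set()
    cur_chrom: str | None = None
    last_pos = -1
    key_to_block: dict[tuple[str, int], int] = {}
    for i, s in enumerate(snps):
        if s.chromosome != cur_chrom:
            if s.chromosome in seen_chroms:
                raise ValidationError(
                    f"SNPs not sorted: chromosome {s.chromosome!r} interleaved"
                )
            seen_chroms.add(s.chromosome)
            cur_chrom = s.chromosome
            last_pos = -1
        if s.position < last_pos:
            raise ValidationError(
                f"SNPs not sorted at {s.chromosome}:{s.position} (after {last_pos})"
            )
        last_pos = s.position
        key = (s.chromosome, (s.position - 1) // window)
        if key not in key_to_block:
            key_to_block[key] = len(key_to_block)
        block_of[i] = key_to_block[key]
    return BlockPartition(window, block_of)
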