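"""Read/variant filtering and pseudo-haploid calling for ancient samples.

Reads below the quality thresholds are removed before calling; pseudo-haploid
genotypes are obtained by sampling one retained read uniformly at random
(over reads, not distinct alleles).  Higher-coverage samples go through the
diploid filter predicate instead, which consumes already-called records with
their quality/depth/gap/repeat annotations — genotype-likelihood calling
itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .datamodel_io.types import PileupSite, SNPRecord
from .errors import ValidationError
from .rng import as_generator

__all__ = [
    "AncientCallSet",
    "DiploidFilterConfig",
    "VariantRecord",
    "filter_reads",
    "call_pseudohaploid",
    "call_sample",
    "filter_diploid_variants",
    "flag_damage",
    "read_call_set",
    "write_call_set",
]

_DAMAGE = {frozenset("CT"): ("C", "T"), frozenset("GA"): ("G", "A")}


@dataclass
class AncientCallSet:
    """Per-site observed alleles for one ancient sample.

    ``alleles[i]`` is a string of observed bases: one character for a
    pseudo-haploid call, two for a diploid call, empty for missing.
    """

    sample_id: str
    chromosomes: list[str]
    positions: np.ndarray
    alleles: list[str]
    ploidy: int = 1
    damage: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n = len(self.positions)
        if not (len(self.chromosomes) == len(self.alleles) == n):
            raise ValidationError("call-set fields have inconsistent lengths")
        for a in self.alleles:
            if a and any(c not in "ACGT" for c in a):
                raise ValidationError(f"observed allele {a!r} not in ACGT")
            if len(a) > self.ploidy:
                raise ValidationError(f"allele string {a!r} exceeds ploidy {self.ploidy}")
        if self.damage is None:
            self.damage = np.zeros(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.positions)

    def site_index(self) -> dict[tuple[str, int], int]:
        idx: dict[tuple[str, int], int] = {}
        for i, (c, p) in enumerate(zip(self.chromosomes, self.positions)):
            key = (c, int(p))
            if key in idx:
                raise ValidationError(f"duplicate call position {c}:{p}")
            idx[key] = i
        return idx


def filter_reads(
    site: PileupSite, min_bq: int = 30, min_mq: int = 30
) -> list[str]:
    """Bases of reads passing both quality thresholds (N always dropped).

    Thresholds are inclusive: the filters remove strictly-below reads.
    """
    return [
        base
        for base, bq, mq in site.reads
        if base != "N" and bq >= min_bq and mq >= min_mq
    ]


def call_pseudohaploid(site: PileupSite, rng, min_bq: int = 30, min_mq: int = 30) -> str:
    """One allele sampled uniformly over retained reads; '' when none remain."""
    rng = as_generator(rng)
    bases = filter_reads(site, min_bq=min_bq, min_mq=min_mq)
    if not bases:
        return ""
    return bases[int(rng.integers(len(bases)))]


def call_sample(
    sites: Iterable[PileupSite],
    sample_id: str,
    seed: int | np.random.Generator,
    min_bq: int = 30,
    min_mq: int = 30,
) -> AncientCallSet:
    """Pseudo-haploid calls for a whole pileup, in input site order."""
    rng = as_generator(seed)
    chroms, positions, alleles = [], [], []
    for site in sites:
        chroms.append(site.chromosome)
        positions.append(site.position)
        alleles.append(call_pseudohaploid(site, rng, min_bq=min_bq, min_mq=min_mq))
    return AncientCallSet(
        sample_id, chroms, np.array(positions, dtype=np.int64), alleles,
        ploidy=1,
        provenance={"min_bq": min_bq, "min_mq": min_mq,
                    "seed": seed if isinstance(seed, int) else None},
    )


@dataclass(frozen=True)
class DiploidFilterConfig:
    """Thresholds for filtering called diploid variant records.

    ``min_qual`` is an exclusive bound (QUAL must be strictly greater);
    depth must lie in [depth_lo, depth_hi].
    """

    min_qual: float = 40.0
    depth_lo: int = 6
    depth_hi: int = 30
    min_gap_distance: int = 5
    exclude_repeats: bool = True

    def __post_init__(self):
        if self.depth_lo > self.depth_hi:
            raise ValidationError("depth_lo must be <= depth_hi")
        if self.depth_lo < 0 or self.min_gap_distance < 0:
            raise ValidationError("filter bounds must be non-negative")


@dataclass(frozen=True)
class VariantRecord:
    qual: float | None
    depth: int | None
    gap_distance: int | None
    in_repeat: bool | None
    genotype: int = 0


def filter_diploid_variants(
    records: Sequence[VariantRecord], cfg: DiploidFilterConfig = DiploidFilterConfig()
) -> list[tuple[bool, list[str]]]:
    """Pure pass/fail predicate per record, with reason codes on failure.

    A record with any missing annotation fails with reason ``missing:<field>``.
    """
    out = []
    for rec in records:
        reasons: list[str] = []
        for name in ("qual", "depth", "gap_distance", "in_repeat"):
            if getattr(rec, name) is None:
                reasons.append(f"missing:{name}")
        if not reasons:
            if not rec.qual > cfg.min_qual:
                reasons.append("low_qual")
            if not (cfg.depth_lo <= rec.depth <= cfg.depth_hi):
                reasons.append("depth")
            if rec.gap_distance < cfg.min_gap_distance:
                reasons.append("near_gap")
            if cfg.exclude_repeats and rec.in_repeat:
                reasons.append("repeat")
        out.append((not reasons, reasons))
    return out


def write_call_set(calls: AncientCallSet, path) -> None:
    """Call-set TSV: '#'-metadata header plus chrom/pos/alleles/damage rows
    ('.' encodes a missing call)."""
    with open(path, "w") as fh:
        fh.write(f"# sample: {calls.sample_id}\n")
        fh.write(f"# ploidy: {calls.ploidy}\n")
        for key, value in sorted(calls.provenance.items()):
            fh.write(f"# {key}: {value}\n")
        fh.write("chrom\tpos\talleles\tdamage\n")
        for i in range(len(calls)):
            a = calls.alleles[i] or "."
            fh.write(
                f"{calls.chromosomes[i]}\t{calls.positions[i]}\t{a}\t"
                f"{int(calls.damage[i])}\n"
            )


def read_call_set(path) -> AncientCallSet:
    sample_id, ploidy = "unknown", 1
    provenance: dict = {}
    chroms: list[str] = []
    positions: list[int] = []
    alleles: list[str] = []
    damage: list[bool] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                key, value = key.strip(), value.strip()
                if key == "sample":
                    sample_id = value
                elif key == "ploidy":
                    ploidy = int(value)
                else:
                    provenance[key] = value
                continue
            if not line or line.startswith("chrom\t"):
                continue
            chrom, pos, a, dmg = line.split("\t")
            chroms.append(chrom)
            positions.append(int(pos))
            alleles.append("" if a == "." else a)
            damage.append(dmg == "1")
    return AncientCallSet(
        sample_id, chroms, np.array(positions, dtype=np.int64), alleles,
        ploidy=ploidy, damage=np.array(damage, dtype=bool), provenance=provenance,
    )


def flag_damage(snp: SNPRecord, observed_allele: str) -> bool:
    """True iff the observed allele is the deamination product at a
    transition site: T at a {C,T} site, A at a {G,A} site."""
    if observed_allele not in snp.allele_pair:
        raise ValidationError(
            f"allele {observed_allele!r} not in pair of SNP {snp.id} "
            f"({snp.ref_allele}/{snp.alt_allele})"
        )
    pair = snp.allele_pair
    if pair in _DAMAGE:
        return observed_allele == _DAMAGE[pair][1]
    return False
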