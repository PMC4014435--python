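"""Merging ancient call sets into modern panels: site intersection,
allele-mismatch handling, damage/transition exclusion, haploidization,
ancestry-tract masking, missingness/ascertainment filters and polarization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ancient_calling import AncientCallSet, flag_damage
from .datamodel_io.bedmask import snp_covered
from .datamodel_io.types import (
    MISSING,
    FrequencyPanel,
    GenotypePanel,
    Individual,
)
from .errors import ValidationError
from .rng import substream

__all__ = [
    "MergeReport",
    "merge_ancient",
    "exclude_damage",
    "haploidize",
    "apply_ancestry_mask",
    "filter_sites",
    "polarize",
    "polarize_frequencies",
]


@dataclass
class MergeReport:
    """Accounting of where ancient call sites went during a merge."""

    sample_id: str
    n_input_sites: int = 0
    n_usable: int = 0
    dropped: dict[str, int] = field(default_factory=lambda: {
        "not_in_panel": 0, "allele_mismatch": 0, "missing_call": 0,
    })

    def check(self) -> None:
        """Accounting identity: reason counts sum to input - usable."""
        if sum(self.dropped.values()) != self.n_input_sites - self.n_usable:
            raise ValidationError("merge report accounting identity violated")


def merge_ancient(
    panel: GenotypePanel, calls: AncientCallSet
) -> tuple[GenotypePanel, MergeReport]:
    """Add an ancient sample to a modern panel, keeping only panel SNPs.

    The ancient genotype at a panel SNP is the count of the alt allele among
    the observed bases; any observed base outside {ref, alt} makes the site
    missing and counts as an allele mismatch.  Calls at positions absent
    from the panel are dropped and counted.
    """
    call_index = calls.site_index()  # raises on duplicate positions
    report = MergeReport(calls.sample_id, n_input_sites=len(calls))
    genotypes = np.full(panel.n_snps, MISSING, dtype=np.int8)
    matched: set[int] = set()
    for m, snp in enumerate(panel.snps):
        key = (snp.chromosome, snp.position)
        ci = call_index.get(key)
        if ci is None:
            continue
        matched.add(ci)
        obs = calls.alleles[ci]
        if not obs:
            report.dropped["missing_call"] += 1
            continue
        if any(a not in snp.allele_pair for a in obs):
            report.dropped["allele_mismatch"] += 1
            continue
        genotypes[m] = sum(1 for a in obs if a == snp.alt_allele)
        report.n_usable += 1
    report.dropped["not_in_panel"] = len(calls) - len(matched)
    report.check()
    ind = Individual(calls.sample_id, calls.sample_id, "ancient", calls.ploidy)
    return panel.with_individual(ind, genotypes), report


def _observed_alleles(panel: GenotypePanel, idx: int, m: int) -> str:
    snp = panel.snps[m]
    g = int(panel.genotypes[idx, m])
    if g == MISSING:
        return ""
    ploidy = panel.individuals[idx].ploidy
    return snp.alt_allele * g + snp.ref_allele * (ploidy - g)


def exclude_damage(
    panel: GenotypePanel, ancient_ids: list[str], mode: str = "single"
) -> GenotypePanel:
    """Drop damage-prone sites.

    mode='single' (exactly one ancient sample): drop transition sites where
    that sample shows the deamination product (T at C/T, A at G/A).
    mode='multi': drop every transition site outright.
    """
    if mode not in ("single", "multi"):
        raise ValidationError(f"unknown damage-exclusion mode {mode!r}")
    if mode == "single":
        if len(ancient_ids) != 1:
            raise ValidationError("mode='single' requires exactly one ancient id")
        idx = panel.individual_index(ancient_ids[0])
        keep = np.ones(panel.n_snps, dtype=bool)
        for m, snp in enumerate(panel.snps):
            if not snp.is_transition:
                continue
            obs = _observed_alleles(panel, idx, m)
            if any(flag_damage(snp, a) for a in obs):
                keep[m] = False
        return panel.subset_snps(keep)
    keep = np.array([not s.is_transition for s in panel.snps])
    return panel.subset_snps(keep)


def haploidize(
    panel: GenotypePanel, individual_ids: list[str], seed: int
) -> GenotypePanel:
    """Replace diploid genotypes by one randomly sampled allele.

    Homozygotes map deterministically (0->0, 2->1); heterozygotes go to 0 or
    1 with probability 1/2 each.  Ploidy annotations become 1.
    """
    new_inds = list(panel.individuals)
    g = panel.genotypes.copy()
    for ind_id in individual_ids:
        rng = substream(seed, f"haploidize:{ind_id}")
        i = panel.individual_index(ind_id)
        ind = panel.individuals[i]
        if ind.ploidy == 1:
            raise ValidationError(f"{ind_id} is already haploid")
        row = g[i]
        het = row == 1
        draws = rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
        row[het] = draws
        row[row == 2] = 1
        new_inds[i] = Individual(ind.id, ind.population, ind.sample_class, 1)
    return GenotypePanel(panel.snps, new_inds, g)


def apply_ancestry_mask(
    panel: GenotypePanel,
    individual_id: str,
    tracts: dict[str, dict[str, list[tuple[int, int]]]],
    target_ancestry: str,
) -> GenotypePanel:
    """Create a virtual individual restricted to homozygous-target tracts.

    ``tracts`` maps ancestry label -> BED-style intervals (0-based
    half-open).  Genotypes outside the target's tracts — or inside another
    ancestry's tracts (a contradictory overlap is an error) — are set to
    missing; the new individual is labeled ``<id>.<ANCESTRY>``.
    """
    if target_ancestry not in tracts:
        raise ValidationError(f"no tracts for target ancestry {target_ancestry!r}")
    i = panel.individual_index(individual_id)
    in_target = snp_covered(panel.snps, tracts[target_ancestry])
    for anc, ivs in tracts.items():
        if anc == target_ancestry:
            continue
        overlap = in_target & snp_covered(panel.snps, ivs)
        if overlap.any():
            m = int(np.flatnonzero(overlap)[0])
            raise ValidationError(
                f"contradictory tracts ({target_ancestry} and {anc}) at "
                f"{panel.snps[m].chromosome}:{panel.snps[m].position}"
            )
    row = panel.genotypes[i].copy()
    row[~in_target] = MISSING
    src = panel.individuals[i]
    virtual = Individual(
        f"{individual_id}.{target_ancestry}", src.population, src.sample_class,
        src.ploidy,
    )
    return panel.with_individual(virtual, row)


def filter_sites(
    panel: GenotypePanel,
    max_missing: float = 0.10,
    required_tags: set[str] | None = None,
) -> GenotypePanel:
    """Drop SNPs with missing fraction strictly above ``max_missing`` among
    modern individuals; optionally keep only SNPs whose ascertainment tags
    intersect ``required_tags``."""
    if required_tags is not None and not required_tags:
        raise ValidationError("required_tags must be None or non-empty")
    modern = np.array([ind.sample_class == "modern" for ind in panel.individuals])
    keep = np.ones(panel.n_snps, dtype=bool)
    if modern.any():
        miss_frac = (panel.genotypes[modern] == MISSING).mean(axis=0)
        keep &= miss_frac <= max_missing
    if required_tags is not None:
        tag_ok = np.array(
            [bool(s.ascertainment_tags & required_tags) for s in panel.snps]
        )
        keep &= tag_ok
    return panel.subset_snps(keep)


def polarize(panel: GenotypePanel) -> tuple[GenotypePanel, int]:
    """Re-orient genotypes so counts are derived-allele counts.

    Sites where the ancestral allele is the alt are flipped (g -> ploidy-g,
    ref/alt swapped); sites with unknown ancestral allele, or an ancestral
    allele outside {ref, alt}, are dropped.  Returns (panel, n_dropped).
    Idempotent: a polarized panel has ancestral == ref everywhere.
    """
    keep = []
    flip = []
    for m, s in enumerate(panel.snps):
        if s.ancestral_allele is None or s.ancestral_allele not in s.allele_pair:
            continue
        keep.append(m)
        flip.append(s.ancestral_allele == s.alt_allele)
    n_dropped = panel.n_snps - len(keep)
    sub = panel.subset_snps(np.array(keep, dtype=int))
    g = sub.genotypes.copy()
    ploidies = sub.ploidies()
    snps = list(sub.snps)
    for j, do_flip in enumerate(flip):
        if not do_flip:
            continue
        col = g[:, j]
        present = col != MISSING
        col[present] = ploidies[present] - col[present]
        s = snps[j]
        snps[j] = s.with_(ref_allele=s.alt_allele, alt_allele=s.ref_allele)
    return GenotypePanel(snps, sub.individuals, g), n_dropped


def polarize_frequencies(panel: FrequencyPanel) -> tuple[FrequencyPanel, int]:
    """Same re-orientation for a frequency panel: flipped sites get
    derived = total - derived."""
    keep = []
    flip = []
    for m, s in enumerate(panel.snps):
        if s.ancestral_allele is None or s.ancestral_allele not in s.allele_pair:
            continue
        keep.append(m)
        flip.append(s.ancestral_allele == s.alt_allele)
    n_dropped = panel.n_snps - len(keep)
    sub = panel.subset_snps(np.array(keep, dtype=int))
    derived = sub.derived_count.copy()
    snps = list(sub.snps)
    for j, do_flip in enumerate(flip):
        if not do_flip:
            continue
        derived[:, j] = sub.total_count[:, j] - derived[:, j]
        s = snps[j]
        snps[j] = s.with_(ref_allele=s.alt_allele, alt_allele=s.ref_allele)
    return FrequencyPanel(snps, sub.populations, derived, sub.total_count), n_dropped
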