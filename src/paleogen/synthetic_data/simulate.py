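"""Forward simulation of allele frequencies, genotype panels, degraded
ancient call sets and read pileups, with ground truth retained.

Drift along an edge follows the Balding-Nichols model: given parent
frequency p and drift F, the child frequency is Beta(p(1-F)/F, (1-p)(1-F)/F)
(a copy when F = 0), which has mean p and variance F p (1-p) and stays in
[0,1] without clipping.  Admixture nodes mix parent frequencies linearly.
Sites are polarized by construction: the ancestral allele is the reference
allele, the derived allele the alternative, and the root draw is the
derived frequency.

Every operation draws from its own labeled substream of the supplied seed
(labels: "frequencies", "panel", "degrade:<sample>", "pileup", "trio"), so
runs are reproducible and stages never perturb each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..ancient_calling import AncientCallSet, flag_damage
from ..datamodel_io.types import (
    MISSING,
    GenotypePanel,
    Individual,
    PileupSite,
    SNPRecord,
)
from ..errors import ValidationError
from ..rng import substream
from .demography import DemographyGraph, SampleSpec

__all__ = [
    "SimFrequencies",
    "SimTruth",
    "simulate_frequencies",
    "sample_panel",
    "degrade_ancient",
    "simulate_pileup",
]

_TRANSVERSION_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
]
_TRANSITION_PAIRS = [("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")]


@dataclass
class SimFrequencies:
    """Per-node derived-allele frequency matrices aligned to a SNP map."""

    snps: list[SNPRecord]
    freqs: dict[str, np.ndarray]
    seed: int | None = None

    def freq(self, node: str) -> np.ndarray:
        return self.freqs[node]


@dataclass
class SimTruth:
    """Ground truth retained alongside degraded outputs."""

    node_freqs: dict[str, np.ndarray]
    true_genotypes: dict[str, np.ndarray] = field(default_factory=dict)
    damage_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int | None = None


def _snp_map(graph: DemographyGraph, m: int, rng: np.random.Generator) -> list[SNPRecord]:
    chroms = list(graph.genome)
    lengths = np.array([graph.genome[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(m, lengths / lengths.sum())
    p_ts = graph.ts_tv_ratio / (graph.ts_tv_ratio + 1.0)
    snps: list[SNPRecord] = []
    i = 0
    for chrom, n in zip(chroms, n_per):
        positions = np.sort(rng.integers(1, graph.genome[chrom] + 1, size=n))
        # bump duplicates so positions are strictly increasing
        for k in range(1, n):
            if positions[k] <= positions[k - 1]:
                positions[k] = positions[k - 1] + 1
        for pos in positions:
            if rng.random() < p_ts:
                ref, alt = _TRANSITION_PAIRS[int(rng.integers(4))]
            else:
                ref, alt = _TRANSVERSION_PAIRS[int(rng.integers(8))]
            snps.append(
                SNPRecord(f"snp{i}", chrom, int(pos), ref, alt, ancestral_allele=ref)
            )
            i += 1
    return snps


def simulate_frequencies(
    graph: DemographyGraph, m: int, seed: int
) -> SimFrequencies:
    """Draw per-node derived-allele frequencies for ``m`` sites.

    Root frequencies are Uniform(lo, hi); children follow Balding-Nichols
    drift or linear admixture, in topological order.
    """
    if m < 1:
        raise ValidationError("site count must be >= 1")
    rng = substream(seed, "frequencies")
    snps = _snp_map(graph, m, rng)
    lo, hi = graph.root_freq
    freqs: dict[str, np.ndarray] = {graph.root: rng.uniform(lo, hi, size=m)}
    drift = {e.child: e for e in graph.drift_edges}
    admix = {e.child: e for e in graph.admixture_edges}
    for node in graph.topological_order():
        if node == graph.root:
            continue
        if node in drift:
            e = drift[node]
            p = freqs[e.parent]
            if e.f == 0.0:
                freqs[node] = p.copy()
            else:
                a = p * (1.0 - e.f) / e.f
                b = (1.0 - p) * (1.0 - e.f) / e.f
                freqs[node] = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
        else:
            e = admix[node]
            freqs[node] = e.alpha * freqs[e.parent1] + (1.0 - e.alpha) * freqs[e.parent2]
    return SimFrequencies(snps, freqs, seed=seed)


def sample_panel(
    sim: SimFrequencies,
    specs: list[SampleSpec] | None = None,
    seed: int = 0,
    graph: DemographyGraph | None = None,
) -> tuple[GenotypePanel, SimTruth]:
    """Draw genotypes: Binomial(ploidy, p) per individual and site.

    Individual ids are ``<population><index>``; sampling specs come either
    from ``specs`` or from ``graph.samples``.
    """
    if specs is None:
        if graph is None:
            raise ValidationError("either specs or graph must be given")
        specs = graph.samples
    rng = substream(seed, "panel")
    individuals: list[Individual] = []
    rows: list[np.ndarray] = []
    m = len(sim.snps)
    truth = SimTruth(node_freqs=sim.freqs, seed=seed)
    for spec in specs:
        if spec.population not in sim.freqs:
            raise ValidationError(f"no simulated frequencies for {spec.population!r}")
        p = sim.freqs[spec.population]
        for j in range(spec.n):
            ind_id = f"{spec.population}{j}"
            individuals.append(
                Individual(ind_id, spec.population, spec.sample_class, spec.ploidy)
            )
            g = rng.binomial(spec.ploidy, p, size=m).astype(np.int8)
            rows.append(g)
            truth.true_genotypes[ind_id] = g.copy()
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, m), dtype=np.int8)
    )
    return GenotypePanel(sim.snps, individuals, genotypes), truth


def _genotype_alleles(g: int, snp: SNPRecord, ploidy: int) -> str:
    if g == MISSING:
        return ""
    n_alt = int(g)
    return snp.alt_allele * n_alt + snp.ref_allele * (ploidy - n_alt)


_DAMAGE_FLIP = {"C": ("T", frozenset("CT")), "G": ("A", frozenset("GA"))}


def degrade_ancient(
    panel: GenotypePanel,
    sample_id: str,
    damage_rate: float,
    missing_rate: float,
    seed: int,
    truth: SimTruth | None = None,
) -> AncientCallSet:
    """Turn one panel individual into an ancient call set with post-mortem
    damage and missingness.

    At {C,T} sites each observed C flips to T with probability
    ``damage_rate`` (and G to A at {G,A} sites); each site is then dropped
    to missing independently with probability ``missing_rate``.
    """
    if not 0.0 <= damage_rate <= 1.0 or not 0.0 <= missing_rate <= 1.0:
        raise ValidationError("damage and missing rates must be in [0,1]")
    rng = substream(seed, f"degrade:{sample_id}")
    i = panel.individual_index(sample_id)
    ind = panel.individuals[i]
    alleles: list[str] = []
    damage_flags = np.zeros(panel.n_snps, dtype=bool)
    for m, snp in enumerate(panel.snps):
        obs = _genotype_alleles(int(panel.genotypes[i, m]), snp, ind.ploidy)
        out = []
        for a in obs:
            if a in _DAMAGE_FLIP:
                product, pair = _DAMAGE_FLIP[a]
                if snp.allele_pair == pair and rng.random() < damage_rate:
                    a = product
            out.append(a)
        call = "".join(out)
        if call and rng.random() < missing_rate:
            call = ""
        alleles.append(call)
        if call:
            damage_flags[m] = any(
                a in snp.allele_pair and flag_damage(snp, a) for a in call
            )
    if truth is not None:
        truth.damage_rate = damage_rate
        truth.missing_rate = missing_rate
    return AncientCallSet(
        sample_id,
        [s.chromosome for s in panel.snps],
        panel.positions,
        alleles,
        ploidy=ind.ploidy,
        damage=damage_flags,
        provenance={"damage_rate": damage_rate, "missing_rate": missing_rate,
                    "seed": seed},
    )


def simulate_pileup(
    snps: list[SNPRecord],
    true_alleles: list[str],
    mean_depth: float,
    base_error: float,
    seed: int,
    base_quality: int = 37,
    map_quality: int = 60,
    low_quality_fraction: float = 0.0,
    low_base_quality: int = 20,
    low_map_quality: int = 20,
) -> list[PileupSite]:
    """Poisson-depth read pileups over true alleles.

    Each read copies one true allele uniformly at random (relevant for
    diploids) and is mutated to a uniform different base with probability
    ``base_error``.  Qualities are a point mass at (37, 60) with an optional
    low-quality fraction.
    """
    if mean_depth < 0:
        raise ValidationError("mean depth must be >= 0")
    if not 0.0 <= base_error < 1.0:
        raise ValidationError("base error must be in [0,1)")
    rng = substream(seed, "pileup")
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    sites: list[PileupSite] = []
    for snp, truth in zip(snps, true_alleles):
        depth = int(rng.poisson(mean_depth)) if truth else 0
        reads = []
        for _ in range(depth):
            base = truth[int(rng.integers(len(truth)))]
            if base_error > 0 and rng.random() < base_error:
                base = others[base][int(rng.integers(3))]
            if low_quality_fraction > 0 and rng.random() < low_quality_fraction:
                bq, mq = low_base_quality, low_map_quality
            else:
                bq, mq = base_quality, map_quality
            reads.append((base, bq, mq))
        sites.append(PileupSite(snp.chromosome, snp.position, snp.ref_allele, reads))
    return sites
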