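"""Ancient–modern divergence time from gene-tree concordance/discordance.

At polarized sites, pair the ancient haploid call with the two gene copies
of one modern genome.  Among sites carrying exactly two derived alleles,
a modern homozygous-derived/ancient-ancestral pattern is *concordant* with
divergence (the modern copies form a clade) and a shared-derived pattern
(ancient + one modern copy) is *discordant* (incomplete lineage sorting).
Under a clean-split coalescent with equal modern and ancestral population
sizes and mutations dropped uniformly on branches, the expected discordant
fraction is

    R(tau) = (2/3) * exp(-tau) / (tau + exp(-tau)),

with tau the split time in units of 2N generations; R(0) = 2/3 (panmixia)
and R decreases to 0 for deep splits.  The estimator inverts the observed
fraction through R and converts to years as T = tau * 2 * Ne * g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .datamodel_io.types import BlockPartition, FrequencyPanel
from .errors import ValidationError
from .fstats import weighted_block_jackknife
from .rng import as_generator

__all__ = [
    "DivergenceCounts",
    "DivergenceEstimate",
    "NE_DEFAULTS",
    "count_topologies",
    "virtual_haploid_pair",
    "expected_discordance",
    "estimate_tau",
    "tau_to_years",
]

#: Continental effective population sizes (point, low, high) used for the
#: year conversion, with a default generation time of 25 years.
NE_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "Africa": (29_300, 23_900, 35_200),
    "Europe": (5_800, 900, 11_500),
    "Asia": (3_000, 300, 6_600),
}

TAU_CEILING = 20.0


@dataclass
class DivergenceCounts:
    """Per-block concordant/discordant topology counts."""

    block_concordant: np.ndarray
    block_discordant: np.ndarray

    def __post_init__(self):
        self.block_concordant = np.asarray(self.block_concordant, dtype=np.int64)
        self.block_discordant = np.asarray(self.block_discordant, dtype=np.int64)
        if self.block_concordant.shape != self.block_discordant.shape:
            raise ValidationError("block count arrays differ in shape")
        if (self.block_concordant < 0).any() or (self.block_discordant < 0).any():
            raise ValidationError("topology counts must be >= 0")

    @property
    def n_concordant(self) -> int:
        return int(self.block_concordant.sum())

    @property
    def n_discordant(self) -> int:
        return int(self.block_discordant.sum())

    @property
    def n_blocks(self) -> int:
        return len(self.block_concordant)


@dataclass
class DivergenceEstimate:
    tau: float
    tau_lo: float
    tau_hi: float
    years: float | None = None
    years_lo: float | None = None
    years_hi: float | None = None
    ne: float | None = None
    generation_time: float | None = None
    n_concordant: int = 0
    n_discordant: int = 0
    flags: list[str] = field(default_factory=list)


def count_topologies(
    ancient: np.ndarray, modern: np.ndarray, blocks: BlockPartition | np.ndarray
) -> DivergenceCounts:
    """Classify aligned, polarized, non-missing sites.

    ``ancient``: haploid derived counts in {0,1}; ``modern``: diploid derived
    counts in {0,1,2}.  (modern=2, ancient=0) is concordant; (modern=1,
    ancient=1) discordant; every other pattern is uninformative.
    """
    anc = np.asarray(ancient)
    mod = np.asarray(modern)
    if anc.shape != mod.shape:
        raise ValidationError("ancient and modern vectors are not aligned")
    if anc.size and not np.isin(anc, (0, 1)).all():
        raise ValidationError("ancient vector must be haploid-coded in {0,1}")
    if mod.size and not np.isin(mod, (0, 1, 2)).all():
        raise ValidationError("modern vector must be diploid-coded in {0,1,2}")
    ids = blocks.block_of if isinstance(blocks, BlockPartition) else np.asarray(blocks)
    if len(ids) != len(anc):
        raise ValidationError("block assignment not aligned to sites")
    g = int(ids.max()) + 1 if len(ids) else 0
    conc = (mod == 2) & (anc == 0)
    disc = (mod == 1) & (anc == 1)
    return DivergenceCounts(
        np.bincount(ids[conc], minlength=g),
        np.bincount(ids[disc], minlength=g),
    )


def virtual_haploid_pair(
    freqs: FrequencyPanel, population: str, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Two virtual haploid genomes for a population: independent Bernoulli
    draws with success probability equal to the derived-allele frequency at
    each site.  Downstream, the pair stands in for one diploid genome."""
    rng = as_generator(seed)
    p = freqs.freq(population)
    h1 = np.where(np.isfinite(p), rng.random(len(p)) < p, 0).astype(np.int8)
    h2 = np.where(np.isfinite(p), rng.random(len(p)) < p, 0).astype(np.int8)
    return h1, h2


def expected_discordance(tau) -> np.ndarray | float:
    """R(tau) = (2/3) e^-tau / (tau + e^-tau); strictly decreasing from 2/3."""
    t = np.asarray(tau, dtype=float)
    if (t < 0).any():
        raise ValidationError("tau must be >= 0")
    r = (2.0 / 3.0) * np.exp(-t) / (t + np.exp(-t))
    return float(r) if np.isscalar(tau) or t.ndim == 0 else r


def _invert_ratio(r: float) -> tuple[float, list[str]]:
    """tau such that R(tau) = r, with boundary/censoring flags."""
    flags: list[str] = []
    if r >= 2.0 / 3.0:
        return 0.0, ["boundary"] if r > 2.0 / 3.0 else []
    if r <= expected_discordance(TAU_CEILING):
        return TAU_CEILING, ["censored"]
    tau = brentq(lambda t: expected_discordance(t) - r, 0.0, TAU_CEILING, xtol=1e-8)
    return float(tau), flags


def estimate_tau(counts: DivergenceCounts) -> DivergenceEstimate:
    """Invert the observed discordance ratio through R, with a weighted
    block-jackknife CI on the ratio transformed through R's inverse."""
    n_c, n_d = counts.n_concordant, counts.n_discordant
    total = n_c + n_d
    if total < 1:
        raise ValidationError("no informative (two-derived-allele) sites")
    ratio = n_d / total
    tau, flags = _invert_ratio(ratio)

    b_tot = (counts.block_concordant + counts.block_discordant).astype(float)
    tau_lo = tau_hi = float("nan")
    if int((b_tot > 0).sum()) >= 2:
        pairs = np.stack([counts.block_discordant.astype(float), b_tot], axis=1)
        se = weighted_block_jackknife(pairs, b_tot)
        r_lo = max(ratio - 1.96 * se, 0.0)
        r_hi = min(ratio + 1.96 * se, 1.0)
        # R is decreasing: high ratio -> low tau
        tau_lo, f_lo = _invert_ratio(r_hi)
        tau_hi, f_hi = _invert_ratio(r_lo)
        for f in f_lo + f_hi:
            tag = f"ci_{f}"
            if tag not in flags:
                flags.append(tag)
    else:
        flags.append("no_ci")
    return DivergenceEstimate(
        tau=tau, tau_lo=tau_lo, tau_hi=tau_hi,
        n_concordant=n_c, n_discordant=n_d, flags=flags,
    )


def tau_to_years(
    estimate: DivergenceEstimate,
    ne: float,
    ne_bounds: tuple[float, float] | None = None,
    generation_time: float = 25.0,
) -> DivergenceEstimate:
    """T = tau * 2 * Ne * g years; the interval is the extreme-product rule
    over the tau CI and the Ne bounds (both uncertainties combined)."""
    if ne <= 0:
        raise ValidationError("Ne must be positive")
    ne_lo, ne_hi = ne_bounds if ne_bounds is not None else (ne, ne)
    if ne_lo > ne_hi or ne_lo <= 0:
        raise ValidationError("invalid Ne bounds")
    estimate.ne = ne
    estimate.generation_time = generation_time
    estimate.years = estimate.tau * 2.0 * ne * generation_time
    t_lo = estimate.tau_lo if np.isfinite(estimate.tau_lo) else estimate.tau
    t_hi = estimate.tau_hi if np.isfinite(estimate.tau_hi) else estimate.tau
    if t_lo > t_hi:
        raise ValidationError("inverted tau bounds")
    products = [
        t * 2.0 * n * generation_time for t in (t_lo, t_hi) for n in (ne_lo, ne_hi)
    ]
    estimate.years_lo = min(products)
    estimate.years_hi = max(products)
    return estimate
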