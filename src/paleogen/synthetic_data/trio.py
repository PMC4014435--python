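"""Monte Carlo oracle for the topology-concordance divergence estimator.

Simulates the three-lineage genealogy (one ancient haploid lineage, the two
gene copies of one modern genome) explicitly, site by site: backwards in
time, the two modern copies may coalesce at rate 1 before the split at
``tau`` (in units of 2N generations); lineages surviving to ``tau`` enter
the ancestral population where every pair coalesces at rate 1.  Mutations
fall uniformly on branches; only mutations on the internal branch — the
branch subtending the first-formed pair ("cherry") — produce a
two-derived-allele site.  A modern-modern cherry yields a concordant site,
an ancient-modern cherry a discordant one.

This simulator is deliberately independent of the closed-form
:func:`paleogen.divergence.expected_discordance`; the two are checked
against each other in the test suite.
"""

from __future__ import annotations

import numpy as np

from ..divergence import DivergenceCounts
from ..errors import ValidationError
from ..rng import substream

__all__ = ["simulate_trio_counts"]


def simulate_trio_counts(
    tau: float,
    n_sites: int,
    seed: int,
    n_blocks: int = 50,
    ancient_age: float = 0.0,
) -> DivergenceCounts:
    """Concordant/discordant counts for ``n_sites`` informative sites.

    ``ancient_age`` (sampling age of the ancient lineage, < tau) only
    shortens the ancient *external* branch, which carries singleton
    mutations; it provably cannot affect the two-derived-allele classes and
    is accepted only so that invariance can be asserted.

    Counts are spread over ``n_blocks`` pseudo-genomic blocks (genealogies
    are assigned to blocks round-robin) for jackknife mechanics.
    """
    if tau < 0:
        raise ValidationError("tau must be >= 0")
    if not 0.0 <= ancient_age <= max(tau, 0.0):
        raise ValidationError("ancient_age must be in [0, tau]")
    if n_sites < 1:
        raise ValidationError("n_sites must be >= 1")
    if n_blocks < 1:
        raise ValidationError("n_blocks must be >= 1")
    rng = substream(seed, "trio")
    g = n_sites  # one genealogy per informative site target

    # time of the modern-modern coalescence attempt in the modern population
    t12 = rng.exponential(size=g)
    internal_exp = rng.exponential(size=g)  # second-coalescence waiting time
    cherry_choice = rng.integers(3, size=g)  # used only when 3 lineages at tau

    early = t12 < tau  # modern pair coalesces before the split
    internal = np.empty(g)
    discordant = np.empty(g, dtype=bool)

    # modern cherry formed at t12; its parent branch spans the rest of the
    # modern epoch plus the ancestral waiting time for the final coalescence
    internal[early] = (tau - t12[early]) + internal_exp[early]
    discordant[early] = False

    # all three lineages reach the ancestral population: the first pair to
    # coalesce is uniform over the three; internal branch is the wait until
    # the final coalescence
    late = ~early
    internal[late] = internal_exp[late]
    discordant[late] = cherry_choice[late] < 2  # 2 of 3 cherries include the ancient

    # mutations fall on the internal branches proportionally to their length
    weights = internal / internal.sum()
    counts = rng.multinomial(n_sites, weights)
    blocks = np.arange(g) % n_blocks
    conc = np.bincount(blocks, weights=counts * ~discordant, minlength=n_blocks)
    disc = np.bincount(blocks, weights=counts * discordant, minlength=n_blocks)
    return DivergenceCounts(conc.astype(np.int64), disc.astype(np.int64))
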