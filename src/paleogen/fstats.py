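"""D-statistics, f3-statistics, derived-allele sharing and the weighted
block jackknife.

All statistics are frequency-based: an individual enters as a 1- or
2-chromosome "population" with within-individual derived frequencies
{0, 1} or {0, 1/2, 1}.  Missing data is handled by sitewise deletion — a
site is used iff every input vector is present there.  Standard errors come
from a weighted delete-one-block jackknife over contiguous genomic blocks
(default 5 Mb windows), with block weights equal to informative-site counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel_io.types import MISSING, BlockPartition, GenotypePanel
from .errors import ValidationError

__all__ = [
    "StatResult",
    "weighted_block_jackknife",
    "d_statistic",
    "f3_statistic",
    "derived_allele_sharing",
]


@dataclass
class StatResult:
    statistic: str
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    block_numerators: np.ndarray = field(repr=False, default=None)
    block_denominators: np.ndarray = field(repr=False, default=None)
    block_weights: np.ndarray = field(repr=False, default=None)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se < 0:
            raise ValidationError("SE must be >= 0")


def _busing_se(theta_hat: float, loo: np.ndarray, weights: np.ndarray) -> float:
    """Weighted delete-one jackknife variance (Busing et al. 1999 form).

    ``loo[j]`` is the estimate with block j removed, ``weights[j]`` the
    information (site count) of block j.  Reduces to the classical
    delete-one jackknife SE when all weights are equal.
    """
    w = np.asarray(weights, dtype=float)
    loo = np.asarray(loo, dtype=float)
    g = len(loo)
    n = w.sum()
    h = n / w
    theta_j = g * theta_hat - ((1.0 - w / n) * loo).sum()
    var = np.sum((h * theta_hat - (h - 1.0) * loo - theta_j) ** 2 / (h - 1.0)) / g
    return float(np.sqrt(max(var, 0.0)))


def weighted_block_jackknife(block_values: np.ndarray, weights: np.ndarray) -> float:
    """Jackknife SE from per-block contributions.

    ``block_values`` is either a (g,) array of per-block statistic values —
    combined as a weights-weighted mean — or a (g, 2) array of per-block
    (numerator, denominator) sums for a ratio statistic.  Blocks with zero
    weight are dropped; fewer than 2 non-empty blocks is an error.
    """
    values = np.asarray(block_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    values, w = values[keep], w[keep]
    if len(w) < 2:
        raise ValidationError("jackknife needs >= 2 non-empty blocks")
    if values.ndim == 2:
        num, den = values[:, 0], values[:, 1]
        theta_hat = num.sum() / den.sum()
        loo = (num.sum() - num) / (den.sum() - den)
    else:
        tot_wv, tot_w = (w * values).sum(), w.sum()
        theta_hat = tot_wv / tot_w
        loo = (tot_wv - w * values) / (tot_w - w)
    return _busing_se(theta_hat, loo, w)


def _block_ids(blocks, n: int) -> np.ndarray:
    if blocks is None:
        raise ValidationError("a block partition is required for jackknife SEs")
    ids = blocks.block_of if isinstance(blocks, BlockPartition) else np.asarray(blocks)
    if len(ids) != n:
        raise ValidationError(f"block assignment length {len(ids)} != {n} sites")
    return np.asarray(ids, dtype=np.int64)


def _as_float(v) -> np.ndarray:
    return np.asarray(v, dtype=float)


def d_statistic(o, x, p1, p2, blocks) -> StatResult:
    """Four-population D from derived-allele frequency vectors.

    D = sum (o-x)(p1-p2) / sum (o+x-2ox)(p1+p2-2*p1*p2) over sites where all
    four frequencies are present.  Negative D means excess derived-allele
    matching of X with P1.  Missing values are NaN; sites contributing zero
    to the denominator are excluded from the informative count.
    """
    o, x, p1, p2 = map(_as_float, (o, x, p1, p2))
    n = len(o)
    if not (len(x) == len(p1) == len(p2) == n):
        raise ValidationError("frequency vectors are not aligned")
    ids = _block_ids(blocks, n)
    present = np.isfinite(o) & np.isfinite(x) & np.isfinite(p1) & np.isfinite(p2)
    num = (o - x) * (p1 - p2)
    den = (o + x - 2 * o * x) * (p1 + p2 - 2 * p1 * p2)
    informative = present & (den != 0)
    if not informative.any() or den[informative].sum() == 0:
        raise ValidationError("no informative sites for D")
    g = int(ids.max()) + 1
    bn = np.bincount(ids[informative], weights=num[informative], minlength=g)
    bd = np.bincount(ids[informative], weights=den[informative], minlength=g)
    bw = np.bincount(ids[informative], minlength=g).astype(float)
    est = float(bn.sum() / bd.sum())
    se = weighted_block_jackknife(np.stack([bn, bd], axis=1), bw)
    z = est / se if se > 0 else float("nan")
    return StatResult(
        "D", est, se, z,
        n_blocks=int((bw > 0).sum()), n_sites=int(informative.sum()),
        block_numerators=bn, block_denominators=bd, block_weights=bw,
    )


def f3_statistic(
    c, a, b, blocks, c_counts=None, corrected: bool = False
) -> StatResult:
    """f3(C; A, B) = mean over sites of (c-a)(c-b), optionally with the
    finite-sample heterozygosity correction c(1-c)/(n-1) subtracted, where
    n is the observed chromosome count in the target C at that site.

    Z <= -3 is the conventional admixture signal.
    """
    c, a, b = map(_as_float, (c, a, b))
    n = len(c)
    if not (len(a) == len(b) == n):
        raise ValidationError("frequency vectors are not aligned")
    ids = _block_ids(blocks, n)
    present = np.isfinite(c) & np.isfinite(a) & np.isfinite(b)
    term = (c - a) * (c - b)
    if corrected:
        if c_counts is None:
            raise ValidationError("corrected f3 requires chromosome counts for C")
        cc = _as_float(c_counts)
        if len(cc) != n:
            raise ValidationError("c_counts not aligned")
        present = present & np.isfinite(cc)
        if (cc[present] < 2).any():
            raise ValidationError("corrected f3 undefined where target has < 2 chromosomes")
        with np.errstate(invalid="ignore", divide="ignore"):
            term = term - c * (1 - c) / (cc - 1)
    if not present.any():
        raise ValidationError("no informative sites for f3")
    g = int(ids.max()) + 1
    bn = np.bincount(ids[present], weights=term[present], minlength=g)
    bw = np.bincount(ids[present], minlength=g).astype(float)
    est = float(bn.sum() / bw.sum())
    se = weighted_block_jackknife(np.stack([bn, bw], axis=1), bw)
    z = est / se if se > 0 else float("nan")
    return StatResult(
        "f3", est, se, z,
        n_blocks=int((bw > 0).sum()), n_sites=int(present.sum()),
        block_numerators=bn, block_denominators=bw, block_weights=bw,
        meta={"corrected": corrected},
    )


def derived_allele_sharing(
    panel: GenotypePanel,
    ancient_id: str,
    denominator: str = "per-individual",
) -> pd.DataFrame:
    """Raw and normalized derived-allele sharing of one ancient sample with
    every modern individual in a derived-polarized panel.

    The ancient's derived site set D is the sites where it carries at least
    one derived allele.  Per modern individual, the raw rate is the fraction
    of its non-missing sites within D at which it carries >= 1 derived
    allele (``denominator='shared'`` instead divides by |D|, counting
    missing as non-shared).  Rates are normalized by the minimum raw rate
    across individuals, so the least-sharing individual scores exactly 1.0.
    """
    if denominator not in ("per-individual", "shared"):
        raise ValidationError(f"unknown denominator convention {denominator!r}")
    ai = panel.individual_index(ancient_id)
    g = panel.genotypes
    derived_sites = g[ai] >= 1
    if not derived_sites.any():
        raise ValidationError(f"{ancient_id} carries no derived alleles")
    rows = []
    for i, ind in enumerate(panel.individuals):
        if i == ai or ind.sample_class != "modern":
            continue
        sub = g[i, derived_sites]
        shared = int((sub >= 1).sum())
        if denominator == "per-individual":
            denom = int((sub != MISSING).sum())
        else:
            denom = int(derived_sites.sum())
        raw = shared / denom if denom else float("nan")
        rows.append({"individual": ind.id, "population": ind.population,
                     "n_sites": denom, "raw": raw})
    df = pd.DataFrame(rows)
    low = df["raw"].min()
    if not np.isfinite(low) or low == 0:
        df["normalized"] = float("nan")
    else:
        df["normalized"] = df["raw"] / low
    return df
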