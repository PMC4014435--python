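"""Binomial-likelihood admixture model.

Unsupervised alternating EM on (Q, P) for modern individuals, and
fixed-P projection of single (typically ancient, missing-heavy) samples by
EM on q alone.  The likelihood is

    L = sum_{i,m observed} [ g_im ln f_im + (c_i - g_im) ln (1 - f_im) ],
    f_im = sum_k q_ik p_km,

with c_i the individual's allele-copy number (1 haploid, 2 diploid).  Both
updates are the classic ratio form of the EM; the log-likelihood is
asserted non-decreasing at every iteration.  No acceleration is applied:
targets are desk-scale panels, and the fixed point is the same.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from ..datamodel_io.types import MISSING, GenotypePanel
from ..errors import ValidationError
from ..rng import substream

__all__ = [
    "AdmixtureModel",
    "ProjectionResult",
    "fit_admixture",
    "project_individual",
    "align_clusters",
    "rmse_subset_eval",
]

EPS = 1e-9
_MONOTONE_SLACK = 1e-8


@dataclass
class AdmixtureModel:
    k: int
    P: np.ndarray  # K x M cluster derived-allele frequencies
    Q: np.ndarray  # N x K membership proportions
    loglik: float
    individual_ids: list[str]
    snp_ids: list[str]
    seed: int | None = None
    replicate: int | None = None
    n_iter: int = 0
    converged: bool = False
    replicate_logliks: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValidationError("Q rows must sum to 1")
        if (self.P < 0).any() or (self.P > 1).any():
            raise ValidationError("P entries must lie in [0,1]")


@dataclass
class ProjectionResult:
    q: np.ndarray
    iterations: int
    loglik: float
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)


def _loglik(g, cmat, mask, f):
    with np.errstate(invalid="ignore"):
        ll = np.where(mask, g * np.log(f) + (cmat - g) * np.log1p(-f), 0.0)
    return float(ll.sum())


def _assert_monotone(trace: list[float]) -> None:
    for prev, cur in zip(trace, trace[1:]):
        if cur < prev - _MONOTONE_SLACK * max(1.0, abs(prev)):
            raise AssertionError(
                f"EM log-likelihood decreased: {prev} -> {cur}"
            )


def _em_full(g, c, mask, P, Q, tol, max_iter):
    cmat = c[:, None] * mask
    c_obs = cmat.sum(axis=1)  # observed allele copies per individual
    trace = []
    converged = False
    for it in range(max_iter):
        F = np.clip(Q @ P, EPS, 1 - EPS)
        trace.append(_loglik(g, cmat, mask, F))
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
            if rel < tol:
                converged = True
                break
        R1 = np.where(mask, g / F, 0.0)
        R0 = np.where(mask, (cmat - g) / (1.0 - F), 0.0)
        Qnew = Q * (R1 @ P.T + R0 @ (1.0 - P.T))
        Qnew /= np.maximum(c_obs, 1)[:, None]
        Qnew = np.clip(Qnew, EPS, None)
        Qnew /= Qnew.sum(axis=1, keepdims=True)
        A = (Q.T @ R1) * P
        B = (Q.T @ R0) * (1.0 - P)
        with np.errstate(invalid="ignore", divide="ignore"):
            Pnew = A / (A + B)
        Pnew = np.where(np.isfinite(Pnew), Pnew, P)
        P = np.clip(Pnew, EPS, 1 - EPS)
        Q = Qnew
    _assert_monotone(trace)
    return P, Q, trace, converged


def fit_admixture(
    panel: GenotypePanel,
    k: int,
    replicates: int = 10,
    tol: float = 1e-6,
    max_iter: int = 2000,
    seed: int = 0,
) -> AdmixtureModel:
    """Fit K clusters to the modern individuals of a panel; the replicate
    with the greatest final log-likelihood is returned."""
    modern_idx = [
        i for i, ind in enumerate(panel.individuals) if ind.sample_class == "modern"
    ]
    if not modern_idx:
        raise ValidationError("panel has no modern individuals to fit")
    n = len(modern_idx)
    if k < 1 or k > n:
        raise ValidationError(f"K must be in [1, {n}]")
    g = panel.genotypes[modern_idx].astype(float)
    mask = g != MISSING
    g = np.where(mask, g, 0.0)
    c = np.array([panel.individuals[i].ploidy for i in modern_idx], dtype=float)

    best = None
    rep_lls: list[float] = []
    for r in range(replicates):
        rng = substream(seed, f"admixture-fit:rep{r}")
        Q0 = rng.dirichlet(np.ones(k), size=n)
        P0 = rng.uniform(0.05, 0.95, size=(k, g.shape[1]))
        P, Q, trace, converged = _em_full(g, c, mask, P0, Q0, tol, max_iter)
        rep_lls.append(trace[-1])
        if best is None or trace[-1] > best[2][-1]:
            best = (P, Q, trace, converged, r)
    P, Q, trace, converged, r = best
    assert trace[-1] >= max(rep_lls)
    return AdmixtureModel(
        k=k, P=P, Q=Q, loglik=trace[-1],
        individual_ids=[panel.individuals[i].id for i in modern_idx],
        snp_ids=[s.id for s in panel.snps],
        seed=seed, replicate=r, n_iter=len(trace), converged=converged,
        replicate_logliks=rep_lls,
    )


def project_individual(
    genotypes: np.ndarray,
    ploidy: int,
    P: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> ProjectionResult:
    """Maximize the likelihood over q with P fixed, using only the sample's
    non-missing sites.  The objective is concave in q, so the deterministic
    uniform start suffices; the projected sample never influences P."""
    g = np.asarray(genotypes, dtype=float)
    if g.shape[-1] != P.shape[1]:
        raise ValidationError("genotype vector not aligned to P's SNP list")
    mask = g != MISSING
    if not mask.any():
        raise ValidationError("no non-missing SNPs overlap the model")
    gm = g[mask]
    Pm = np.clip(P[:, mask], EPS, 1 - EPS)
    k = P.shape[0]
    c = float(ploidy)
    q = np.full(k, 1.0 / k)
    n_obs = c * mask.sum()
    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        f = np.clip(q @ Pm, EPS, 1 - EPS)
        trace.append(float((gm * np.log(f) + (c - gm) * np.log1p(-f)).sum()))
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / max(1.0, abs(trace[-2]))
            if rel < tol:
                converged = True
                break
        r1 = gm / f
        r0 = (c - gm) / (1.0 - f)
        q = q * (Pm @ r1 + (1.0 - Pm) @ r0) / n_obs
        q = np.clip(q, EPS, None)
        q /= q.sum()
    _assert_monotone(trace)
    return ProjectionResult(q, len(trace), trace[-1], converged, trace)


def align_clusters(
    q_ref: np.ndarray, q: np.ndarray, method: str = "greedy"
) -> np.ndarray:
    """Permutation ``perm`` such that ``q[:, perm]`` matches ``q_ref``.

    Similarity is the correlation between membership columns; 'greedy'
    picks the best remaining pair repeatedly, 'hungarian' solves the
    assignment problem exactly.
    """
    k = q_ref.shape[1]
    if q.shape != q_ref.shape:
        raise ValidationError("Q matrices must have identical shapes")
    sim = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            va, vb = q_ref[:, a], q[:, b]
            sa, sb = va.std(), vb.std()
            if sa == 0 or sb == 0:
                sim[a, b] = -np.mean((va - vb) ** 2)  # fallback for flat columns
            else:
                sim[a, b] = np.corrcoef(va, vb)[0, 1]
    perm = np.empty(k, dtype=int)
    if method == "hungarian":
        rows, cols = linear_sum_assignment(-sim)
        perm[rows] = cols
    elif method == "greedy":
        s = sim.copy()
        for _ in range(k):
            a, b = np.unravel_index(np.argmax(s), s.shape)
            perm[a] = b
            s[a, :] = -np.inf
            s[:, b] = -np.inf
    else:
        raise ValidationError(f"unknown alignment method {method!r}")
    return perm


def rmse_subset_eval(
    panel: GenotypePanel,
    models: dict[int, AdmixtureModel],
    subsets: dict[str, np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 2000,
    align: str = "greedy",
) -> pd.DataFrame:
    """Accuracy of membership estimates on reduced SNP subsets.

    Every modern individual is re-projected (P fixed from the full fit)
    using only the subset's SNPs; subset clusters are aligned to the full
    run's and the RMSE of (q_subset - q_full) over the individuals of each
    population and all clusters is reported per (population, K, subset).
    The baseline q_full is the re-projection on the complete SNP set, so a
    subset equal to the full set scores exactly zero.
    """
    rows = []
    for k, model in sorted(models.items()):
        idx = {ind_id: panel.individual_index(ind_id) for ind_id in model.individual_ids}
        full_mask = np.ones(panel.n_snps, dtype=bool)
        q_full = np.empty_like(model.Q)
        for row_i, ind_id in enumerate(model.individual_ids):
            i = idx[ind_id]
            res = project_individual(
                panel.genotypes[i].astype(float), panel.individuals[i].ploidy,
                model.P, tol=tol, max_iter=max_iter,
            )
            q_full[row_i] = res.q
        for name, mask in subsets.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape[0] != panel.n_snps:
                raise ValidationError(f"subset {name!r} not aligned to panel SNPs")
            if not mask.any():
                raise ValidationError(f"subset {name!r} is empty")
            q_sub = np.empty_like(model.Q)
            for row_i, ind_id in enumerate(model.individual_ids):
                i = idx[ind_id]
                g = panel.genotypes[i].astype(float).copy()
                g[~mask] = MISSING
                res = project_individual(
                    g, panel.individuals[i].ploidy, model.P, tol=tol, max_iter=max_iter
                )
                q_sub[row_i] = res.q
            perm = align_clusters(q_full, q_sub, method=align)
            q_sub = q_sub[:, perm]
            pops = np.array(
                [panel.individuals[idx[ind_id]].population
                 for ind_id in model.individual_ids]
            )
            for pop in dict.fromkeys(pops):
                sel = pops == pop
                err = q_sub[sel] - q_full[sel]
                rows.append({
                    "population": pop, "K": k, "subset": name,
                    "n_snps": int(mask.sum()),
                    "rmse": float(np.sqrt(np.mean(err ** 2))),
                })
    return pd.DataFrame(rows)
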