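"""PCA of a fit panel with least-squares projection of held-out samples.

The component space is estimated by singular value decomposition of the
SNP-wise centered (optionally 1/sqrt(p(1-p)) scaled) fit matrix, with
missing fit entries mean-imputed.  Projected samples never influence the
decomposition; each is regressed onto the SNP loadings restricted to its
own non-missing sites.  Genotypes enter on the diploid dosage scale
(2 * g / ploidy) so haploid and diploid samples are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..datamodel_io.types import MISSING, GenotypePanel
from ..errors import ValidationError

__all__ = ["PCAResult", "pca_fit_project"]


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # one row per individual (fit + projected)
    loadings: np.ndarray  # n_components x M SNP loadings
    singular_values: np.ndarray
    means: np.ndarray
    scale: np.ndarray | None
    fit_ids: list[str]
    projected_ids: list[str]


def _dosage(panel: GenotypePanel) -> np.ndarray:
    g = panel.genotypes.astype(float)
    g[panel.genotypes == MISSING] = np.nan
    return g * (2.0 / panel.ploidies()[:, None])


def pca_fit_project(
    panel: GenotypePanel,
    project_ids: list[str] | None = None,
    fit_ids: list[str] | None = None,
    n_components: int | None = None,
    scale: str = "none",
) -> PCAResult:
    """Build the PC space from ``fit_ids`` (default: everyone not projected)
    and project ``project_ids`` onto it.

    ``scale`` is 'none' (centering only, the default) or 'unit-variance'
    (1/sqrt(p(1-p)) SNP weights).  Components with numerically zero
    singular value are discarded, so a fit panel of s samples yields at
    most s-1 components.
    """
    if scale not in ("none", "unit-variance"):
        raise ValidationError(f"unknown scale option {scale!r}")
    project_ids = list(project_ids or [])
    all_ids = [ind.id for ind in panel.individuals]
    if fit_ids is None:
        fit_ids = [i for i in all_ids if i not in set(project_ids)]
    if len(fit_ids) < 2:
        raise ValidationError("need >= 2 fit individuals")
    x = _dosage(panel)
    fit_rows = np.array([panel.individual_index(i) for i in fit_ids])
    xf = x[fit_rows]

    means = np.nanmean(np.where(np.isnan(xf).all(axis=0), 0.0, xf), axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    weights = None
    if scale == "unit-variance":
        p_hat = np.clip(means / 2.0, 0.0, 1.0)
        var = p_hat * (1.0 - p_hat)
        with np.errstate(divide="ignore"):
            weights = np.where(var > 0, 1.0 / np.sqrt(var), 0.0)

    xc = xf - means
    xc = np.where(np.isnan(xc), 0.0, xc)  # mean imputation
    if weights is not None:
        xc = xc * weights
    if not (xc != 0).any():
        raise ValidationError("fit panel has zero polymorphic SNPs")

    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    nontrivial = s > max(s[0], 1.0) * 1e-10
    k = int(nontrivial.sum())
    if n_components is not None:
        k = min(k, n_components)
    u, s, vt = u[:, :k], s[:k], vt[:k]

    rows = {}
    for r, ind_id in enumerate(fit_ids):
        rows[ind_id] = u[r] * s
    for ind_id in project_ids:
        i = panel.individual_index(ind_id)
        xs = x[i] - means
        if weights is not None:
            xs = xs * weights
        nm = np.isfinite(xs)
        if weights is not None:
            nm &= weights > 0
        if not nm.any():
            raise ValidationError(f"{ind_id}: no usable SNPs for projection")
        coords, *_ = np.linalg.lstsq(vt[:, nm].T, xs[nm], rcond=None)
        rows[ind_id] = coords

    coords = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=[f"PC{j + 1}" for j in range(k)])
    coords.index.name = "individual"
    return PCAResult(
        coordinates=coords, loadings=vt, singular_values=s, means=means,
        scale=weights, fit_ids=list(fit_ids), projected_ids=project_ids,
    )
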