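"""Reference-panel principal-component spaces and least-squares projection.

A PC space is built from an external panel: LD pruning, per-variant
standardization, eigendecomposition of the sample covariance, and up to five
iterations of outlier removal (samples beyond 6 SD on any of the top 10 PCs).
Other cohorts are then projected onto the space using the *panel's*
standardization constants and loadings — the projected cohort's own allele
frequencies are never used, which is what distinguishes projection from a
cohort-specific PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .variant_qc import ld_prune

logger = logging.getLogger(__name__)


@dataclass
class PCSpace:
    """Eigenvectors and standardization constants from a reference panel."""

    loadings: np.ndarray          # variants x K, orthonormal columns
    eigenvalues: np.ndarray       # K, non-increasing
    snp_means: np.ndarray
    snp_sds: np.ndarray
    variant_ids: np.ndarray
    alleles: pd.DataFrame         # variant_id, allele1, allele2
    panel_ids: np.ndarray
    label: str = "panel"

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def __post_init__(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.k), atol=1e-8):
            raise ValueError("loadings columns are not orthonormal")
        if np.any(np.diff(self.eigenvalues) > 1e-10) or np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-increasing and non-negative")
        if np.any(self.snp_sds <= 0):
            raise ValueError("snp_sds must be positive for every retained variant")


@dataclass
class PCCoordinates:
    """PC scores for one cohort in one space."""

    sample_ids: np.ndarray
    scores: np.ndarray            # samples x K
    source_space: str

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        df = pd.DataFrame(self.scores, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def matrix(self, k: int | None = None) -> np.ndarray:
        return self.scores if k is None else self.scores[:, :k]


def _orient_signs(loadings: np.ndarray) -> np.ndarray:
    """Fix eigenvector sign: largest-|entry| of each column made positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs


def build_pc_space(
    panel: GenotypeMatrix,
    k: int = 20,
    n_outlier_iters: int = 5,
    outlier_sd: float = 6.0,
    top_pcs_checked: int = 10,
    prune: bool = True,
    shrinkage: bool = False,
    label: str = "panel",
) -> PCSpace:
    """Eigendecompose a reference panel with iterative outlier removal.

    Outliers (> ``outlier_sd`` standard deviations along any of the first
    ``top_pcs_checked`` PCs) are removed for at most ``n_outlier_iters``
    rounds, stopping early when a round removes nobody.  Standardization
    constants come from the final, post-removal panel.
    """
    if shrinkage:
        raise NotImplementedError(
            "shrinkage-corrected projection is not implemented (config stub)"
        )
    if prune:
        keep = ld_prune(panel)
        panel = panel.take_variants(keep)

    sample_mask = np.ones(panel.n_samples, dtype=bool)
    variant_mask = np.ones(panel.n_variants, dtype=bool)
    result = None
    for iteration in range(max(1, n_outlier_iters)):
        d = panel.dosages[sample_mask][:, variant_mask]
        means = np.nanmean(d, axis=0)
        sds = np.nanstd(d, axis=0, ddof=0)
        poly = sds > 0
        if not poly.all():
            vm_idx = np.flatnonzero(variant_mask)
            variant_mask[vm_idx[~poly]] = False
            d = d[:, poly]
            means, sds = means[poly], sds[poly]
        n = d.shape[0]
        k_eff = min(k, n - 1, d.shape[1])
        if k_eff < k:
            logger.warning("reducing K from %d to %d (panel size %d)", k, k_eff, n)
        z = np.nan_to_num((d - means) / sds, nan=0.0)
        # SVD of Z/sqrt(n): eigenvalues of the sample covariance Z'Z/n.
        # Large panels with few requested components use a randomized
        # truncated SVD (deterministic under the fixed random_state).
        if z.size > 5_000_000 and k_eff < min(z.shape) / 4:
            from sklearn.utils.extmath import randomized_svd

            u, s, vt = randomized_svd(
                z, n_components=k_eff, n_iter=7, random_state=0
            )
        else:
            u, s, vt = np.linalg.svd(z, full_matrices=False)
        loadings = _orient_signs(vt[:k_eff].T)
        eigenvalues = (s[:k_eff] ** 2) / n
        scores = z @ loadings
        result = (loadings, eigenvalues, means, sds)

        top = scores[:, :min(top_pcs_checked, k_eff)]
        sd_top = top.std(axis=0, ddof=0)
        sd_top = np.where(sd_top > 0, sd_top, 1.0)
        outlier = (np.abs(top - top.mean(axis=0)) / sd_top > outlier_sd).any(axis=1)
        if not outlier.any():
            break
        logger.info(
            "PC outlier iteration %d: removing %d samples", iteration + 1,
            int(outlier.sum()),
        )
        sm_idx = np.flatnonzero(sample_mask)
        sample_mask[sm_idx[outlier]] = False

    loadings, eigenvalues, means, sds = result
    v = panel.variants.loc[variant_mask, ["variant_id", "allele1", "allele2"]]
    return PCSpace(
        loadings=loadings,
        eigenvalues=eigenvalues,
        snp_means=means,
        snp_sds=sds,
        variant_ids=v["variant_id"].to_numpy(),
        alleles=v.reset_index(drop=True),
        panel_ids=panel.sample_ids[sample_mask],
        label=label,
    )


def project_samples(space: PCSpace, cohort: GenotypeMatrix) -> PCCoordinates:
    """Project a cohort onto a panel-derived PC space.

    Because the loadings are orthonormal, multiplying the panel-standardized
    dosages by them is the least-squares solution for the coordinates.
    Dosages are flipped (``2 - g``) for variants whose alleles are swapped
    relative to the panel; inconsistent alleles raise.
    """
    idx = cohort.variant_index(space.variant_ids)
    cv = cohort.variants.iloc[idx]
    flip = np.zeros(len(idx), dtype=bool)
    for row, (pa1, pa2, ca1, ca2, vid) in enumerate(
        zip(space.alleles["allele1"], space.alleles["allele2"],
            cv["allele1"], cv["allele2"], cv["variant_id"])
    ):
        if (ca1, ca2) == (pa1, pa2):
            continue
        if (ca1, ca2) == (pa2, pa1):
            flip[row] = True
        else:
            raise ValueError(
                f"allele mismatch for variant {vid!r}: panel {pa1}/{pa2}, "
                f"cohort {ca1}/{ca2}"
            )
    d = cohort.dosages[:, idx]  # fancy indexing yields a fresh writable array
    if flip.any():
        d[:, flip] = 2.0 - d[:, flip]
    d -= space.snp_means
    d /= space.snp_sds
    z = np.nan_to_num(d, nan=0.0, copy=False)
    return PCCoordinates(
        sample_ids=cohort.sample_ids.copy(),
        scores=z @ space.loadings,
        source_space=space.label,
    )


def make_pc_sets(
    cohorts: dict[str, GenotypeMatrix],
    panels: dict[str, GenotypeMatrix],
    k: int = 20,
) -> tuple[dict[str, PCSpace], dict[str, dict[str, PCCoordinates]]]:
    """Build one PC space per panel and project every cohort onto each.

    Returns ``(spaces, coords)`` with ``coords[cohort][panel_label]``; a
    panel sharing samples with a projected cohort is an error (projection
    requires independence between panel and projected samples).
    """
    spaces = {
        name: build_pc_space(panel, k=k, label=name)
        for name, panel in panels.items()
    }
    coords: dict[str, dict[str, PCCoordinates]] = {}
    for cname, cohort in cohorts.items():
        cohort_set = set(cohort.sample_ids)
        coords[cname] = {}
        for pname, space in spaces.items():
            overlap = cohort_set & set(space.panel_ids)
            if overlap:
                raise ValueError(
                    f"cohort {cname!r} overlaps panel {pname!r}: "
                    f"{sorted(overlap)[:5]}"
                )
            coords[cname][pname] = project_samples(space, cohort)
    return spaces, coords
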