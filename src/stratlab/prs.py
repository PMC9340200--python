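"""Polygenic scores: greedy LD clumping, thresholding, best-threshold search.

Clumping keeps the most significant variant of each LD region: variants are
visited in ascending p-value order; each index variant claims (removes) all
unclaimed variants within +-window_kb on its chromosome whose squared
correlation with it exceeds r2_max.  Scores are sums of effect-allele dosages
weighted by GWAS betas, standardized in the target set.  Among the eight
p-value cut-offs the one maximizing the validation-model R-squared wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .gwas import SummaryStats
from .pc_space import PCCoordinates

logger = logging.getLogger(__name__)

#: the p-value cut-off grid searched during threshold selection
THRESHOLD_GRID = (0.00005, 0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.5)


@dataclass
class ClumpSpec:
    r2_max: float = 0.05
    p_max: float = 1.0
    window_kb: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.r2_max < 1):
            raise ValueError("r2_max must be in (0, 1)")
        if self.p_max <= 0 or self.window_kb <= 0:
            raise ValueError("p_max and window_kb must be positive")


@dataclass
class PRSProfile:
    """Standardized per-sample score and the recipe that produced it."""

    sample_ids: np.ndarray
    score: np.ndarray                     # standardized: mean 0, sd 1
    chosen_threshold: float
    variants: pd.DataFrame                # variant_id, effect_allele, beta, p
    source_label: str = "PRS"
    objective_r2: float = float("nan")

    @property
    def n_snps_included(self) -> int:
        return len(self.variants)

    def to_files(self, prefix) -> None:
        df = pd.DataFrame({"sample_id": self.sample_ids, "prs_standardized": self.score})
        df.to_csv(f"{prefix}.prs.tsv", sep="\t", index=False, float_format="%.10g")
        self.variants.to_csv(
            f"{prefix}.variants.tsv", sep="\t", index=False, float_format="%.10g"
        )
        meta = {
            "chosen_threshold": self.chosen_threshold,
            "n_snps": self.n_snps_included,
            "source_label": self.source_label,
            "objective_r2": self.objective_r2,
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def unit_norm_dosages(ld_reference: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed, centered, unit-norm dosage columns (for fast r²).

    Precompute once when clumping several summary-statistics sets against
    the same LD reference.
    """
    z = ld_reference.standardized()
    norms = np.sqrt(np.einsum("ij,ij->j", z, z))
    return z / np.where(norms > 0, norms, 1.0)


def clump(
    stats: SummaryStats,
    ld_reference: GenotypeMatrix,
    spec: ClumpSpec | None = None,
    z: np.ndarray | None = None,
) -> list[str]:
    """Greedy p-value-ordered clumping against an LD reference.

    Returns index-variant ids in selection order.  Ties in p are broken by
    (chrom, pos) ascending; variants absent from the LD reference are
    excluded (count logged).  ``z`` optionally supplies the output of
    :func:`unit_norm_dosages` to avoid recomputation across calls.
    """
    spec = spec or ClumpSpec()
    t = stats.table.dropna(subset=["p"])
    t = t[t["p"] <= spec.p_max]
    ref_ids = set(ld_reference.variants["variant_id"])
    absent = (~t["variant_id"].isin(ref_ids)).sum()
    if absent:
        logger.info("clump: %d variants absent from LD reference, excluded", absent)
        t = t[t["variant_id"].isin(ref_ids)]
    if t.empty:
        return []
    t = t.sort_values(["p", "chrom", "pos"], kind="mergesort")

    idx = ld_reference.variant_index(t["variant_id"].to_list())
    if z is None:
        z = unit_norm_dosages(ld_reference)
    pos = t["pos"].to_numpy(dtype=float)
    chrom = t["chrom"].to_numpy()
    window_bp = spec.window_kb * 1000.0

    # Precompute the banded high-r² adjacency per chromosome with blocked
    # matrix products, then run the p-ordered greedy on that (sparse) graph.
    adjacency: dict[int, list[int]] = {}
    block = 256
    for c in pd.unique(chrom):
        rows = np.flatnonzero(chrom == c)
        order_pos = rows[np.argsort(pos[rows], kind="mergesort")]
        cpos = pos[order_pos]
        zc = np.ascontiguousarray(z[:, idx[order_pos]])
        mloc = len(order_pos)
        for start in range(0, mloc, block):
            stop = min(start + block, mloc)
            lo = np.searchsorted(cpos, cpos[start] - window_bp, side="left")
            hi = np.searchsorted(cpos, cpos[stop - 1] + window_bp, side="right")
            r = zc[:, start:stop].T @ zc[:, lo:hi]
            in_window = (
                np.abs(cpos[start:stop, None] - cpos[None, lo:hi]) <= window_bp
            )
            gi, gj = np.nonzero((r**2 > spec.r2_max) & in_window)
            for a, b in zip(order_pos[start:stop][gi], order_pos[lo:hi][gj]):
                if a != b:
                    adjacency.setdefault(a, []).append(b)

    claimed = np.zeros(len(t), dtype=bool)
    selected: list[str] = []
    vids = t["variant_id"].to_numpy()
    for i in range(len(t)):
        if claimed[i]:
            continue
        claimed[i] = True
        selected.append(vids[i])
        for b in adjacency.get(i, ()):
            claimed[b] = True
    return selected


def score(
    geno: GenotypeMatrix,
    stats: SummaryStats,
    variants: list[str],
    threshold: float,
) -> np.ndarray:
    """Raw PRS: sum of effect-allele dosages weighted by beta, p <= threshold.

    Missing dosages are replaced by the variant's mean dosage in the cohort.
    Dosages are flipped (2 - g) when the cohort's alleles are swapped relative
    to the summary statistics; inconsistent alleles raise.
    """
    t = stats.table.set_index("variant_id")
    use = [v for v in variants if t.loc[v, "p"] <= threshold]
    if not use:
        return np.zeros(geno.n_samples)
    d = _aligned_dosages(geno, t, use)
    betas = t.loc[use, "beta"].to_numpy(dtype=float)
    return d @ betas


def _aligned_dosages(geno: GenotypeMatrix, t: pd.DataFrame, use: list[str]) -> np.ndarray:
    """Effect-allele dosages for the listed variants, mean-imputed."""
    idx = geno.variant_index(use)
    gv = geno.variants.iloc[idx]
    d = geno.dosages[:, idx]  # fancy indexing yields a fresh writable array
    ea = t.loc[use, "effect_allele"].to_numpy(dtype=object)
    oa = t.loc[use, "other_allele"].to_numpy(dtype=object)
    ca1 = gv["allele1"].to_numpy(dtype=object)
    ca2 = gv["allele2"].to_numpy(dtype=object)
    same = (ca1 == ea) & (ca2 == oa)
    swapped = (ca1 == oa) & (ca2 == ea)
    bad = ~(same | swapped)
    if bad.any():
        j = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"allele mismatch for {use[j]!r}: stats {ea[j]}/{oa[j]}, "
            f"cohort {ca1[j]}/{ca2[j]}"
        )
    if swapped.any():
        d[:, swapped] = 2.0 - d[:, swapped]
    nan_mask = np.isnan(d)
    if nan_mask.any():
        col_mean = np.nanmean(d, axis=0)
        nan_r, nan_c = np.nonzero(nan_mask)
        d[nan_r, nan_c] = col_mean[nan_c]
    return d


def standardize(raw: np.ndarray) -> np.ndarray:
    sd = raw.std(ddof=0)
    if sd == 0:
        return raw - raw.mean()
    return (raw - raw.mean()) / sd


def select_best_threshold(
    geno: GenotypeMatrix,
    trait: np.ndarray,
    samples: pd.DataFrame,
    stats: SummaryStats,
    clumped: list[str],
    pc_covariates: PCCoordinates | None = None,
    grid: tuple[float, ...] = THRESHOLD_GRID,
    objective: str = "total",
    source_label: str | None = None,
) -> PRSProfile:
    """Pick the p-value cut-off whose PRS maximizes the validation R-squared.

    For every threshold the standardized score enters an OLS of the trait on
    [1, PRS, age, sex, batch, (PCs)]; ``objective='total'`` ranks thresholds
    by that model's R² (the scoring tool's default), ``objective='prs_only'``
    by the R² of trait ~ PRS alone.  Ties go to the smaller threshold.
    """
    from .gwas import _covariate_design

    trait = np.asarray(trait, dtype=float)
    design, _ = _covariate_design(samples, pc_covariates)
    t = stats.table.set_index("variant_id")
    # align dosages to effect alleles once for the full clumped list
    clumped = list(clumped)
    d_all = _aligned_dosages(geno, t, clumped) if clumped else None
    p_all = t.loc[clumped, "p"].to_numpy(dtype=float) if clumped else None
    b_all = t.loc[clumped, "beta"].to_numpy(dtype=float) if clumped else None
    best = None
    for thr in sorted(grid):
        if not clumped:
            break
        mask = p_all <= thr
        use = [v for v, m in zip(clumped, mask) if m]
        if not use:
            logger.info("threshold %g admits no variants, skipped", thr)
            continue
        raw = d_all[:, mask] @ b_all[mask]
        std = standardize(raw)
        if objective == "total":
            x = np.column_stack([design, std])
        elif objective == "prs_only":
            x = np.column_stack([np.ones(len(std)), std])
        else:
            raise ValueError(f"unknown objective {objective!r}")
        beta, *_ = np.linalg.lstsq(x, trait, rcond=None)
        resid = trait - x @ beta
        tss = ((trait - trait.mean()) ** 2).sum()
        r2 = 1.0 - (resid @ resid) / tss if tss > 0 else 0.0
        if best is None or r2 > best[0] + 1e-15:
            best = (r2, thr, std, use)
    if best is None:
        raise ValueError("no threshold admitted any variants")
    r2, thr, std, use = best
    variants = pd.DataFrame(
        {
            "variant_id": use,
            "effect_allele": t.loc[use, "effect_allele"].to_numpy(),
            "beta": t.loc[use, "beta"].to_numpy(),
            "p": t.loc[use, "p"].to_numpy(),
        }
    )
    return PRSProfile(
        sample_ids=geno.sample_ids.copy(),
        score=std,
        chosen_threshold=thr,
        variants=variants,
        source_label=source_label or f"PRS_{stats.pc_set_label}",
        objective_r2=float(r2),
    )
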