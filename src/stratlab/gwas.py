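"""Per-variant additive linear-model association with PC adjustment.

Each variant is tested with ordinary least squares of the trait on
``[1, age, sex, batch, dosage, PC1..PC20]``; the reported effect is the
dosage coefficient.  For complete dosages the per-variant loop is computed
as one residualization-then-batched-regression pass (project trait and all
dosages off the shared covariates once), which is algebraically identical to
per-variant OLS; variants with missing calls fall back to the per-variant
complete-case fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import GenotypeMatrix
from .pc_space import PCCoordinates

logger = logging.getLogger(__name__)

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = 0.4549364231195724


@dataclass
class SummaryStats:
    """GWAS output: per-variant effects plus the run's PC label and lambda."""

    table: pd.DataFrame
    pc_set_label: str = "none"
    lambda_gc: float = float("nan")
    covariate_betas: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# pc_set_label: {self.pc_set_label}\n")
            fh.write(f"# lambda_gc: {self.lambda_gc:.6f}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SummaryStats":
        label, lam = "none", float("nan")
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].partition(":")
                if key.strip() == "pc_set_label":
                    label = val.strip()
                elif key.strip() == "lambda_gc":
                    lam = float(val)
        table = pd.read_csv(path, sep="\t", comment="#")
        return cls(table=table, pc_set_label=label, lambda_gc=lam)


def _covariate_design(samples: pd.DataFrame, pcs: PCCoordinates | np.ndarray | None,
                      n_pcs: int = 20) -> tuple[np.ndarray, list[str]]:
    """Shared covariate matrix [1, age, sex, batch dummies, PCs]."""
    n = len(samples)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for c in ("age", "sex"):
        if c in samples.columns:
            cols.append(samples[c].to_numpy(dtype=float))
            names.append(c)
    if "batch" in samples.columns:
        levels = sorted(pd.unique(samples["batch"].astype(str)))
        for lev in levels[1:]:  # reference level = lexicographically first
            cols.append((samples["batch"].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"batch[{lev}]")
    if pcs is not None:
        mat = pcs.matrix() if isinstance(pcs, PCCoordinates) else np.asarray(pcs)
        use = min(n_pcs, mat.shape[1])
        for j in range(use):
            cols.append(mat[:, j])
            names.append(f"PC{j + 1}")
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name a collinear pair for the error message
        corr = np.corrcoef(design[:, 1:].T) if design.shape[1] > 2 else None
        pair = ""
        if corr is not None:
            cc = np.abs(corr - np.eye(len(corr)))
            i, j = np.unravel_index(np.argmax(cc), cc.shape)
            pair = f" (e.g. {names[i + 1]!r} vs {names[j + 1]!r}, |r|={cc[i, j]:.4f})"
        raise ValueError(f"collinear covariates: rank {rank} < {design.shape[1]}{pair}")
    return design, names


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    # QR projection: x has full column rank (checked upstream); much faster
    # than SVD-based lstsq when y has many columns
    q, _ = np.linalg.qr(x)
    return y - q @ (q.T @ y)


def run_gwas(
    geno: GenotypeMatrix,
    trait: np.ndarray,
    samples: pd.DataFrame,
    pcs: PCCoordinates | None = None,
    n_pcs: int = 20,
    pc_set_label: str | None = None,
) -> SummaryStats:
    """Genome-wide per-variant OLS association.

    ``pcs=None`` is the uncorrected control GWAS.  Samples with a missing
    dosage at a variant are excluded from that variant's fit; variants
    monomorphic in complete cases get an NA row with a reason code.
    """
    trait = np.asarray(trait, dtype=float)
    if len(trait) != geno.n_samples:
        raise ValueError("trait length does not match genotype matrix")
    if pcs is not None and not np.array_equal(pcs.sample_ids, geno.sample_ids):
        raise ValueError("PC coordinates are not aligned with the cohort samples")
    label = pc_set_label or (pcs.source_space if pcs is not None else "none")

    c, _ = _covariate_design(samples, pcs, n_pcs=n_pcs)
    n, p = c.shape
    m = geno.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    n_used = np.full(m, 0, dtype=int)
    reason = np.full(m, "", dtype=object)

    d = geno.dosages
    has_missing = np.isnan(d).any(axis=0)
    complete_cols = np.flatnonzero(~has_missing)

    if complete_cols.size:
        # Frisch-Waugh: one shared projection off the covariates
        q, _ = np.linalg.qr(c)
        y_res = trait - q @ (q.T @ trait)
        g_res = d[:, complete_cols]  # fancy indexing copies; residualize in place
        g_res -= q @ (q.T @ g_res)
        gg = np.einsum("ij,ij->j", g_res, g_res)
        poly = gg > 1e-12
        df = n - p - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            b = (g_res.T @ y_res) / gg
            rss = y_res @ y_res - b**2 * gg
            s = np.sqrt(np.maximum(rss, 0.0) / df / gg)
        cols = complete_cols[poly]
        beta[cols] = b[poly]
        se[cols] = s[poly]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat[cols] = beta[cols] / se[cols]
        pval[cols] = 2.0 * sps.t.sf(np.abs(tstat[cols]), df)
        n_used[complete_cols] = n
        reason[complete_cols[~poly]] = "monomorphic"

    for j in np.flatnonzero(has_missing):
        ok = ~np.isnan(d[:, j])
        gj = d[ok, j]
        if gj.size <= p + 1 or gj.std() == 0:
            reason[j] = "monomorphic" if gj.size else "all_missing"
            continue
        x = np.column_stack([c[ok], gj])
        bj, *_ = np.linalg.lstsq(x, trait[ok], rcond=None)
        resid = trait[ok] - x @ bj
        dfj = gj.size - x.shape[1]
        xtx_inv = np.linalg.inv(x.T @ x)
        s2 = resid @ resid / dfj
        beta[j] = bj[-1]
        se[j] = np.sqrt(s2 * xtx_inv[-1, -1])
        tstat[j] = beta[j] / se[j]
        pval[j] = 2.0 * sps.t.sf(abs(tstat[j]), dfj)
        n_used[j] = int(gj.size)

    table = pd.DataFrame(
        {
            "variant_id": geno.variants["variant_id"],
            "chrom": geno.variants["chrom"],
            "pos": geno.variants["pos"],
            "effect_allele": geno.variants["allele1"],
            "other_allele": geno.variants["allele2"],
            "beta": beta,
            "se": se,
            "t": tstat,
            "p": pval,
            "n_used": n_used,
            "reason": reason,
        }
    )
    valid_p = table["p"].dropna().to_numpy()
    lam = genomic_inflation(valid_p) if valid_p.size else float("nan")
    logger.info("GWAS [%s]: %d variants, lambda=%.4f", label, m, lam)
    return SummaryStats(table=table, pc_set_label=label, lambda_gc=lam)


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-square / null median.

    The two-sided p-values are transformed back to 1-df chi-square quantiles;
    lambda is their median divided by 0.4549364 (the 1-df chi-square median).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        warnings.warn(f"only {p.size} p-values; lambda estimate is unstable")
    if (p <= 0).any():
        warnings.warn("p-values of 0 clamped to smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    chi2 = sps.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)
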