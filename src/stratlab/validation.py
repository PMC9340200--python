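"""Validation-model comparison: BIC, delta-BIC, total and added R-squared.

Each cell of the 5x5 grid fits trait ~ 1 + PRS + age + sex + batch (+ 20 PCs)
by OLS.  BIC uses the Gaussian likelihood at the MLE with k counting every
regression coefficient plus the residual variance; delta-BIC is taken against
the grid's best (minimum-BIC) cell and interpreted with the usual
rules-of-thumb bins (<6 weak, 6-10 strong, >10 very strong).  Added R² is the
model's total R² minus that of the matched fit without the PRS term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gwas import _covariate_design
from .pc_space import PCCoordinates
from .prs import PRSProfile

PRS_LABELS = ("PRS_0", "PRS_cohort", "PRS_allref", "PRS_EURlike", "PRS_NEURlike")
PC_LABELS = ("PC_0", "PC_cohort", "PC_allref", "PC_EURlike", "PC_NEURlike")


@dataclass
class ValidationFit:
    prs_label: str
    pc_label: str
    log_likelihood: float
    k: int
    n: int
    bic: float
    total_r2: float
    added_r2_prs: float
    prs_beta: float
    prs_p: float


@dataclass
class GridResult:
    """All 25 fits plus the delta-BIC table and the winning cell."""

    fits: pd.DataFrame            # long format, one row per cell
    bic: pd.DataFrame             # 5x5, rows = PRS, cols = PC set
    delta_bic: pd.DataFrame
    total_r2: pd.DataFrame
    added_r2: pd.DataFrame
    best_cell: tuple[str, str]


def _gaussian_bic(loglik: float, k: int, n: int) -> float:
    return -2.0 * loglik + k * np.log(n)


def fit_validation_model(
    trait: np.ndarray,
    prs: PRSProfile | np.ndarray | None,
    samples: pd.DataFrame,
    pcs: PCCoordinates | None = None,
    prs_label: str = "PRS",
    pc_label: str = "PC_0",
    n_pcs: int = 20,
) -> ValidationFit:
    """One validation OLS fit with its BIC and added R² by the PRS.

    ``prs=None`` fits the matched no-PRS model (used internally for added
    R²).  ``k`` counts all coefficients plus the residual variance.
    """
    trait = np.asarray(trait, dtype=float)
    design, names = _covariate_design(samples, pcs, n_pcs=n_pcs)

    def _fit(x: np.ndarray):
        model = sm.OLS(trait, x)
        res = model.fit()
        return res

    base = _fit(design)
    if prs is None:
        score = None
    else:
        score = prs.score if isinstance(prs, PRSProfile) else np.asarray(prs, float)
    if score is not None:
        x_full = np.column_stack([design, score])
        full = _fit(x_full)
        prs_beta = float(full.params[-1])
        prs_p = float(full.pvalues[-1])
        total_r2 = float(full.rsquared)
        added = total_r2 - float(base.rsquared)
        loglik = float(full.llf)
        k = x_full.shape[1] + 1  # + residual variance
    else:
        full = base
        prs_beta, prs_p = float("nan"), float("nan")
        total_r2 = float(base.rsquared)
        added = 0.0
        loglik = float(base.llf)
        k = design.shape[1] + 1
    n = len(trait)
    if added < -1e-12:
        raise AssertionError("added R2 cannot be negative beyond rounding")
    return ValidationFit(
        prs_label=prs_label,
        pc_label=pc_label,
        log_likelihood=loglik,
        k=k,
        n=n,
        bic=_gaussian_bic(loglik, k, n),
        total_r2=total_r2,
        added_r2_prs=max(added, 0.0),
        prs_beta=prs_beta,
        prs_p=prs_p,
    )


def run_grid(
    trait: np.ndarray,
    prs_profiles: dict[str, PRSProfile],
    samples: pd.DataFrame,
    pc_sets: dict[str, PCCoordinates],
    n_pcs: int = 20,
) -> GridResult:
    """Fit the full PRS x PC-adjustment grid and rank cells by BIC.

    ``prs_profiles`` maps row labels to profiles; ``pc_sets`` maps column
    labels to coordinates, with the control column ``PC_0`` (no PCs) added
    automatically if absent.
    """
    columns: dict[str, PCCoordinates | None] = {"PC_0": None}
    columns.update(pc_sets)
    rows = list(prs_profiles)
    fits: list[ValidationFit] = []
    for r in rows:
        for c, pcs in columns.items():
            fits.append(
                fit_validation_model(
                    trait, prs_profiles[r], samples, pcs,
                    prs_label=r, pc_label=c, n_pcs=n_pcs,
                )
            )
    long = pd.DataFrame([vars(f) for f in fits])
    col_order = list(columns)
    bic = long.pivot(index="prs_label", columns="pc_label", values="bic")
    bic = bic.loc[rows, col_order]
    delta = bic - bic.min().min()
    total = long.pivot(index="prs_label", columns="pc_label", values="total_r2")
    added = long.pivot(index="prs_label", columns="pc_label", values="added_r2_prs")
    flat = bic.stack()
    best = flat.idxmin()
    return GridResult(
        fits=long,
        bic=bic,
        delta_bic=delta,
        total_r2=total.loc[rows, col_order],
        added_r2=added.loc[rows, col_order],
        best_cell=(best[0], best[1]),
    )


def classify_delta_bic(delta: float) -> str:
    """Rules-of-thumb bin for a delta-BIC value.

    <6 is a weak difference in model performance, 6-10 (inclusive) strong,
    >10 very strong.
    """
    if delta < 0:
        raise ValueError("delta BIC must be non-negative")
    if delta < 6:
        return "weak"
    if delta <= 10:
        return "strong"
    return "very strong"
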