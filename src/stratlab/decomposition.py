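"""Shared-variance decomposition of trait, PRS, and principal components.

Six regression models quantify how much population structure (summarized by
20 cohort-specific PCs) and the polygenic score overlap in the variance they
explain, after the trait is residualized on its non-genetic covariates
(age, sex, genotyping batch):

    (1) trait_res ~ PCs          (4) trait_res ~ PCs + PRS
    (2) PRS ~ PCs                (5) trait_res_PRS ~ PCs
    (3) trait_res ~ PRS          (6) trait_res_PCs ~ PRS

Each model is compared with the intercept-only model by the overall F-test
(upper tail); significance uses a Bonferroni cut-off for the family of
PRS x trait combinations tested (0.05 / 10 = 0.005 in the default design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .gwas import _covariate_design
from .pc_space import PCCoordinates
from .prs import PRSProfile

MODEL_LABELS = {
    1: "trait_res ~ PCs",
    2: "PRS ~ PCs",
    3: "trait_res ~ PRS",
    4: "trait_res ~ PCs + PRS",
    5: "trait_res_PRS ~ PCs",
    6: "trait_res_PCs ~ PRS",
}


@dataclass
class DecompositionResult:
    table: pd.DataFrame           # model, formula, r2, f_statistic, p_value, significant
    alpha: float

    def r2(self, model: int) -> float:
        return float(self.table.set_index("model").loc[model, "r2"])

    def significant(self, model: int) -> bool:
        return bool(self.table.set_index("model").loc[model, "significant"])


def residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residual of ``y`` on a full-rank design that includes an intercept."""
    y = np.asarray(y, dtype=float)
    design = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("residualize: design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _r2_f_p(y: np.ndarray, x_no_intercept: np.ndarray) -> tuple[float, float, float]:
    """R², overall F and its upper-tail p for y ~ 1 + X vs y ~ 1."""
    x = sm.add_constant(x_no_intercept, has_constant="add")
    res = sm.OLS(y, x).fit()
    return float(res.rsquared), float(res.fvalue), float(res.f_pvalue)


def run_decomposition(
    trait: np.ndarray,
    prs: PRSProfile | np.ndarray,
    pcs: PCCoordinates,
    samples: pd.DataFrame,
    n_pcs: int = 20,
    n_family_tests: int = 10,
) -> DecompositionResult:
    """Fit the six residual-regression models; F-test against intercept-only.

    ``n_family_tests`` sets the Bonferroni family size (default: 5 PRS
    versions times 2 traits, giving the 0.005 cut-off).
    """
    trait = np.asarray(trait, dtype=float)
    score = prs.score if isinstance(prs, PRSProfile) else np.asarray(prs, float)
    if abs(score.mean()) > 1e-8 or abs(score.std(ddof=0) - 1) > 1e-8:
        warnings.warn("PRS was not standardized; standardizing internally")
        sd = score.std(ddof=0)
        score = (score - score.mean()) / (sd if sd > 0 else 1.0)
    pc_mat = pcs.matrix(n_pcs)

    covar, _ = _covariate_design(samples, None)  # [1, age, sex, batch]
    trait_res = residualize(trait, covar)
    with_prs = np.column_stack([np.ones(len(trait)), score])
    with_pcs = np.column_stack([np.ones(len(trait)), pc_mat])
    trait_res_prs = residualize(trait_res, with_prs)
    trait_res_pcs = residualize(trait_res, with_pcs)

    designs = {
        1: (trait_res, pc_mat),
        2: (score, pc_mat),
        3: (trait_res, score[:, None]),
        4: (trait_res, np.column_stack([pc_mat, score])),
        5: (trait_res_prs, pc_mat),
        6: (trait_res_pcs, score[:, None]),
    }
    alpha = 0.05 / n_family_tests
    rows = []
    for mid, (y, x) in designs.items():
        r2, f, p = _r2_f_p(y, x)
        rows.append(
            {
                "model": mid,
                "formula": MODEL_LABELS[mid],
                "r2": r2,
                "f_statistic": f,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return DecompositionResult(table=pd.DataFrame(rows), alpha=alpha)
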