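"""Variant-level quality control and significance-agnostic LD pruning.

QC removes, in a fixed order, duplicated positions, indels, palindromic
(strand-ambiguous A/T, C/G) SNPs, variants with more than 5% missing calls,
and variants with minor allele frequency below 1%.  Each variant is counted
at the first filter that removes it, which makes the report deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

FILTER_ORDER = ("duplicate", "indel", "palindromic", "missingness", "maf")
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


@dataclass
class QCReport:
    """Removal counts per filter plus input/output totals."""

    variants_in: int
    removed: dict[str, int] = field(
        default_factory=lambda: {f: 0 for f in FILTER_ORDER}
    )

    @property
    def variants_out(self) -> int:
        return self.variants_in - sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": f, "removed": self.removed[f]} for f in FILTER_ORDER]
        rows.append({"filter": "variants_in", "removed": self.variants_in})
        rows.append({"filter": "variants_out", "removed": self.variants_out})
        return pd.DataFrame(rows)


def filter_variants(
    geno: GenotypeMatrix,
    max_missing: float = 0.05,
    min_maf: float = 0.01,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the five QC filters in order; surviving variant order preserved.

    Duplicate positions keep their first occurrence.  MAF is computed from
    complete cases only (no imputation), after no other preprocessing.
    """
    v = geno.variants
    report = QCReport(variants_in=geno.n_variants)
    removed_by: np.ndarray = np.full(geno.n_variants, "", dtype=object)

    # 1. duplicated chrom:pos (first kept)
    dup = v.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
    removed_by[dup] = "duplicate"

    # 2. indels: any allele not a single nucleotide
    a1 = v["allele1"].astype(str).str.len().to_numpy()
    a2 = v["allele2"].astype(str).str.len().to_numpy()
    indel = (a1 != 1) | (a2 != 1)
    removed_by[(removed_by == "") & indel] = "indel"

    # 3. palindromic SNPs (strand-naive on the stated alleles)
    pal = np.array(
        [{x, y} in _PALINDROMIC for x, y in zip(v["allele1"], v["allele2"])]
    )
    removed_by[(removed_by == "") & pal] = "palindromic"

    # 4. missingness
    miss = geno.missing_rate() > max_missing
    removed_by[(removed_by == "") & miss] = "missingness"

    # 5. minor allele frequency
    low_maf = geno.maf() < min_maf
    removed_by[(removed_by == "") & low_maf] = "maf"

    for f in FILTER_ORDER:
        report.removed[f] = int((removed_by == f).sum())

    keep = np.flatnonzero(removed_by == "")
    if keep.size == 0:
        logger.warning("variant QC removed every variant")
    return geno.take_variants(keep), report


def _window_r2(z: np.ndarray) -> np.ndarray:
    """Pairwise squared correlation of pre-standardized columns."""
    n = z.shape[0]
    c = (z.T @ z) / n
    sd = np.sqrt(np.diag(c))
    sd = np.where(sd > 0, sd, 1.0)
    r = c / np.outer(sd, sd)
    return r**2


def ld_prune(
    geno: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Sliding-window greedy LD pruning (PLINK ``--indep-pairwise`` style).

    Within each ``window``-variant window (per chromosome, advancing by
    ``step``), pairs with squared dosage correlation above ``r2_max`` are
    resolved by dropping the later-positioned member.  Monomorphic variants
    are dropped up front.  Returns kept positional indices, sorted.
    """
    if geno.n_variants < 2:
        return np.arange(geno.n_variants)
    z = geno.standardized()
    mono = z.std(axis=0) == 0
    if mono.any():
        logger.info("ld_prune: dropping %d monomorphic variants", int(mono.sum()))
    kept = ~mono
    chroms = geno.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero((chroms == chrom) & ~mono)
        for start in range(0, max(1, len(cidx)), step):
            widx = cidx[start:start + window]
            active = widx[kept[widx]]
            if len(active) < 2:
                if start + window >= len(cidx):
                    break
                continue
            r2 = _window_r2(z[:, active])
            iu = np.triu_indices(len(active), k=1)
            if not (r2[iu] > r2_max).any():
                if start + window >= len(cidx):
                    break
                continue
            for i in range(len(active)):
                if not kept[active[i]]:
                    continue
                for j in range(i + 1, len(active)):
                    if kept[active[j]] and r2[i, j] > r2_max:
                        kept[active[j]] = False
            if start + window >= len(cidx):
                break
    return np.flatnonzero(kept)
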