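"""In-memory genotype container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns required in the variant metadata table
VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "allele1", "allele2")


@dataclass
class GenotypeMatrix:
    """Additive dosages for ``n_samples x n_variants`` biallelic variants.

    Dosages count copies of ``allele1`` (the effect/A1 allele, PLINK
    convention) and live in {0, 1, 2}; missing calls are ``NaN``.  Variant
    metadata (``variant_id, chrom, pos, allele1, allele2``) and sample
    identifiers are attached positionally.

    Parameters
    ----------
    dosages
        float array of shape ``(n_samples, n_variants)``.
    variants
        DataFrame with one row per variant, columns :data:`VARIANT_COLUMNS`.
    sample_ids
        sequence of unique string identifiers, one per row of ``dosages``.
    sample_info
        optional per-sample covariate table indexed like ``sample_ids``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: np.ndarray
    sample_info: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.dosages.shape[0]} rows"
            )
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError(
                f"{len(self.variants)} variant rows for {self.dosages.shape[1]} columns"
            )
        missing_cols = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing_cols:
            raise ValueError(f"variant table missing columns: {sorted(missing_cols)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.variants = self.variants.reset_index(drop=True)

    # ------------------------------------------------------------------ #
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return np.isnan(self.dosages).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-variant allele-1 frequency from complete cases (no imputation)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency from complete cases."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    # ------------------------------------------------------------------ #
    def take_samples(self, ids) -> "GenotypeMatrix":
        """Row-subset by sample identifier, preserving the requested order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([pos[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample id not in matrix: {exc.args[0]!r}") from None
        info = None
        if self.sample_info is not None:
            info = self.sample_info.iloc[idx].reset_index(drop=True)
        return GenotypeMatrix(
            self.dosages[idx], self.variants.copy(), self.sample_ids[idx], info
        )

    def take_variants(self, index) -> "GenotypeMatrix":
        """Column-subset by positional variant index."""
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            self.sample_ids.copy(),
            None if self.sample_info is None else self.sample_info.copy(),
        )

    def variant_index(self, variant_ids) -> np.ndarray:
        """Positional indices for the given variant ids (error if absent)."""
        pos = pd.Series(
            np.arange(self.n_variants), index=self.variants["variant_id"].to_numpy()
        )
        missing = [v for v in variant_ids if v not in pos.index]
        if missing:
            raise KeyError(f"variants absent from matrix: {missing[:10]}")
        return pos.loc[list(variant_ids)].to_numpy()

    def standardized(self, means=None, sds=None) -> np.ndarray:
        """(g - mean)/sd with missing -> 0 after centering (mean imputation)."""
        x = self.dosages
        if means is None:
            means = np.nanmean(x, axis=0)
        if sds is None:
            sds = np.nanstd(x, axis=0, ddof=0)
        z = (x - means) / np.where(sds > 0, sds, 1.0)
        return np.nan_to_num(z, nan=0.0)
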