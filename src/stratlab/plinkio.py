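"""PLINK 1 binary fileset (.bed/.bim/.fam) reading and writing.

Variant-major .bed (magic bytes ``0x6c 0x1b 0x01``): each variant occupies
``ceil(n_samples/4)`` bytes, two bits per sample, little-endian within a byte.
Two-bit codes map to allele-1 dosage as ``00 -> 2``, ``10 -> 1``, ``11 -> 0``,
``01 -> missing``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# code -> dosage lookup; 3.0 is a sentinel replaced by NaN
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}

BIM_COLUMNS = ["chrom", "variant_id", "cm", "pos", "allele1", "allele2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read ``prefix``.bed/.bim/.fam into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", names=BIM_COLUMNS,
        dtype={"chrom": str, "variant_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", names=FAM_COLUMNS,
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not variant-major PLINK bed)")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != m * bytes_per_variant:
        raise ValueError(
            f"{prefix}.bed: expected {m * bytes_per_variant} data bytes, got {body.size}"
        )
    blocks = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes: sample i lives in byte i//4, bits (i%4)*2
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # samples x variants

    variants = bim[["variant_id", "chrom", "pos", "allele1", "allele2"]].copy()
    return GenotypeMatrix(dosages, variants, fam["iid"].to_numpy(dtype=object))


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as ``prefix``.bed/.bim/.fam."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    v = geno.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "variant_id": v["variant_id"],
            "cm": 0,
            "pos": v["pos"],
            "allele1": v["allele1"],
            "allele2": v["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": geno.sample_ids,
            "iid": geno.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = geno.n_samples, geno.n_variants
    d = geno.dosages
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # default missing
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[(d.T == dosage)] = code
    bad = ~np.isnan(d) & ~np.isin(d, list(_DOSAGE_TO_CODE))
    if bad.any():
        raise ValueError("write_plink requires hard calls in {0,1,2} or NaN")
    bytes_per_variant = (n + 3) // 4
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(m, bytes_per_variant, 4) << shifts[None, None, :]).sum(
        axis=2, dtype=np.uint8
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())
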