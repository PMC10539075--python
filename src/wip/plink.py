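"""Minimal PLINK 1 binary fileset (.bed/.bim/.fam) reader and writer.

Only the variant-major (SNP-major) layout written by modern PLINK is
supported.  Genotypes are decoded to the additive dosage of the A1 allele
(0, 1, 2, or NaN for missing).  The writer exists to build small test
fixtures and round-trips exactly through the reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> A1 dosage: 00 hom A1 -> 2, 01 missing -> NaN, 10 het -> 1, 11 hom A2 -> 0
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])
_DOSAGE_TO_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}

_BIM_COLS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
_FAM_COLS = ["fid", "iid", "father", "mother", "sex", "pheno"]


def _byte_decode_table() -> np.ndarray:
    # table[byte] -> 4 dosages, lowest-order bit pair first
    table = np.empty((256, 4))
    for b in range(256):
        for s in range(4):
            table[b, s] = _CODE_TO_DOSAGE[(b >> (2 * s)) & 0b11]
    return table


_TABLE = _byte_decode_table()


def read_plink(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Read ``prefix{.bed,.bim,.fam}``.

    Returns ``(variants, samples, dosage)`` where ``dosage`` has shape
    ``(n_variants, n_samples)`` and counts copies of the A1 allele.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(f"missing companion file {prefix.with_suffix(ext)}")
    variants = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", names=_BIM_COLS, dtype={"chrom": str, "snp": str}
    )
    samples = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", names=_FAM_COLS, dtype={"fid": str, "iid": str}
    )
    n_var, n_samp = len(variants), len(samples)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != _MAGIC[:2]:
        raise ValueError(f"{prefix.with_suffix('.bed')} is not a PLINK .bed file")
    if raw[2:3] != _MAGIC[2:3]:
        raise ValueError("only SNP-major .bed files are supported")
    bpv = (n_samp + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != n_var * bpv:
        raise ValueError(
            f".bed payload has {body.size} bytes, expected {n_var * bpv} "
            f"({n_var} variants x {bpv} bytes)"
        )
    dosage = _TABLE[body.reshape(n_var, bpv)].reshape(n_var, bpv * 4)[:, :n_samp]
    return variants, samples, dosage


def write_plink(
    prefix: str | Path,
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    dosage: np.ndarray,
) -> None:
    """Write a SNP-major fileset; ``dosage`` counts A1 copies (NaN = missing)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n_var, n_samp = dosage.shape
    if len(variants) != n_var or len(samples) != n_samp:
        raise ValueError("dosage shape does not match variant/sample tables")
    variants[_BIM_COLS].to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    samples[_FAM_COLS].to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bpv = (n_samp + 3) // 4
    out = bytearray(_MAGIC)
    for v in range(n_var):
        row = np.zeros(bpv, dtype=np.uint8)
        for s in range(n_samp):
            d = dosage[v, s]
            code = 0b01 if np.isnan(d) else _DOSAGE_TO_CODE[float(d)]
            row[s // 4] |= code << (2 * (s % 4))
        out += row.tobytes()
    prefix.with_suffix(".bed").write_bytes(bytes(out))
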