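"""Readers for the pipeline's standard inputs (VCF via cyvcf2, TSV tables)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = ["read_vcf", "read_expression", "read_covariates", "read_viability"]


def read_vcf(path: str | Path):
    """Read a VCF into (genotype matrix, site table, samples, dosages).

    Genotypes are coded as ALT-allele count 0/1/2 with -1 for missing; the
    site table carries snp_id, chrom, pos, imputed (INFO IMPR2 present) and
    dosage_r2; dosages is the DS matrix or None when absent.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    header_has_ds = "##FORMAT=<ID=DS" in vcf.raw_header
    genos, rows, dosages = [], [], []
    has_ds = False
    for var in vcf:
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = np.asarray(var.gt_types)
        coded = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=-1)
        genos.append(coded.astype(np.int8))
        r2 = var.INFO.get("IMPR2")
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "imputed": r2 is not None,
                "dosage_r2": float(r2) if r2 is not None else np.nan,
            }
        )
        ds = var.format("DS") if header_has_ds else None
        if ds is not None:
            has_ds = True
            dosages.append(np.asarray(ds, dtype=float).reshape(-1))
        else:
            dosages.append(np.full(len(samples), np.nan))
    G = np.vstack(genos) if genos else np.empty((0, len(samples)), dtype=np.int8)
    DS = np.vstack(dosages) if has_ds else None
    return G, pd.DataFrame(rows), samples, DS


def read_expression(path: str | Path) -> pd.DataFrame:
    """Probe x sample TSV; first column is the probe id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "sex", "race"}
    if not required <= set(df.columns):
        raise ValueError(f"covariate TSV needs columns {sorted(required)}")
    return df


def read_viability(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "dose_nM", "replicate", "viability"}
    if not required <= set(df.columns):
        raise ValueError(f"viability TSV needs columns {sorted(required)}")
    return df
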