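"""Genome-wide application of the LR / IP / WIP association tests.

Reads genotypes (PLINK bed or VCF), a covariate table and phenotypes or
affection probabilities; runs the chosen test per variant; emits an
association table with odds ratios, optionally misclassification-adjusted
odds ratios, and p-values, flagging genome-wide significance at 5e-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .bias import BiasModel, adjust_coefficient
from .plink import read_plink
from .wgee import CohortData, SeparationError, fit_wgee, score_test, wald_test

__all__ = [
    "VariantRecord",
    "GWS_THRESHOLD",
    "read_genotypes",
    "build_cohort_inputs",
    "run_scan",
    "genomic_inflation",
    "make_fixtures",
]

log = logging.getLogger(__name__)

GWS_THRESHOLD = 5e-8

ASSOC_COLUMNS = ["CHR", "BP", "SNP", "MA", "MAF", "N", "OR", "ORADJ", "P", "GWS_FLAG", "NOTE"]


@dataclass
class VariantRecord:
    """One variant, oriented so that dosage counts the minor allele."""

    chrom: str
    pos: int
    vid: str
    minor: str
    major: str
    dosage: np.ndarray  # minor-allele count per subject, NaN = missing
    maf: float
    swapped: bool = False  # True if the file's counted allele was the major one


def _orient_minor(dosage: np.ndarray, a_counted: str, a_other: str) -> tuple[np.ndarray, str, str, float, bool]:
    ok = np.isfinite(dosage)
    freq = float(dosage[ok].mean() / 2) if ok.any() else 0.0
    if freq > 0.5:
        return 2 - dosage, a_other, a_counted, 1 - freq, True
    return dosage, a_counted, a_other, freq, False


def _iter_plink(prefix: str | Path) -> tuple[list[str], Iterator[VariantRecord]]:
    variants, samples, dosage = read_plink(prefix)

    def gen() -> Iterator[VariantRecord]:
        for i, row in variants.iterrows():
            d, minor, major, maf, swapped = _orient_minor(dosage[i].copy(), row.a1, row.a2)
            yield VariantRecord(str(row.chrom), int(row.pos), str(row.snp), minor, major, d, maf, swapped)

    return samples["iid"].tolist(), gen()


def _iter_vcf(path: str | Path) -> tuple[list[str], Iterator[VariantRecord]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)

    def gen() -> Iterator[VariantRecord]:
        for var in vcf:
            alt = var.ALT[0] if var.ALT else "."
            try:
                ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
            except (TypeError, KeyError):
                gt = np.asarray(var.gt_types, dtype=float)  # 0 homref,1 het,2 unknown,3 homalt
                ds = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
            vid = var.ID or f"{var.CHROM}:{var.POS}"
            d, minor, major, maf, swapped = _orient_minor(ds, alt, var.REF)
            yield VariantRecord(str(var.CHROM), int(var.POS), vid, minor, major, d, maf, swapped)

    return ids, gen()


def read_genotypes(path: str | Path, fmt: str | None = None) -> tuple[list[str], Iterator[VariantRecord]]:
    """Stream variants (minor-allele oriented) plus the subject-id order.

    ``fmt`` is "plink_bed" or "vcf"; by default it is inferred from the
    path (a ``.vcf``/``.vcf.gz`` suffix means VCF, anything else is treated
    as a PLINK prefix).
    """
    p = str(path)
    if fmt is None:
        fmt = "vcf" if p.endswith((".vcf", ".vcf.gz")) else "plink_bed"
    if fmt == "vcf":
        return _iter_vcf(path)
    if fmt == "plink_bed":
        prefix = Path(p[:-4]) if p.endswith(".bed") else Path(p)
        return _iter_plink(prefix)
    raise ValueError(f"unknown genotype format {fmt!r}")


def build_cohort_inputs(
    sample_ids: list[str],
    covar: pd.DataFrame,
    pheno: pd.DataFrame,
    probs: pd.DataFrame | None = None,
) -> dict:
    """Reconcile covariate/phenotype/probability tables with genotype order.

    All tables need an ``IID`` column.  ``pheno`` needs ``STATUS`` coded
    1/0/NA (case/control/missing); missing subjects must appear in ``probs``
    (columns ``IID``, ``P_AFFECTED``).  Returns per-subject arrays aligned
    to ``sample_ids``.
    """
    for name, tab in (("covar", covar), ("pheno", pheno)):
        if "IID" not in tab.columns:
            raise ValueError(f"{name} table lacks an IID column")
    covar = covar.set_index("IID")
    pheno = pheno.set_index("IID")
    missing_ids = [s for s in sample_ids if s not in covar.index or s not in pheno.index]
    if missing_ids:
        raise ValueError(
            f"{len(missing_ids)} genotyped subjects absent from covariate/phenotype "
            f"tables, e.g. {missing_ids[:5]}"
        )
    covar = covar.loc[sample_ids]
    status = pd.to_numeric(pheno.loc[sample_ids, "STATUS"], errors="coerce").to_numpy()
    labeled = np.isfinite(status)
    p = np.where(labeled, status, np.nan)
    if (~labeled).any():
        if probs is None:
            raise ValueError("phenotype table has missing status but no probability table given")
        pr = probs.set_index("IID")["P_AFFECTED"]
        need = [s for s, lab in zip(sample_ids, labeled) if not lab]
        absent = [s for s in need if s not in pr.index]
        if absent:
            raise ValueError(f"no affection probability for {len(absent)} subjects, e.g. {absent[:5]}")
        p[~labeled] = pr.loc[need].to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(sample_ids)), covar.to_numpy(dtype=float)])
    y = np.where(labeled, status, 0.0)
    return {"Z": Z, "y": y, "p": p, "labeled": labeled, "covar_names": list(covar.columns)}


def run_scan(
    genotypes: Iterable[VariantRecord],
    cohort: dict,
    method: str = "wip",
    test: str = "wald",
    min_maf: float = 0.0,
    max_missing: float = 1.0,
    adjust: BiasModel | None = None,
) -> pd.DataFrame:
    """Per-variant association scan; returns the association table.

    Subjects with missing dosage are dropped per variant.  Variants failing
    the MAF or missingness filters are skipped (counted in the log).  A
    non-converged fit yields an NA row with a reason code rather than a
    crash.
    """
    rows = []
    n_filtered = 0
    y, p, Z, labeled = cohort["y"], cohort["p"], cohort["Z"], cohort["labeled"]
    for var in genotypes:
        ok = np.isfinite(var.dosage)
        miss_rate = 1 - ok.mean()
        maf_obs = float(var.dosage[ok].mean() / 2) if ok.any() else 0.0
        maf_obs = min(maf_obs, 1 - maf_obs)
        if maf_obs < min_maf or miss_rate > max_missing:
            n_filtered += 1
            continue
        base = {"CHR": var.chrom, "BP": var.pos, "SNP": var.vid, "MA": var.minor}
        try:
            data = CohortData.for_method(
                method, y[ok], p[ok], Z[ok], var.dosage[ok], labeled[ok]
            )
            if test == "score":
                res = score_test(data, method=method.upper())
                fit = fit_wgee(data)  # for the reported OR
            else:
                fit = fit_wgee(data)
                if not fit.converged:
                    rows.append({**base, "MAF": maf_obs, "N": int(ok.sum()), "OR": np.nan,
                                 "ORADJ": np.nan, "P": np.nan, "GWS_FLAG": False,
                                 "NOTE": "non_converged"})
                    continue
                res = wald_test(fit, method=method.upper())
            beta = float(fit.beta[0]) if fit.converged else np.nan
            or_adj = np.nan
            if adjust is not None and np.isfinite(beta):
                or_adj = float(np.exp(adjust_coefficient(beta, adjust.b_hat, adjust.d_star)))
            rows.append(
                {
                    **base,
                    "MAF": maf_obs,
                    "N": int(ok.sum()),
                    "OR": float(np.exp(beta)) if np.isfinite(beta) else np.nan,
                    "ORADJ": or_adj,
                    "P": res.pvalue,
                    "GWS_FLAG": bool(res.pvalue < GWS_THRESHOLD),
                    "NOTE": "",
                }
            )
        except SeparationError as exc:
            rows.append({**base, "MAF": maf_obs, "N": int(ok.sum()), "OR": np.nan,
                         "ORADJ": np.nan, "P": np.nan, "GWS_FLAG": False,
                         "NOTE": f"separation:{exc}"})
    if n_filtered:
        log.info("filtered %d variants (min_maf=%g, max_missing=%g)", n_filtered, min_maf, max_missing)
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic inflation factor: median test chi2 over its null median.

    lambda = median(qchisq(1 - p, 1)) / 0.4549364.  Requires >= 100
    p-values for a stable median.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError(f"need at least 100 p-values for lambda_GC, got {p.size}")
    stats = chi2.isf(p, 1)
    return float(np.median(stats) / chi2.ppf(0.5, 1))


def make_fixtures(outdir: str | Path, seed: int = 0, n_subjects: int = 300, n_null: int = 20) -> dict:
    """Write a small synthetic genotype/phenotype fixture set with one planted signal.

    Produces ``fixture.{bed,bim,fam}``, ``fixture.vcf``, ``covar.tsv``,
    ``pheno.tsv`` and ``probs.tsv`` under ``outdir`` and returns the paths.
    The first variant carries a real effect (beta = 0.4); the rest are null.
    """
    from .plink import write_plink

    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_var = n_null + 1
    mafs = rng.uniform(0.1, 0.5, n_var)
    dosage = rng.binomial(2, mafs[:, None], (n_var, n_subjects)).astype(float)
    sex = rng.integers(0, 2, n_subjects).astype(float)
    age = rng.normal(70, 6, n_subjects)
    eta = -0.3 + 0.4 * dosage[0] + 0.3 * sex + 0.02 * (age - 70) + rng.normal(0, 1, n_subjects)
    prob = 1 / (1 + np.exp(-eta))
    y = rng.binomial(1, prob).astype(float)
    # a third of subjects lose their label; a noisy probability stands in
    masked = rng.random(n_subjects) < 1 / 3
    p_guess = np.clip(prob + rng.normal(0, 0.1, n_subjects), 0.01, 0.99)

    iids = [f"S{i:04d}" for i in range(n_subjects)]
    variants = pd.DataFrame(
        {
            "chrom": ["1"] * n_var,
            "snp": [f"var{i}" for i in range(n_var)],
            "cm": 0,
            "pos": np.arange(1, n_var + 1) * 1000,
            "a1": ["A"] * n_var,
            "a2": ["G"] * n_var,
        }
    )
    samples = pd.DataFrame(
        {"fid": iids, "iid": iids, "father": "0", "mother": "0",
         "sex": (sex + 1).astype(int), "pheno": -9}
    )
    write_plink(outdir / "fixture", variants, samples, dosage)

    with open(outdir / "fixture.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in ["1"]:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(iids) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i in range(n_var):
            gts = "\t".join(gt_map[d] for d in dosage[i])
            fh.write(f"1\t{i * 1000 + 1000}\tvar{i}\tG\tA\t.\tPASS\t.\tGT\t{gts}\n")

    pd.DataFrame({"IID": iids, "AGE": age, "SEX": sex}).to_csv(outdir / "covar.tsv", sep="\t", index=False)
    status = np.where(masked, "NA", y.astype(int).astype(str))
    pd.DataFrame({"IID": iids, "STATUS": status}).to_csv(outdir / "pheno.tsv", sep="\t", index=False)
    pd.DataFrame({"IID": np.array(iids)[masked], "P_AFFECTED": p_guess[masked]}).to_csv(
        outdir / "probs.tsv", sep="\t", index=False
    )
    return {
        "bed": outdir / "fixture.bed",
        "vcf": outdir / "fixture.vcf",
        "covar": outdir / "covar.tsv",
        "pheno": outdir / "pheno.tsv",
        "probs": outdir / "probs.tsv",
        "causal": "var0",
        "truth_y": y,
    }
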