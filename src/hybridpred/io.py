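"""Readers and writers for the pipeline's on-disk formats.

Delimited matrices are tab-separated, UTF-8, row ids in the first column,
'.' for missing — a fixed dialect so file hashes are stable across runs.
Genotypes can additionally be read from (biallelic) VCF and exported as a
minimal VCF.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CrossPlan, MixedModelFit, OmicsMatrix

log = logging.getLogger("hybridpred")

NA_REP = "."
SEP = "\t"


def write_matrix(om: OmicsMatrix, path: str | Path) -> None:
    om.data.to_csv(path, sep=SEP, na_rep=NA_REP, index_label="id")


def read_matrix(path: str | Path, layer: str) -> OmicsMatrix:
    try:
        df = pd.read_csv(path, sep=SEP, index_col=0, na_values=[NA_REP])
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed delimited matrix {path}: {exc}") from exc
    df.index.name = None
    return OmicsMatrix(df, layer)


def read_genotypes(path: str | Path, format: str = "matrix") -> OmicsMatrix:
    """Read a dosage matrix from a delimited file or a biallelic VCF.

    VCF: one column per sample, dosage = ALT allele count; multiallelic
    sites are skipped (count logged); missing genotypes are imputed to the
    site mean with a warning.
    """
    if format == "matrix":
        return read_matrix(path, "genomic")
    if format != "vcf":
        raise ValueError(f"unknown genotype format {format!r}")
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids, skipped, imputed = [], [], 0, 0
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        gt = np.asarray(v.gt_types, dtype=float)
        dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        if np.any(np.isnan(dose)):
            m = np.nanmean(dose) if np.any(np.isfinite(dose)) else 0.0
            imputed += int(np.sum(np.isnan(dose)))
            dose = np.where(np.isnan(dose), m, dose)
        rows.append(dose)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
    if skipped:
        log.info("skipped %d multiallelic site(s)", skipped)
    if imputed:
        warnings.warn(f"imputed {imputed} missing genotype call(s) to site mean")
    df = pd.DataFrame(np.asarray(rows).T, index=samples, columns=ids)
    return OmicsMatrix(df, "genomic")


def write_vcf(om: OmicsMatrix, path: str | Path) -> None:
    """Minimal biallelic VCF export of a dosage matrix (A/T placeholder
    alleles, one pseudo-chromosome)."""
    if om.layer != "genomic":
        raise ValueError("VCF export is for genotype matrices")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(om.individuals) + "\n")
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        V = om.values
        for j, snp in enumerate(om.features):
            gts = "\t".join(code.get(V[i, j], "./.") for i in range(V.shape[0]))
            fh.write(f"1\t{j + 1}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def write_cross_plan(plan: CrossPlan, path: str | Path) -> None:
    plan.pairs.to_csv(path, sep=SEP, index=False)


def read_cross_plan(path: str | Path) -> CrossPlan:
    return CrossPlan(pd.read_csv(path, sep=SEP, dtype=str))


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep=SEP, na_rep=NA_REP, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP, na_values=[NA_REP])


def write_fit(fit: MixedModelFit, path: str | Path) -> None:
    payload = {
        "beta": np.asarray(fit.beta).tolist(),
        "variance_components": fit.variance_components,
        "residual_variance": fit.residual_variance,
        "loglik": fit.loglik,
        "iterations": fit.iterations,
        "converged": fit.converged,
        "trace": list(fit.trace),
        "floored": fit.floored,
        "ids": fit.ids,
        "blups": {k: np.asarray(v).tolist() for k, v in fit.blups.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
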