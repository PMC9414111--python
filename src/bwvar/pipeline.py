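"""End-to-end orchestration: dataset -> scores -> analysis cohort -> models.

`analyze_dataset` reads a dataset directory (VCF + trio map + phenotype
TSV + weights TSV), builds the three genetic scores, prepares the
analysis cohort and runs the model suite, writing a model-report TSV,
an R²/CI series TSV, exclusion logs and a JSON run summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cohort as cohort_prep
from . import dataio, models, scores

logger = logging.getLogger(__name__)

__all__ = ["build_scores", "prepare_cohort", "analyze_dataset"]

DEFAULT_MAF_MIN = 0.001
DEFAULT_INFO_MIN = 0.4

_ROLE_WEIGHT = {
    "mother": ("maternal_score", "weight_maternal_adj"),
    "child": ("fetal_score", "weight_fetal_adj"),
    "father": ("paternal_score", "weight_fetal_unadj"),
}


def build_scores(vcf_data: dataio.VcfData, weights: pd.DataFrame,
                 trios: pd.DataFrame, maf_min: float = DEFAULT_MAF_MIN,
                 info_min: float = DEFAULT_INFO_MIN,
                 allow_missing: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute standardized maternal/fetal/paternal scores per trio.

    Returns ``(score_table, exclusion_report)`` where the score table is
    indexed by trio with one column per available role's score.  A role
    whose samples are absent from the VCF yields no column (downstream
    models needing it are skipped).
    """
    kept, report = scores.filter_variants(weights, maf_min, info_min)
    aligned = scores.align_dosages(vcf_data, kept, allow_missing=allow_missing)
    sample_index = {sid: i for i, sid in enumerate(vcf_data.sample_ids)}
    out = pd.DataFrame({"trio_id": sorted(set(trios["family_id"]))})
    for role, (col, wcol) in _ROLE_WEIGHT.items():
        members = trios[trios["role"] == role].set_index("family_id")["individual_id"]
        ids = [members.get(t) for t in out["trio_id"]]
        if any(i is None or i not in sample_index for i in ids):
            logger.warning("no complete %s genotypes; %s not computed", role, col)
            continue
        raw = scores.compute_score(aligned[[sample_index[i] for i in ids], :],
                                   kept, wcol)
        out[col] = scores.standardize(raw)
    return out, report


def prepare_cohort(pheno: pd.DataFrame, score_table: pd.DataFrame | None = None,
                   adjust_mode: str = "internal",
                   reference: cohort_prep.GestAgeReference | None = None,
                   required_fields: tuple[str, ...] = (
                       "maternal_age", "maternal_weight", "maternal_height",
                       "paternal_height", "glucose", "smoking", "parity",
                       "gest_age", "birthweight_raw"),
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Adjust birthweight, apply term and completeness filters.

    Returns ``(analysis_cohort, exclusion_log, comparison_table)``; the
    comparison table holds included-vs-excluded t / chi-square tests.
    """
    records = pheno.copy()
    records["birthweight_adj"] = cohort_prep.adjust_birthweight(
        records, mode=adjust_mode, reference=reference)
    if score_table is not None:
        # genotype-derived scores replace any score columns already present
        records = records.drop(
            columns=[c for c in ("maternal_score", "fetal_score", "paternal_score")
                     if c in records.columns]
        ).merge(score_table, on="trio_id", how="left")
    term, term_log = cohort_prep.filter_term(records)
    genotyped = None
    if score_table is not None:
        genotyped = {}
        for role, (col, _) in _ROLE_WEIGHT.items():
            if col in score_table.columns:
                ok = score_table.loc[~score_table[col].isna(), "trio_id"]
                genotyped[role] = set(ok)
    complete, comp_log = cohort_prep.filter_complete(
        term, genotyped=genotyped,
        required_fields=[f for f in required_fields if f in term.columns])
    log = pd.concat([term_log, comp_log], ignore_index=True)
    excluded = records[~records["trio_id"].isin(complete["trio_id"])]
    if excluded.empty:
        comparison = pd.DataFrame(
            columns=["variable", "test", "statistic", "df", "p", "testable"])
    else:
        comparison = cohort_prep.compare_cohorts(
            complete, excluded,
            continuous=[c for c in ("maternal_height", "maternal_weight",
                                    "gest_age", "birthweight_raw", "maternal_age")
                        if c in records.columns],
            categorical=[c for c in ("smoking", "parity", "sex_male")
                         if c in records.columns])
    return complete, log, comparison


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def analyze_dataset(dataset_dir, outdir, maf_min: float = DEFAULT_MAF_MIN,
                    info_min: float = DEFAULT_INFO_MIN, n_boot: int = 1000,
                    seed: int = 0, sensitivity: tuple[float, float] | None = None,
                    adjust_mode: str = "internal") -> dict:
    """Run the whole analysis on a written dataset and emit report files."""
    dataset_dir, outdir = Path(dataset_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pheno = dataio.read_phenotypes(dataset_dir / "phenotypes.tsv")
    inputs = {"phenotypes": dataset_dir / "phenotypes.tsv"}
    score_table = None
    score_report = pd.DataFrame()
    vcf_path = dataset_dir / "genotypes.vcf"
    if vcf_path.exists():
        inputs["vcf"] = vcf_path
        inputs["weights"] = dataset_dir / "weights.tsv"
        inputs["trios"] = dataset_dir / "trios.tsv"
        vcf_data = dataio.read_vcf(vcf_path)
        weights = scores.read_weights(inputs["weights"])
        trios = dataio.read_trios(inputs["trios"])
        score_table, score_report = build_scores(
            vcf_data, weights, trios, maf_min=maf_min, info_min=info_min)
    cohort, exclusions, comparison = prepare_cohort(
        pheno, score_table, adjust_mode=adjust_mode)
    suite = models.run_model_suite(cohort, n_boot=n_boot, seed=seed)
    summary = suite.to_summary()
    summary["config"] = {
        "package_version": __version__,
        "seed": seed,
        "maf_min": maf_min,
        "info_min": info_min,
        "n_boot": n_boot,
        "adjust_mode": adjust_mode,
        "inputs": {k: {"path": str(p), "sha256_16": _checksum(p)}
                   for k, p in inputs.items()},
    }
    summary["cohort"] = {
        "n_input": int(len(pheno)),
        "n_analysis": int(len(cohort)),
        "n_excluded": int(len(exclusions)),
    }
    if sensitivity is not None and score_table is not None:
        alt_scores, _ = build_scores(vcf_data, weights, trios,
                                     maf_min=sensitivity[0], info_min=sensitivity[1])
        alt_cohort, _, _ = prepare_cohort(pheno, alt_scores, adjust_mode=adjust_mode)
        alt = models.run_model_suite(alt_cohort, n_boot=max(100, n_boot // 10),
                                     seed=seed)
        summary["sensitivity"] = {
            "maf_min": sensitivity[0], "info_min": sensitivity[1],
            "r2_delta": {mid: alt.fits[mid].r2 - suite.fits[mid].r2
                         for mid in suite.fits if mid in alt.fits},
        }
    # emitted artifacts
    tables = []
    for mid, fit in suite.fits.items():
        t = fit.table()
        t.insert(0, "model", mid)
        tables.append(t)
    pd.concat(tables, ignore_index=True).to_csv(
        outdir / "model_report.tsv", sep="\t", index=False)
    suite.fig_series().to_csv(outdir / "r2_series.tsv", sep="\t", index=False)
    exclusions.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    comparison.to_csv(outdir / "included_vs_excluded.tsv", sep="\t", index=False)
    if not score_report.empty:
        score_report.to_csv(outdir / "variant_exclusions.tsv", sep="\t", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
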