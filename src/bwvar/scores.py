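"""Construction and validation of maternal, fetal and paternal genetic scores.

A genetic score is the weighted sum of effect-allele dosages,
GS = sum_i w_i * g_i, over a table of variant weights.  The maternal
score uses weights adjusted for fetal genotype, the fetal score weights
adjusted for maternal genotype, and the paternal score (for the father's
own birthweight) the unadjusted fetal weights.  Scores are standardized
to mean 0 / SD 1 on the analysis sample before modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_WEIGHT_COLUMNS",
    "WEIGHT_COLUMNS",
    "ScoreSet",
    "read_weights",
    "filter_variants",
    "align_dosages",
    "compute_score",
    "standardize",
    "validate_score",
]

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = ("weight_maternal_adj", "weight_fetal_adj", "weight_fetal_unadj")
REQUIRED_WEIGHT_COLUMNS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "effect_allele_freq", "imputation_r2",
) + WEIGHT_COLUMNS

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class ScoreSet:
    """Raw and standardized scores for one role across the cohort."""

    role: str  # maternal | fetal | paternal
    raw: np.ndarray
    standardized: np.ndarray
    n_snps_used: int

    def __post_init__(self) -> None:
        if self.role not in ("maternal", "fetal", "paternal"):
            raise ValueError(f"unknown score role {self.role!r}")


def read_weights(path) -> pd.DataFrame:
    """Read and validate a tab-separated variant-weights table.

    Required columns: snp_id, chrom, pos, effect_allele, other_allele,
    effect_allele_freq, imputation_r2 and the three weight columns.
    Duplicate SNP ids, identical allele pairs, or non-finite weights are
    rejected; an empty file yields an empty table with a logged warning.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        logger.warning("weights file %s is empty", path)
        return pd.DataFrame(columns=list(REQUIRED_WEIGHT_COLUMNS))
    missing = [c for c in REQUIRED_WEIGHT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"weights table missing required column(s): {', '.join(missing)}")
    if table.empty:
        logger.warning("weights file %s has a header but no variants", path)
        return table
    dup = table["snp_id"][table["snp_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate snp_id in weights table: {dup.iloc[0]!r}")
    same = table["effect_allele"] == table["other_allele"]
    if same.any():
        bad = table.loc[same, "snp_id"].iloc[0]
        raise ValueError(f"effect and other allele identical for SNP {bad!r}")
    freqs = table["effect_allele_freq"].to_numpy(dtype=float)
    if not np.all((freqs > 0) & (freqs < 1)):
        bad = table["snp_id"].iloc[int(np.argmin((freqs > 0) & (freqs < 1)))]
        raise ValueError(f"effect_allele_freq out of (0,1) for SNP {bad!r}")
    for col in WEIGHT_COLUMNS:
        vals = table[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = table["snp_id"].iloc[int(np.argmin(np.isfinite(vals)))]
            raise ValueError(f"non-finite {col} for SNP {bad!r}")
    return table


def filter_variants(weights: pd.DataFrame, maf_min: float, info_min: float,
                    *, drop_ambiguous: bool = False
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the MAF / imputation-quality filter.

    Retains variants with MAF = min(f, 1-f) strictly greater than
    ``maf_min`` AND imputation r^2 strictly greater than ``info_min``
    (strict inequalities mirror the published "> 0.001" / "> 0.4"
    thresholds).  Strand-ambiguous (A/T, C/G) variants are retained with
    a warning unless ``drop_ambiguous``.

    Returns ``(retained, report)`` where report lists one row per
    excluded variant with its reason.
    """
    for name, thr in (("maf_min", maf_min), ("info_min", info_min)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {thr}")
    if weights.empty:
        logger.warning("filter_variants received an empty weights table")
        return weights.copy(), pd.DataFrame(columns=["snp_id", "reason"])
    f = weights["effect_allele_freq"].to_numpy(dtype=float)
    maf = np.minimum(f, 1.0 - f)
    info = weights["imputation_r2"].to_numpy(dtype=float)
    ambiguous = np.array([
        {e, o} in _AMBIGUOUS
        for e, o in zip(weights["effect_allele"], weights["other_allele"])
    ])
    # "strictly greater" thresholds, robust to float representation of
    # quantities like 1 - 0.999 that should sit exactly on the boundary
    def _not_above(value: float, thr: float) -> bool:
        return value <= thr or np.isclose(value, thr, rtol=1e-9, atol=1e-12)

    reasons = []
    keep = np.ones(len(weights), dtype=bool)
    for i in range(len(weights)):
        why = []
        if _not_above(maf[i], maf_min):
            why.append(f"MAF {maf[i]:.6g} <= {maf_min:g}")
        if _not_above(info[i], info_min):
            why.append(f"imputation r2 {info[i]:.6g} <= {info_min:g}")
        if ambiguous[i]:
            if drop_ambiguous:
                why.append("strand-ambiguous allele pair")
            else:
                logger.warning(
                    "retaining strand-ambiguous SNP %s (%s/%s)",
                    weights["snp_id"].iloc[i],
                    weights["effect_allele"].iloc[i],
                    weights["other_allele"].iloc[i],
                )
        if why:
            keep[i] = False
            reasons.append({"snp_id": weights["snp_id"].iloc[i],
                            "reason": "; ".join(why)})
    retained = weights.loc[keep].reset_index(drop=True)
    if retained.empty:
        logger.warning("variant filter removed every SNP")
    return retained, pd.DataFrame(reasons, columns=["snp_id", "reason"])


def align_dosages(genotypes, weights: pd.DataFrame,
                  allow_missing: bool = False) -> np.ndarray:
    """Orient dosages so every column counts the weights' effect allele.

    ``genotypes`` is either an ``(n_people, n_snps)`` array already in
    weights order and orientation, or a mapping-style object exposing
    ``snp_ids``, ``ref``, ``alt`` and ``dosages`` (as produced by
    :func:`bwvar.dataio.read_vcf`) whose ALT-allele dosages are flipped
    to ``2 - d`` wherever ALT is the weights' *other* allele.

    With ``allow_missing``, a SNP absent from the genotypes is imputed
    for everyone as ``2 * effect_allele_freq``; otherwise it is an error.
    """
    if isinstance(genotypes, np.ndarray):
        if genotypes.shape[1] != len(weights):
            raise ValueError("dosage matrix width does not match weights table")
        return np.asarray(genotypes, dtype=float)
    index = {sid: j for j, sid in enumerate(genotypes.snp_ids)}
    n_people = genotypes.dosages.shape[0]
    out = np.empty((n_people, len(weights)), dtype=float)
    for k, row in enumerate(weights.itertuples(index=False)):
        j = index.get(row.snp_id)
        if j is None:
            if allow_missing:
                out[:, k] = 2.0 * float(row.effect_allele_freq)
                continue
            raise KeyError(f"SNP {row.snp_id!r} absent from genotype data")
        ref, alt = genotypes.ref[j], genotypes.alt[j]
        d = genotypes.dosages[:, j]
        if (alt, ref) == (row.effect_allele, row.other_allele):
            out[:, k] = d
        elif (alt, ref) == (row.other_allele, row.effect_allele):
            out[:, k] = 2.0 - d
        else:
            raise ValueError(
                f"allele mismatch at {row.snp_id}: genotype file has {ref}/{alt}, "
                f"weights have {row.other_allele}/{row.effect_allele}"
            )
    return out


def compute_score(aligned_dosages: np.ndarray, weights: pd.DataFrame,
                  weight_column: str) -> np.ndarray:
    """GS = sum_i w_i g_i per person over the retained SNPs.

    Missing dosages (NaN) are imputed as twice the effect-allele
    frequency, the standard polygenic-score convention.
    """
    if weight_column not in weights.columns:
        raise KeyError(f"weights table has no column {weight_column!r}")
    w = weights[weight_column].to_numpy(dtype=float)
    if len(w) and np.all(~np.isfinite(w)):
        raise ValueError(f"all weights missing in column {weight_column!r}")
    dosages = np.asarray(aligned_dosages, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] != len(w):
        raise ValueError("aligned dosage matrix does not match weights table")
    if np.isnan(dosages).any():
        fill = 2.0 * weights["effect_allele_freq"].to_numpy(dtype=float)
        dosages = np.where(np.isnan(dosages), fill[None, :], dosages)
    return dosages @ w


def standardize(raw_scores) -> np.ndarray:
    """Center and scale to sample mean 0 / SD 1 (n-1 denominator)."""
    x = np.asarray(raw_scores, dtype=float)
    if x.size < 2:
        raise ValueError("standardization requires at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant score")
    return (x - x.mean()) / sd


def validate_score(standardized_score, phenotype) -> dict[str, float]:
    """Simple linear regression of a phenotype on its standardized score.

    Returns slope (phenotype units per 1 SD of score), its SE, t, p and
    the regression R^2 — the association check applied to each score
    against its respective phenotype.
    """
    x = np.asarray(standardized_score, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("score and phenotype must be paired 1-d arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) predictor")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "se": float(res.stderr),
        "t": float(res.slope / res.stderr) if res.stderr > 0 else float("inf"),
        "p": float(res.pvalue),
        "r2": float(res.rvalue**2),
        "n": int(len(x)),
    }
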