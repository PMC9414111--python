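"""Synthetic parent-offspring trio cohorts.

Parental genotypes are drawn under Hardy-Weinberg equilibrium, offspring
genotypes by Mendelian transmission (each parent passes one allele), so
the parent-child dosage correlation of ~0.5 expected in a real trio
cohort emerges rather than being imposed.  Birthweight on the
sex/gestational-age-adjusted scale is generated as

    bw = bw_mean + sum_j beta_j * z_j + e,   e ~ N(0, sigma_resid^2)

with each continuous predictor entered as a z-score of its configured
mean/SD (so beta_j is grams per 1 SD), binary predictors as raw 0/1, and
sigma_resid calibrated so the marginal SD of bw equals ``total_bw_sd``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BINARY_COVARIATES, SimulationConfig

__all__ = [
    "TrioGenotypes",
    "TrioCohort",
    "generate_weights_table",
    "simulate_parental_genotypes",
    "transmit_alleles",
    "simulate_covariates",
    "simulate_birthweight",
    "simulate_cohort",
]

_BASES = ("A", "C", "G", "T")
# non-strand-ambiguous allele pairs (exclude A/T and C/G)
_ALLELE_PAIRS = [
    (a, b) for a in _BASES for b in _BASES
    if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})
]


@dataclass
class TrioGenotypes:
    """Aligned effect-allele dosage matrices for a trio cohort.

    Rows are trios, columns SNPs; entries count the effect allele (0/1/2
    for simulated hard genotypes).
    """

    snp_ids: list[str]
    mother: np.ndarray
    father: np.ndarray
    child: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.mother.shape, self.father.shape, self.child.shape}
        if len(shapes) != 1:
            raise ValueError(f"dosage matrices have mismatched shapes: {shapes}")
        if self.mother.shape[1] != len(self.snp_ids):
            raise ValueError("number of SNP ids does not match dosage columns")

    @property
    def n_trios(self) -> int:
        return self.mother.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class TrioCohort:
    """A simulated cohort: per-trio phenotypes plus optional genotypes.

    ``phenotypes`` always carries trio_id, the clinical covariates, sex,
    gestational age, raw and adjusted-scale birthweight, and the three
    standardized genetic scores (true scores in direct mode, genotype-
    derived scores in genotype mode).
    """

    phenotypes: pd.DataFrame
    config: SimulationConfig
    genotypes: TrioGenotypes | None = None
    weights: pd.DataFrame | None = None

    @property
    def n_trios(self) -> int:
        return len(self.phenotypes)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_weights_table(n_snps: int, seed, allele_freqs=None,
                           weight_scale: float = 20.0) -> pd.DataFrame:
    """Synthetic variant-weights table (stand-in for a published SNP list).

    Produces ``n_snps`` biallelic, non-strand-ambiguous SNPs with
    effect-allele frequencies either as given or uniform on (0.1, 0.9),
    imputation quality uniform on (0.6, 1.0), and three per-allele weight
    columns (maternal-adjusted, fetal-adjusted, unadjusted-fetal) drawn
    N(0, weight_scale) grams, loosely mimicking GWAS effect estimates.
    """
    rng = _as_rng(seed)
    if allele_freqs is None:
        freqs = rng.uniform(0.1, 0.9, size=n_snps)
    else:
        freqs = np.asarray(allele_freqs, dtype=float)
        if len(freqs) != n_snps:
            raise ValueError("allele_freqs length does not match n_snps")
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    chrom = (np.arange(n_snps) % 22) + 1
    pos = 10_000 + 5_000 * (np.arange(n_snps) // 22 + 1)
    fetal = rng.normal(0.0, weight_scale, size=n_snps)
    return pd.DataFrame(
        {
            "snp_id": [f"rs{900000 + i}" for i in range(n_snps)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "effect_allele_freq": freqs,
            "imputation_r2": rng.uniform(0.6, 1.0, size=n_snps),
            "weight_maternal_adj": rng.normal(0.0, weight_scale, size=n_snps),
            # adjusted and unadjusted fetal weights correlated, as in practice
            "weight_fetal_adj": fetal,
            "weight_fetal_unadj": fetal + rng.normal(0.0, weight_scale / 4, size=n_snps),
        }
    )


def simulate_parental_genotypes(n_trios: int, allele_freqs, seed) -> TrioGenotypes:
    """Draw independent maternal and paternal dosages under Hardy-Weinberg.

    Each parental dosage at SNP i is Binomial(2, f_i).  The returned
    object has an all-zero child matrix placeholder; fill it with
    :func:`transmit_alleles`.
    """
    if n_trios < 1:
        raise ValueError(f"n_trios must be >= 1, got {n_trios}")
    freqs = np.asarray(allele_freqs, dtype=float)
    bad = ~np.isfinite(freqs) | (freqs <= 0.0) | (freqs >= 1.0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"allele frequency for SNP index {i} must be finite and in (0,1), "
            f"got {freqs[i]!r}"
        )
    rng = _as_rng(seed)
    mother = rng.binomial(2, freqs, size=(n_trios, len(freqs)))
    father = rng.binomial(2, freqs, size=(n_trios, len(freqs)))
    snp_ids = [f"rs{900000 + i}" for i in range(len(freqs))]
    child = np.zeros_like(mother)
    return TrioGenotypes(snp_ids=snp_ids, mother=mother, father=father, child=child)


def transmit_alleles(mother_dosages: np.ndarray, father_dosages: np.ndarray,
                     seed) -> np.ndarray:
    """Mendelian transmission: each parent contributes one allele.

    A homozygote transmits its allele deterministically; a heterozygote
    transmits the effect allele with probability 1/2.
    """
    mother = np.asarray(mother_dosages)
    father = np.asarray(father_dosages)
    for name, arr in (("mother", mother), ("father", father)):
        as_float = np.asarray(arr, dtype=float)
        if not np.all(np.isin(as_float, (0.0, 1.0, 2.0))):
            raise ValueError(
                f"{name} dosages must be integers in {{0,1,2}}; "
                "transmission is undefined for fractional dosages"
            )
    rng = _as_rng(seed)

    def contribution(parent: np.ndarray) -> np.ndarray:
        het_draw = rng.integers(0, 2, size=parent.shape)
        return np.where(parent == 2, 1, np.where(parent == 1, het_draw, 0))

    return (contribution(mother) + contribution(father)).astype(mother.dtype)


def simulate_covariates(n: int, covariate_params: dict, seed, *,
                        required: list[str] | None = None,
                        male_fraction: float = 0.522,
                        ga_mean: float = 40.1, ga_sd: float = 1.2) -> pd.DataFrame:
    """Draw mutually independent clinical covariates plus sex and GA.

    Continuous covariates are normal with the configured mean/SD; binary
    ones Bernoulli with the configured prevalence.  Offspring sex
    (male = 1) and gestational age (weeks) are always drawn so the
    downstream adjustment and term filters can be exercised.
    """
    if required:
        missing = [name for name in required if name not in covariate_params]
        if missing:
            raise ValueError(
                "no distribution parameters for covariate(s): " + ", ".join(missing)
            )
    rng = _as_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for name, params in covariate_params.items():
        if "prevalence" in params:
            cols[name] = rng.binomial(1, params["prevalence"], size=n)
        else:
            cols[name] = rng.normal(params["mean"], params["sd"], size=n)
    cols["sex_male"] = rng.binomial(1, male_fraction, size=n)
    cols["gest_age"] = rng.normal(ga_mean, ga_sd, size=n)
    return pd.DataFrame(cols)


def _systematic_component(predictors: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    parts = np.zeros(len(predictors))
    for name, beta in config.clinical_effects.items():
        if name not in predictors.columns:
            raise ValueError(f"predictor {name!r} required by clinical_effects is absent")
        x = predictors[name].to_numpy(dtype=float)
        if name in BINARY_COVARIATES or "prevalence" in config.covariate_params.get(name, {}):
            parts += beta * x
        else:
            params = config.covariate_params[name]
            parts += beta * (x - params["mean"]) / params["sd"]
    for score, beta in config.score_betas.items():
        if beta != 0.0:
            if score not in predictors.columns:
                raise ValueError(f"score {score!r} has a nonzero effect but is absent")
            parts += beta * predictors[score].to_numpy(dtype=float)
    return parts


def simulate_birthweight(predictors: pd.DataFrame, config: SimulationConfig,
                         seed) -> np.ndarray:
    """Generate adjusted-scale birthweight (g) for each trio.

    The residual SD is calibrated against the *sample* variance of the
    realized systematic component so that the marginal birthweight SD
    equals ``config.total_bw_sd`` in expectation for any admissible
    effect configuration, including genotype mode where the maternal and
    fetal scores are correlated through transmission.
    """
    rng = _as_rng(seed)
    systematic = _systematic_component(predictors, config)
    sys_var = float(np.var(systematic, ddof=1)) if len(systematic) > 1 else 0.0
    resid_var = config.total_bw_sd**2 - sys_var
    if resid_var < 0:
        raise ValueError(
            "systematic variance exceeds total_bw_sd^2 by "
            f"{-resid_var:.1f} g^2; reduce effects or raise total_bw_sd"
        )
    resid = rng.normal(0.0, np.sqrt(resid_var), size=len(systematic))
    return config.bw_mean + systematic - systematic.mean() + resid


def simulate_cohort(config: SimulationConfig, mode: str = "direct") -> TrioCohort:
    """Generate a complete trio cohort under one of the two modes.

    ``direct``  — standardized genetic scores drawn as (bivariate) normals
    with the configured maternal-fetal correlation; gives exact control of
    score-attributable variance.

    ``genotype`` — trio genotypes simulated and transmitted, a synthetic
    weights table generated, and the three scores computed through the
    score-construction pipeline before entering the birthweight model.
    """
    if mode not in ("direct", "genotype"):
        raise ValueError(f"mode must be 'direct' or 'genotype', got {mode!r}")
    rng = np.random.default_rng(config.seed)
    n = config.n_trios
    pheno = simulate_covariates(
        n, config.covariate_params, rng,
        required=[c for c in config.clinical_effects if c not in
                  ("maternal_score", "fetal_score", "paternal_score")],
        male_fraction=config.male_fraction,
        ga_mean=config.ga_mean, ga_sd=config.ga_sd,
    )
    genotypes = None
    weights = None
    if mode == "direct":
        rho = config.score_correlation
        cov = np.array([[1.0, rho], [rho, 1.0]])
        mf = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        pheno["maternal_score"] = mf[:, 0]
        pheno["fetal_score"] = mf[:, 1]
        pheno["paternal_score"] = rng.normal(0.0, 1.0, size=n)
    else:
        from . import scores as _scores

        weights = generate_weights_table(config.n_snps, rng,
                                         allele_freqs=config.allele_freqs)
        genotypes = simulate_parental_genotypes(
            n, weights["effect_allele_freq"].to_numpy(), rng
        )
        genotypes.child = transmit_alleles(genotypes.mother, genotypes.father, rng)
        pheno["maternal_score"] = _scores.standardize(
            _scores.compute_score(genotypes.mother, weights, "weight_maternal_adj")
        )
        pheno["fetal_score"] = _scores.standardize(
            _scores.compute_score(genotypes.child, weights, "weight_fetal_adj")
        )
        pheno["paternal_score"] = _scores.standardize(
            _scores.compute_score(genotypes.father, weights, "weight_fetal_unadj")
        )
    adjusted = simulate_birthweight(pheno, config, rng)
    pheno["birthweight_adj"] = adjusted
    pheno["birthweight_raw"] = (
        adjusted
        + config.sex_diff_g * (pheno["sex_male"].to_numpy() - config.male_fraction)
        + config.ga_slope_g_per_week * (pheno["gest_age"].to_numpy() - 40.0)
    )
    # parents' own self-reported birthweights: correlated with their score
    # on the fetal (direct-effect) scale, rounded to self-report precision
    own_sd = config.total_bw_sd
    pheno["maternal_own_bw"] = np.round(
        (3450.0 + 60.0 * pheno["maternal_score"].to_numpy()
         + rng.normal(0.0, np.sqrt(own_sd**2 - 60.0**2), size=n)) / 10
    ) * 10
    pheno["paternal_own_bw"] = np.round(
        (3550.0 + 70.0 * pheno["paternal_score"].to_numpy()
         + rng.normal(0.0, np.sqrt(own_sd**2 - 70.0**2), size=n)) / 10
    ) * 10
    pheno.insert(0, "trio_id", [f"F{i + 1:04d}" for i in range(n)])
    if abs(float(pheno["birthweight_adj"].std(ddof=1)) - config.total_bw_sd) > \
            5 * config.total_bw_sd / np.sqrt(2 * max(n - 1, 1)):
        warnings.warn("marginal birthweight SD drifted from total_bw_sd", stacklevel=2)
    return TrioCohort(phenotypes=pheno, config=config,
                      genotypes=genotypes, weights=weights)
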