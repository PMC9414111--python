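"""Simulation configuration and calibrated presets.

The synthetic cohort emulates a UK community-based birth cohort of
parent-offspring trios.  Marginal distributions of the clinical and
anthropometric covariates, and the per-SD effect sizes used to generate
birthweight, default to the values reported for that cohort (n = 549
trios, birthweight 3570 (444) g after sex/gestational-age adjustment).

Two generative modes are supported:

* ``direct`` — maternal/fetal (and optionally paternal) genetic scores are
  drawn directly as standardized normals, which gives exact control of the
  variance each score contributes;
* ``genotype`` — scores are computed from simulated trio genotypes through
  the score-construction pipeline, so parent-offspring genetic correlation
  emerges from Mendelian transmission.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "SimulationConfig",
    "BINARY_COVARIATES",
    "DEFAULT_COVARIATE_PARAMS",
    "MODEL_EFFECTS",
    "preset_config",
]

#: Covariates entered into design matrices as raw 0/1 indicators.
BINARY_COVARIATES = frozenset({"smoking", "parity"})

#: Marginal distributions of the covariates: continuous ones as mean/sd,
#: binary ones as prevalence.  Maternal measures are the published cohort
#: characteristics; paternal height and fasting glucose location/scale are
#: package defaults (all effects are per-SD, so they do not influence the
#: variance calibration).
DEFAULT_COVARIATE_PARAMS: dict[str, dict[str, float]] = {
    "maternal_age": {"mean": 30.0, "sd": 5.0},  # years
    "maternal_weight": {"mean": 76.3, "sd": 12.6},  # kg
    "maternal_height": {"mean": 165.0, "sd": 6.4},  # cm
    "paternal_height": {"mean": 178.0, "sd": 7.0},  # cm
    "glucose": {"mean": 4.5, "sd": 0.4},  # mmol/L, fasting, 28 weeks
    "smoking": {"prevalence": 0.146},  # 1 = smoked in pregnancy
    "parity": {"prevalence": 0.448},  # 1 = first pregnancy
}

#: Per-predictor generative effects (g per 1 SD for continuous predictors,
#: g per category for the binary indicators) for each of the seven nested
#: models, taken from the published coefficient columns.  Score entries are
#: split out of ``clinical_effects`` into the dedicated beta fields when a
#: preset config is built.
MODEL_EFFECTS: dict[str, dict[str, float]] = {
    "m1": {"maternal_score": 81.0, "fetal_score": 69.0},
    "m2": {
        "maternal_age": -38.0,
        "maternal_weight": 125.0,
        "smoking": -280.0,
        "parity": -187.0,
        "glucose": 87.0,
    },
    "m3": {
        "maternal_age": -42.0,
        "maternal_weight": 121.0,
        "smoking": -273.0,
        "parity": -194.0,
        "glucose": 85.0,
        "maternal_score": 68.0,
    },
    "m4": {
        "maternal_age": -49.0,
        "maternal_weight": 101.0,
        "smoking": -251.0,
        "parity": -210.0,
        "glucose": 104.0,
        "maternal_height": 52.0,
        "paternal_height": 69.0,
    },
    "m5": {
        "maternal_age": -50.0,
        "maternal_weight": 97.0,
        "smoking": -241.0,
        "parity": -216.0,
        "glucose": 106.0,
        "maternal_height": 49.0,
        "paternal_height": 66.0,
        "fetal_score": 56.0,
    },
    "m6": {
        "maternal_age": -54.0,
        "maternal_weight": 97.0,
        "smoking": -241.0,
        "parity": -211.0,
        "glucose": 104.0,
        "maternal_height": 44.0,
        "paternal_height": 61.0,
        "maternal_score": 57.0,
        "paternal_score": 39.0,
    },
    "m7": {
        "maternal_age": -53.0,
        "maternal_weight": 98.0,
        "smoking": -241.0,
        "parity": -217.0,
        "glucose": 101.0,
        "maternal_height": 39.0,
        "paternal_height": 64.0,
        "maternal_score": 60.0,
        "fetal_score": 57.0,
    },
}

_SCORE_NAMES = ("maternal_score", "fetal_score", "paternal_score")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic trio-cohort generator.

    Parameters
    ----------
    n_trios
        Number of mother-father-child trios (default 549).
    n_snps
        Number of score SNPs in genotype mode (default 209).
    allele_freqs
        Effect-allele frequencies, strictly in (0, 1).  ``None`` means
        draw them uniformly on (0.1, 0.9) from the seed in genotype mode.
    beta_maternal_score, beta_fetal_score, beta_paternal_score
        Birthweight change (g) per 1 SD of the respective standardized
        genetic score.
    score_correlation
        Target correlation of the standardized maternal and fetal scores
        in direct-score mode (default 0: the published marginal and joint
        R-squared values are consistent only near zero correlation).
    clinical_effects
        Map covariate name -> g per 1 SD (continuous) or g per category
        (binary).
    covariate_params
        Per-covariate mean/sd (continuous) or prevalence (binary).
    total_bw_sd, bw_mean
        Marginal SD and mean (g) of the generated, sex/GA-adjusted-scale
        birthweight.
    ga_mean, ga_sd
        Gestational-age distribution (weeks).
    male_fraction
        Probability the offspring is male.
    sex_diff_g, ga_slope_g_per_week
        Components added on top of the adjusted-scale birthweight to form
        the *raw* birthweight written to phenotype files, so the
        adjustment step downstream has real work to do.
    seed
        Base seed for all randomness.
    """

    n_trios: int = 549
    n_snps: int = 209
    allele_freqs: list[float] | None = None
    beta_maternal_score: float = 0.0
    beta_fetal_score: float = 0.0
    beta_paternal_score: float = 0.0
    score_correlation: float = 0.0
    clinical_effects: dict[str, float] = field(default_factory=dict)
    covariate_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_PARAMS.items()}
    )
    total_bw_sd: float = 444.0
    bw_mean: float = 3570.0
    ga_mean: float = 40.1
    ga_sd: float = 1.2
    male_fraction: float = 0.522
    sex_diff_g: float = 120.0
    ga_slope_g_per_week: float = 125.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_trios < 1:
            raise ValueError(f"n_trios must be >= 1, got {self.n_trios}")
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")
        if self.allele_freqs is not None:
            for i, f in enumerate(self.allele_freqs):
                if not (0.0 < float(f) < 1.0):
                    raise ValueError(
                        f"allele frequency for SNP index {i} must be in (0,1), got {f!r}"
                    )
        if not -1.0 < self.score_correlation < 1.0:
            raise ValueError("score_correlation must be in (-1, 1)")
        if self.total_bw_sd <= 0:
            raise ValueError("total_bw_sd must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        for name, params in self.covariate_params.items():
            if "prevalence" in params and not 0.0 <= params["prevalence"] <= 1.0:
                raise ValueError(f"prevalence of {name!r} must be in [0, 1]")
        missing = [
            name
            for name in self.clinical_effects
            if name not in self.covariate_params and name not in _SCORE_NAMES
        ]
        if missing:
            raise ValueError(
                "clinical_effects name covariates with no distribution parameters: "
                + ", ".join(sorted(missing))
            )

    @property
    def score_betas(self) -> dict[str, float]:
        return {
            "maternal_score": self.beta_maternal_score,
            "fetal_score": self.beta_fetal_score,
            "paternal_score": self.beta_paternal_score,
        }

    def systematic_variance_bound(self) -> float:
        """Upper bound on the systematic variance under independence.

        Continuous per-SD effects contribute beta^2; binary effects
        beta^2 * p(1-p); score effects beta^2 (unit variance), ignoring any
        score correlation (which the sample-based residual calibration
        absorbs).
        """
        var = sum(b * b for b in self.score_betas.values())
        for name, beta in self.clinical_effects.items():
            params = self.covariate_params.get(name)
            if params is None:
                continue
            if "prevalence" in params:
                p = params["prevalence"]
                var += beta * beta * p * (1.0 - p)
            else:
                var += beta * beta
        return var

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def preset_config(model_id: str, *, seed: int = 0, n_trios: int = 549,
                  overrides: Mapping[str, object] | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` calibrated to one published model.

    The generative effects are the published coefficient column of the
    requested model (``"m1"`` .. ``"m7"``); everything else keeps the
    cohort defaults.
    """
    try:
        effects = dict(MODEL_EFFECTS[model_id])
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id!r}; expected one of {sorted(MODEL_EFFECTS)}"
        ) from None
    betas = {name: effects.pop(name, 0.0) for name in _SCORE_NAMES}
    cfg = SimulationConfig(
        n_trios=n_trios,
        beta_maternal_score=betas["maternal_score"],
        beta_fetal_score=betas["fetal_score"],
        beta_paternal_score=betas["paternal_score"],
        clinical_effects=effects,
        seed=seed,
    )
    if overrides:
        cfg = cfg.replace(**dict(overrides))
    return cfg
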