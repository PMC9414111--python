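"""Monte-Carlo recovery of the published model statistics.

Each replicate draws a fresh direct-score cohort of ``n_trios`` trios
from the preset calibrated to one published model's coefficient column,
refits that model, and the statistics are averaged over replicates.
This is the machinery behind both the calibration checks in the test
suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .config import preset_config
from .models import MODEL_SPECS, fit_ols
from .simulate import simulate_cohort

__all__ = ["recover_model", "recover_model1_marginals"]


def _rep_seeds(base_seed: int, n_reps: int) -> np.ndarray:
    return np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n_reps)


def recover_model(model_id: str, n_reps: int = 300, n_trios: int = 549,
                  base_seed: int = 1) -> dict:
    """Mean R², Adj-R² and per-SD coefficients over simulated replicates."""
    predictors = MODEL_SPECS[model_id]
    r2s = np.empty(n_reps)
    adj = np.empty(n_reps)
    coefs = {name: np.empty(n_reps) for name in predictors}
    for r, seed in enumerate(_rep_seeds(base_seed, n_reps)):
        cfg = preset_config(model_id, seed=int(seed), n_trios=n_trios)
        cohort = simulate_cohort(cfg, mode="direct")
        fit = fit_ols(cohort.phenotypes, "birthweight_adj", predictors,
                      model_id=model_id)
        r2s[r] = fit.r2
        adj[r] = fit.adj_r2
        for name in predictors:
            coefs[name][r] = fit.coef[name]
    return {
        "model": model_id,
        "n_reps": n_reps,
        "n_trios": n_trios,
        "mean_r2": float(r2s.mean()),
        "mean_adj_r2": float(adj.mean()),
        "mean_coef": {k: float(v.mean()) for k, v in coefs.items()},
        "sd_r2": float(r2s.std(ddof=1)),
    }


def recover_model1_marginals(n_reps: int = 300, n_trios: int = 549,
                             base_seed: int = 1) -> dict:
    """Single-score regressions under the two-score generative model.

    Uses the joint (two-score) generative configuration, then regresses
    birthweight on each score alone — the marginal variance each score
    explains by itself.
    """
    out = {"maternal_score": np.empty(n_reps), "fetal_score": np.empty(n_reps)}
    for r, seed in enumerate(_rep_seeds(base_seed, n_reps)):
        cfg = preset_config("m1", seed=int(seed), n_trios=n_trios)
        cohort = simulate_cohort(cfg, mode="direct")
        for score in out:
            fit = fit_ols(cohort.phenotypes, "birthweight_adj", [score])
            out[score][r] = fit.r2
    return {k: float(v.mean()) for k, v in out.items()} | {
        "n_reps": n_reps, "n_trios": n_trios}
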