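"""Nested linear models for variance explained in adjusted birthweight.

Seven models of increasing scope are fitted by OLS: genetic scores only
(m1), maternal clinical characteristics (m2), clinical + maternal score
(m3), clinical + parental heights (m4), and m4 plus the fetal score
(m5), parental scores (m6) or both maternal and fetal scores (m7).
Continuous predictors are scaled by their analysis-sample SD before
fitting so coefficients read as grams per 1 SD; binary predictors enter
as raw 0/1 indicators.  Model improvement is judged by Adj-R² and nested
F-tests; R² uncertainty by a nonparametric case-resampling percentile
bootstrap; multicollinearity by variance inflation factors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import BINARY_COVARIATES

__all__ = [
    "MODEL_SPECS",
    "NESTED_PAIRS",
    "ModelFit",
    "NestedTest",
    "BootstrapCI",
    "SuiteResult",
    "fit_ols",
    "adjusted_r2",
    "nested_f_test",
    "bootstrap_r2",
    "vif",
    "residual_diagnostics",
    "run_model_suite",
]

logger = logging.getLogger(__name__)

#: Ordered predictor lists of the seven models (order follows the model
#: formulas: glucose + age + weight + parity + smoking + ...).
MODEL_SPECS: dict[str, list[str]] = {
    "m1": ["maternal_score", "fetal_score"],
    "m2": ["glucose", "maternal_age", "maternal_weight", "parity", "smoking"],
    "m3": ["glucose", "maternal_age", "maternal_weight", "parity", "smoking",
           "maternal_score"],
    "m4": ["glucose", "maternal_age", "maternal_weight", "parity", "smoking",
           "maternal_height", "paternal_height"],
    "m5": ["glucose", "maternal_age", "maternal_weight", "parity", "smoking",
           "maternal_height", "paternal_height", "fetal_score"],
    "m6": ["glucose", "maternal_age", "maternal_weight", "parity", "smoking",
           "maternal_height", "paternal_height", "maternal_score",
           "paternal_score"],
    "m7": ["glucose", "maternal_age", "maternal_weight", "parity", "smoking",
           "maternal_height", "paternal_height", "fetal_score",
           "maternal_score"],
}

#: Model extensions adding parents' own (self-reported) birthweights,
#: fitted on the subsample where both are recorded.
EXTENSION_SPECS: dict[str, list[str]] = {
    "m4_parentbw": MODEL_SPECS["m4"] + ["maternal_own_bw", "paternal_own_bw"],
    "m5_parentbw": MODEL_SPECS["m4"] + ["maternal_own_bw", "paternal_own_bw",
                                        "fetal_score"],
}

#: The nested comparisons reported: (full, reduced).
NESTED_PAIRS: list[tuple[str, str]] = [
    ("m3", "m2"), ("m4", "m2"), ("m5", "m4"), ("m6", "m4"), ("m7", "m4"),
]

DEFAULT_OUTCOME = "birthweight_adj"


@dataclass
class ModelFit:
    """One fitted model with per-SD coefficients and fit statistics."""

    model_id: str
    outcome: str
    predictors: list[str]
    coef: pd.Series  # includes 'intercept'; g per 1 SD (continuous) / per category
    se: pd.Series
    t: pd.Series
    p: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    r2: float
    adj_r2: float
    rss: float
    n: int
    df_resid: int
    scales: dict[str, float]  # SD divisor applied per continuous predictor
    fitted: np.ndarray = field(repr=False, default=None)
    resid: np.ndarray = field(repr=False, default=None)

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    def table(self) -> pd.DataFrame:
        """Coefficient table in the reporting layout."""
        names = ["intercept"] + self.predictors
        return pd.DataFrame({
            "variable": names,
            "coef_g_per_sd": [self.coef[v] for v in names],
            "ci_low": [self.ci_low[v] for v in names],
            "ci_high": [self.ci_high[v] for v in names],
            "t": [self.t[v] for v in names],
            "p": [self.p[v] for v in names],
        })


@dataclass
class NestedTest:
    reduced: str
    full: str
    f: float
    df1: int
    df2: int
    p: float


@dataclass
class BootstrapCI:
    statistic: str
    point: float
    lower: float
    upper: float
    level: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("bootstrap interval has lower > upper")


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        scale = np.linalg.norm(X[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            bad.append(names[j])
    return bad


def _design(data: pd.DataFrame, predictors: list[str],
            binary=BINARY_COVARIATES, scales: dict[str, float] | None = None
            ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-SD-scaled design matrix with intercept; returns applied scales."""
    used: dict[str, float] = {}
    X = pd.DataFrame(index=data.index)
    X["intercept"] = 1.0
    for name in predictors:
        x = data[name].to_numpy(dtype=float)
        if name in binary:
            used[name] = 1.0
            X[name] = x
        else:
            sd = (scales or {}).get(name)
            if sd is None:
                sd = float(np.std(x, ddof=1))
            if sd <= 0 or not np.isfinite(sd):
                raise ValueError(f"predictor {name!r} has non-positive SD")
            used[name] = sd
            X[name] = x / sd
    return X, used


def fit_ols(data: pd.DataFrame, outcome: str, predictors: list[str],
            model_id: str = "", binary=BINARY_COVARIATES,
            scales: dict[str, float] | None = None,
            ci_level: float = 0.95) -> ModelFit:
    """Fit one model by OLS with per-SD predictor scaling.

    Continuous predictors are divided by their sample SD (or a supplied
    cohort-wide SD) so coefficients report grams per 1 SD; binary
    predictors stay 0/1.  SEs are classical; coefficient CIs use the t
    distribution with residual df.  Rank-deficient designs are rejected
    with the collinear columns named.
    """
    y = data[outcome].to_numpy(dtype=float)
    X, used_scales = _design(data, predictors, binary, scales)
    n, p1 = X.shape
    if n <= p1:
        raise ValueError(f"n = {n} too small for {p1 - 1} predictors")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < p1:
        bad = _collinear_columns(Xv, list(X.columns))
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=1 - ci_level)
    return ModelFit(
        model_id=model_id or "+".join(predictors),
        outcome=outcome,
        predictors=list(predictors),
        coef=res.params,
        se=res.bse,
        t=res.tvalues,
        p=res.pvalues,
        ci_low=ci[0],
        ci_high=ci[1],
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        rss=float(res.ssr),
        n=int(n),
        df_resid=int(res.df_resid),
        scales=used_scales,
        fitted=np.asarray(res.fittedvalues),
        resid=np.asarray(res.resid),
    )


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adj-R² = 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n = {n}, p = {p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def nested_f_test(fit_reduced: ModelFit, fit_full: ModelFit) -> NestedTest:
    """F-test comparing nested models from their residual sums of squares."""
    if fit_reduced.outcome != fit_full.outcome or fit_reduced.n != fit_full.n:
        raise ValueError("nested models must share outcome and sample")
    if not set(fit_reduced.predictors) < set(fit_full.predictors):
        raise ValueError(
            f"model {fit_reduced.model_id!r} is not nested in {fit_full.model_id!r}"
        )
    df1 = fit_full.n_predictors - fit_reduced.n_predictors
    df2 = fit_full.n - fit_full.n_predictors - 1
    f = ((fit_reduced.rss - fit_full.rss) / df1) / (fit_full.rss / df2)
    f = max(f, 0.0)  # guard tiny negative rounding
    p = float(stats.f.sf(f, df1, df2))
    return NestedTest(reduced=fit_reduced.model_id, full=fit_full.model_id,
                      f=float(f), df1=df1, df2=df2, p=p)


def bootstrap_r2(data: pd.DataFrame, outcome: str, predictors: list[str],
                 n_boot: int = 1000, level: float = 0.95, seed: int = 0,
                 statistic: str = "", max_retries: int = 100) -> BootstrapCI:
    """Percentile bootstrap CI for a model's R² by case resampling.

    Trios are resampled with replacement and the model refitted per
    resample (streamlined least-squares path: R² is scale-invariant, so
    per-SD rescaling is skipped).  Rank-deficient resamples are redrawn
    up to ``max_retries`` times.  Deterministic given the seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    y = data[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y))]
                        + [data[c].to_numpy(dtype=float) for c in predictors])
    n, p1 = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    point = _r2_of(y, X, beta)
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, n, size=n)
            Xb, yb = X[idx], y[idx]
            if np.linalg.matrix_rank(Xb) == p1:
                break
        else:
            raise RuntimeError("bootstrap resamples persistently rank deficient")
        bb, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        vals[b] = _r2_of(yb, Xb, bb)
    alpha = 1.0 - level
    lower, upper = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return BootstrapCI(statistic=statistic or f"R2({'+'.join(predictors)})",
                       point=float(point), lower=float(lower),
                       upper=float(upper), level=level, n_boot=n_boot, seed=seed)


def _r2_of(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 1.0
    return 1.0 - float(resid @ resid) / tss


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1/(1 − R²_j).

    ``design`` holds the non-intercept predictor columns.  R²_j comes
    from regressing column j on all the others (with intercept).
    Perfectly collinear predictors are reported as ``inf`` with the most
    correlated partner logged.
    """
    cols = [c for c in design.columns if c != "intercept"]
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 non-intercept predictors")
    X = design[cols].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(cols):
        others = np.column_stack([np.ones(len(X))] + [X[:, k] for k in range(X.shape[1]) if k != j])
        bj, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        r2j = _r2_of(X[:, j], others, bj)
        if r2j >= 1.0 - 1e-12:
            corr = [abs(np.corrcoef(X[:, j], X[:, k])[0, 1])
                    for k in range(X.shape[1]) if k != j]
            partner = [c for c in cols if c != name][int(np.argmax(corr))]
            logger.warning("predictor %r is perfectly collinear (e.g. with %r)",
                           name, partner)
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2j)
    return pd.Series(out)


def residual_diagnostics(fit: ModelFit) -> dict:
    """Residual/fitted pairs plus simple summaries for diagnostic plots."""
    resid, fitted = fit.resid, fit.fitted
    slope = float(np.polyfit(fitted, np.abs(resid), 1)[0]) if len(resid) > 2 else np.nan
    return {
        "fitted": fitted,
        "resid": resid,
        "resid_skew": float(stats.skew(resid)),
        "abs_resid_on_fitted_slope": slope,
        "resid_mean": float(resid.mean()),
    }


@dataclass
class SuiteResult:
    """Fits, nested tests and bootstrap CIs for the whole model sequence."""

    fits: dict[str, ModelFit]
    nested: list[NestedTest]
    bootstrap: dict[str, BootstrapCI]
    vifs: dict[str, pd.Series]
    skipped: dict[str, str]
    n: int

    def fig_series(self) -> pd.DataFrame:
        """R² with bootstrap CI per model — the model-summary plot data."""
        rows = []
        for mid, f in self.fits.items():
            ci = self.bootstrap.get(mid)
            rows.append({"model": mid, "r2": f.r2,
                         "ci_low": ci.lower if ci else np.nan,
                         "ci_high": ci.upper if ci else np.nan})
        return pd.DataFrame(rows)

    def to_summary(self) -> dict:
        """JSON-serializable run summary (every reported number lives here)."""
        return {
            "n": self.n,
            "models": {
                mid: {
                    "predictors": f.predictors,
                    "coefficients": f.table().to_dict(orient="records"),
                    "r2": f.r2,
                    "adj_r2": f.adj_r2,
                    "rss": f.rss,
                    "n": f.n,
                    "df_resid": f.df_resid,
                }
                for mid, f in self.fits.items()
            },
            "nested_tests": [vars(t) for t in self.nested],
            "bootstrap": {mid: vars(ci) for mid, ci in self.bootstrap.items()},
            "vif": {mid: v.to_dict() for mid, v in self.vifs.items()},
            "skipped": self.skipped,
        }


def run_model_suite(data: pd.DataFrame, outcome: str = DEFAULT_OUTCOME,
                    n_boot: int = 1000, level: float = 0.95, seed: int = 0,
                    include_extensions: bool = True) -> SuiteResult:
    """Fit the seven nested models with comparisons and bootstrap CIs.

    Models whose predictors are absent from ``data`` are skipped with a
    logged reason; nested tests and CIs are produced for whatever ran.
    Parental-own-birthweight extensions run on the subsample with both
    parents' birthweights recorded, when those columns exist.
    """
    scales = {
        name: float(np.std(data[name].to_numpy(dtype=float), ddof=1))
        for spec in MODEL_SPECS.values() for name in spec
        if name in data.columns and name not in BINARY_COVARIATES
    }
    fits: dict[str, ModelFit] = {}
    skipped: dict[str, str] = {}
    boot: dict[str, BootstrapCI] = {}
    vifs: dict[str, pd.Series] = {}
    rng = np.random.default_rng(seed)
    for mid, predictors in MODEL_SPECS.items():
        missing = [c for c in predictors if c not in data.columns]
        if missing:
            skipped[mid] = f"missing predictor(s): {', '.join(missing)}"
            logger.info("skipping %s: %s", mid, skipped[mid])
            continue
        fits[mid] = fit_ols(data, outcome, predictors, model_id=mid, scales=scales)
        boot[mid] = bootstrap_r2(data, outcome, predictors, n_boot=n_boot,
                                 level=level, seed=int(rng.integers(2**31)),
                                 statistic=f"R2({mid})")
        if len(predictors) >= 2:
            vifs[mid] = vif(data[predictors])
    nested = [nested_f_test(fits[r], fits[f])
              for f, r in NESTED_PAIRS if f in fits and r in fits]
    # nested-R2 monotonicity must hold by construction
    for f_id, r_id in NESTED_PAIRS:
        if f_id in fits and r_id in fits:
            assert fits[f_id].r2 >= fits[r_id].r2 - 1e-12, (f_id, r_id)
    if include_extensions and {"maternal_own_bw", "paternal_own_bw"} <= set(data.columns):
        sub = data.dropna(subset=["maternal_own_bw", "paternal_own_bw"])
        sub_scales = dict(scales)
        for extra in ("maternal_own_bw", "paternal_own_bw"):
            sub_scales[extra] = float(np.std(sub[extra].to_numpy(dtype=float), ddof=1))
        for mid, predictors in EXTENSION_SPECS.items():
            missing = [c for c in predictors if c not in sub.columns]
            if missing:
                skipped[mid] = f"missing predictor(s): {', '.join(missing)}"
                continue
            fits[mid] = fit_ols(sub, outcome, predictors, model_id=mid,
                                scales=sub_scales)
    return SuiteResult(fits=fits, nested=nested, bootstrap=boot, vifs=vifs,
                       skipped=skipped, n=len(data))
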