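"""Analysis-cohort preparation.

Raw birthweight is adjusted for offspring sex and gestational age,
centred at 40 weeks — either against an external sex/week reference
table of birthweight means and SDs (z-score at the observed week,
rescaled to the 40-week distribution) or, by default, internally via an
OLS residual.  Trios are then restricted to term births (37 <= GA < 42
weeks) with complete phenotype and three-way genotype data, and the
included and excluded groups are compared with t and chi-square tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GestAgeReference",
    "adjust_birthweight",
    "filter_term",
    "filter_complete",
    "compare_cohorts",
]

TERM_MIN_WEEKS = 37.0
TERM_MAX_WEEKS = 42.0  # exclusive


class GestAgeReference:
    """Sex- and week-specific reference means/SDs of birthweight (g).

    Built from a table with columns sex ('male'/'female'), week (integer),
    mean_g, sd_g.  Lookup uses the floor integer week of a decimal
    gestational age.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "week", "mean_g", "sd_g"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"reference table missing column(s): {sorted(missing)}")
        if (table["sd_g"] <= 0).any():
            raise ValueError("reference SDs must be positive everywhere")
        self._lookup = {
            (str(r.sex), int(r.week)): (float(r.mean_g), float(r.sd_g))
            for r in table.itertuples(index=False)
        }

    @classmethod
    def from_tsv(cls, path) -> "GestAgeReference":
        return cls(pd.read_csv(path, sep="\t"))

    def mean_sd(self, sex: str, week: int) -> tuple[float, float]:
        try:
            return self._lookup[(sex, int(week))]
        except KeyError:
            raise KeyError(f"reference table does not cover sex={sex!r}, week={week}") from None


def adjust_birthweight(records: pd.DataFrame, mode: str = "internal",
                       reference: GestAgeReference | None = None,
                       quadratic_ga: bool = False) -> np.ndarray:
    """Adjust raw birthweight for sex and gestational age, centred at 40 weeks.

    ``internal`` regresses raw birthweight on a male indicator and
    (GA - 40) (optionally plus its square) and returns the residual plus
    the fitted value at GA = 40 with sex at its sample mean, so the
    adjusted values stay on the gram scale and are uncorrelated with sex
    and GA.  ``reference`` converts each birthweight to a z-score in its
    sex/week reference distribution and maps it onto the same sex's
    40-week distribution.
    """
    bw = records["birthweight_raw"].to_numpy(dtype=float)
    ga = records["gest_age"].to_numpy(dtype=float)
    male = records["sex_male"].to_numpy(dtype=float)
    if mode == "internal":
        cols = [np.ones_like(bw), male, ga - 40.0]
        if quadratic_ga:
            cols.append((ga - 40.0) ** 2)
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, bw, rcond=None)
        resid = bw - X @ beta
        return resid + beta[0] + beta[1] * male.mean()
    if mode == "reference":
        if reference is None:
            raise ValueError("reference mode requires a GestAgeReference")
        out = np.empty_like(bw)
        for i in range(len(bw)):
            sex = "male" if male[i] == 1 else "female"
            week = int(np.floor(ga[i]))
            try:
                mean_w, sd_w = reference.mean_sd(sex, week)
            except KeyError:
                raise ValueError(
                    f"record {i} (GA {ga[i]:.1f} weeks) outside reference coverage"
                ) from None
            mean_40, sd_40 = reference.mean_sd(sex, 40)
            z = (bw[i] - mean_w) / sd_w
            out[i] = mean_40 + z * sd_40
        return out
    raise ValueError(f"mode must be 'internal' or 'reference', got {mode!r}")


def filter_term(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep term births: 37.0 <= GA < 42.0 weeks (closed-left, open-right)."""
    ga = records["gest_age"].to_numpy(dtype=float)
    keep = (ga >= TERM_MIN_WEEKS) & (ga < TERM_MAX_WEEKS)
    log = pd.DataFrame({
        "trio_id": records.loc[~keep, "trio_id"]
        if "trio_id" in records.columns else records.index[~keep],
        "reason": np.where(ga[~keep] < TERM_MIN_WEEKS,
                           "preterm (<37 weeks)", "post-term (>=42 weeks)"),
    })
    return records.loc[keep].reset_index(drop=True), log.reset_index(drop=True)


def filter_complete(records: pd.DataFrame,
                    genotyped: dict[str, set] | None = None,
                    required_fields: list[str] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep trios with all required fields and all three genotypes.

    ``genotyped`` maps role ('mother'/'father'/'child') to the set of
    trio_ids with genotype data for that member; ``None`` for a role (or
    entirely) means genotypes are taken as available.  ``required_fields``
    lists phenotype columns that must be non-missing.  Returns the
    retained records and an exclusion log with one reason per dropped
    trio (first failing check wins: genotype roles in order, then fields).
    """
    genotyped = genotyped or {}
    required_fields = required_fields or []
    missing_cols = [c for c in required_fields if c not in records.columns]
    if missing_cols:
        raise ValueError(f"required field(s) absent from records: {missing_cols}")
    reasons = []
    keep = np.ones(len(records), dtype=bool)
    ids = records["trio_id"] if "trio_id" in records.columns else records.index
    for i, tid in enumerate(ids):
        for role in ("mother", "father", "child"):
            avail = genotyped.get(role)
            if avail is not None and tid not in avail:
                keep[i] = False
                reasons.append({"trio_id": tid, "reason": f"missing {role} genotype"})
                break
        else:
            for field in required_fields:
                if pd.isna(records[field].iloc[i]):
                    keep[i] = False
                    reasons.append({"trio_id": tid, "reason": f"missing {field}"})
                    break
    return (records.loc[keep].reset_index(drop=True),
            pd.DataFrame(reasons, columns=["trio_id", "reason"]))


def compare_cohorts(included: pd.DataFrame, excluded: pd.DataFrame,
                    continuous: list[str] = (), categorical: list[str] = (),
                    equal_var: bool = False, correction: bool = False
                    ) -> pd.DataFrame:
    """Compare included vs excluded participants variable by variable.

    Continuous variables get a two-sample t-test (Welch by default,
    pooled-variance with ``equal_var=True``); categorical ones a
    chi-square test on the contingency table (no continuity correction by
    default).  A variable empty in either group is marked not-testable
    rather than raising.
    """
    rows = []
    for var in continuous:
        a = included[var].dropna().to_numpy(dtype=float)
        b = excluded[var].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            rows.append({"variable": var, "test": "t", "statistic": np.nan,
                         "df": np.nan, "p": np.nan, "testable": False})
            continue
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        df = (len(a) + len(b) - 2) if equal_var else float(res.df)
        rows.append({"variable": var, "test": "t",
                     "statistic": float(res.statistic), "df": df,
                     "p": float(res.pvalue), "testable": True})
    for var in categorical:
        a = included[var].dropna()
        b = excluded[var].dropna()
        if a.empty or b.empty:
            rows.append({"variable": var, "test": "chi2", "statistic": np.nan,
                         "df": np.nan, "p": np.nan, "testable": False})
            continue
        levels = sorted(set(a) | set(b))
        table = np.array([[int((g == lv).sum()) for lv in levels] for g in (a, b)])
        if table.shape[1] < 2:  # a single observed level carries no signal
            rows.append({"variable": var, "test": "chi2", "statistic": 0.0,
                         "df": 0, "p": 1.0, "testable": False})
            continue
        chi2, p, df, _ = stats.chi2_contingency(table, correction=correction)
        rows.append({"variable": var, "test": "chi2", "statistic": float(chi2),
                     "df": int(df), "p": float(p), "testable": True})
    return pd.DataFrame(rows)
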