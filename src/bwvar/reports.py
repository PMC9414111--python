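"""Human-readable rendering of a run summary.

Every number printed comes straight from the JSON summary — nothing is
recomputed at render time, so a report regenerated from the same summary
is byte-identical.
"""

from __future__ import annotations

__all__ = ["render_report"]

_MODEL_TITLES = {
    "m1": "Model 1: maternal + fetal genetic scores",
    "m2": "Model 2: maternal clinical characteristics",
    "m3": "Model 3: clinical + maternal genetic score",
    "m4": "Model 4: clinical + parental heights",
    "m5": "Model 5: clinical + heights + fetal genetic score",
    "m6": "Model 6: clinical + heights + maternal & paternal genetic scores",
    "m7": "Model 7: clinical + heights + fetal & maternal genetic scores",
    "m4_parentbw": "Extension: Model 4 + parents' own birthweights",
    "m5_parentbw": "Extension: Model 4 + parents' own birthweights + fetal score",
}


def _fmt(x, nd=2) -> str:
    if x is None:
        return "NA"
    return f"{x:.{nd}f}"


def render_report(summary: dict) -> str:
    """Render model tables, nested tests and R² intervals as aligned text."""
    lines: list[str] = []
    models = summary.get("models", {})
    if not models:
        lines.append("(no fitted models in summary)")
    for mid, m in models.items():
        lines.append(_MODEL_TITLES.get(mid, mid))
        lines.append(f"  n = {m['n']}; R2 = {m['r2']:.3f}; Adj-R2 = {m['adj_r2']:.3f}")
        lines.append(f"  {'variable':<18}{'g per 1 SD':>12}{'95% CI':>20}"
                     f"{'t':>8}{'p':>11}")
        for row in m["coefficients"]:
            ci = f"{_fmt(row['ci_low'], 0)}, {_fmt(row['ci_high'], 0)}"
            lines.append(f"  {row['variable']:<18}{_fmt(row['coef_g_per_sd'], 0):>12}"
                         f"{ci:>20}{_fmt(row['t'], 1):>8}{row['p']:>11.2g}")
        lines.append("")
    nested = summary.get("nested_tests", [])
    if nested:
        lines.append("Nested model comparisons (F-tests)")
        for t in nested:
            lines.append(f"  {t['full']} vs {t['reduced']}: "
                         f"F({t['df1']},{t['df2']}) = {t['f']:.2f}, p = {t['p']:.2g}")
        lines.append("")
    boot = summary.get("bootstrap", {})
    if boot:
        lines.append("R2 with bootstrap percentile CIs")
        for mid, ci in boot.items():
            lines.append(f"  {mid}: R2 = {ci['point']:.3f} "
                         f"[{ci['lower']:.3f}, {ci['upper']:.3f}] "
                         f"({ci['level']:.0%}, B = {ci['n_boot']})")
        lines.append("")
    sens = summary.get("sensitivity")
    if sens:
        lines.append(f"Sensitivity refit (MAF > {sens['maf_min']:g}, "
                     f"info > {sens['info_min']:g}): R2 deltas")
        for mid, d in sens["r2_delta"].items():
            lines.append(f"  {mid}: {d:+.4f}")
        lines.append("")
    return "\n".join(lines) + "\n"
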