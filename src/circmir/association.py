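"""Association testing between miRNA expression and clinical variables.

Test choice follows common biomarker-study practice: a Kolmogorov-Smirnov
normality check (Lilliefors-corrected, Monte-Carlo null), log10
transformation when non-normal, then Welch's t / Mann-Whitney U for two
groups, one-way ANOVA across factor levels and Pearson / Spearman
correlation for continuous covariates. Raw p < 0.05 is the significance
convention; an optional Benjamini-Hochberg adjustment is available but off
by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "NormalityResult",
    "normality_gate",
    "compare_two_groups",
    "anova_across_levels",
    "correlate",
    "benjamini_hochberg",
    "associate_expression",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    mirna_id: str
    variable: str
    test_name: str  # t, mann_whitney, anova, pearson, spearman
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    transform_applied: str = "none"  # none or log10


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    normal: bool
    recommendation: str  # none | log10 | nonparametric


# Monte-Carlo Lilliefors null distributions, cached per (n, n_sim, seed)
_LILLIEFORS_NULL: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_stat(x: np.ndarray) -> float:
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return 1.0
    return stats.kstest(x, "norm", args=(mu, sd)).statistic


def _lilliefors_null(n: int, n_sim: int, seed: int) -> np.ndarray:
    key = (n, n_sim, seed)
    if key not in _LILLIEFORS_NULL:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_sim, n))
        mu = draws.mean(axis=1, keepdims=True)
        sd = draws.std(axis=1, ddof=1, keepdims=True)
        z = np.sort((draws - mu) / sd, axis=1)
        grid = stats.norm.cdf(z)
        k = (np.arange(1, n + 1)) / n
        km = (np.arange(n)) / n
        d = np.maximum(np.abs(grid - k), np.abs(grid - km)).max(axis=1)
        _LILLIEFORS_NULL[key] = np.sort(d)
    return _LILLIEFORS_NULL[key]


def normality_gate(values: Sequence[float], *, alpha: float = ALPHA,
                   n_sim: int = 10_000, seed: int = 0,
                   allow_log: bool = True) -> NormalityResult:
    """Lilliefors-corrected KS normality test with a simulated null.

    The KS distance to a normal with estimated mean/SD is compared against
    ``n_sim`` seeded Monte-Carlo draws of the same size (the estimation step
    makes standard KS tables anti-conservative — the Lilliefors correction).
    Non-normal samples of positive values get a log10 recommendation; if the
    logged values are still non-normal, nonparametric tests are recommended.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 4:
        raise ValueError("normality test needs at least 4 observations")
    null = _lilliefors_null(len(x), n_sim, seed)
    d = _lilliefors_stat(x)
    p = float((len(null) - np.searchsorted(null, d, side="left") + 1) / (len(null) + 1))
    if p >= alpha:
        return NormalityResult(d, p, True, "none")
    if allow_log and np.all(x > 0):
        d2 = _lilliefors_stat(np.log10(x))
        p2 = float((len(null) - np.searchsorted(null, d2, side="left") + 1) / (len(null) + 1))
        if p2 >= alpha:
            return NormalityResult(d, p, False, "log10")
    return NormalityResult(d, p, False, "nonparametric")


def _clean(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    return x[~np.isnan(x)]


def compare_two_groups(values_a: Sequence[float], values_b: Sequence[float],
                       mode: str = "auto", *, mirna_id: str = "",
                       variable: str = "group", seed: int = 0,
                       n_sim: int = 10_000) -> TestResult:
    """Two-group comparison: Welch's t or Mann-Whitney U, two-sided.

    ``auto`` applies the normality gate to each group (with the shared log10
    option) and uses Welch's t only when both pass — on log10 values if that
    is what the gate recommended for either group; otherwise Mann-Whitney.
    The U test is exact when both groups have n ≤ 8 with no ties, and uses
    the tie- and continuity-corrected normal approximation otherwise.
    """
    a, b = _clean(values_a), _clean(values_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    transform = "none"

    if len(np.unique(np.concatenate([a, b]))) == 1:
        warnings.warn("all values identical in both groups; p = 1")
        name = "t" if mode == "t" else "mann_whitney"
        center = 0.0 if name == "t" else len(a) * len(b) / 2.0
        return TestResult(mirna_id, variable, name, center, 1.0,
                          (len(a), len(b)), transform)

    use_t = mode == "t"
    if mode == "auto":
        ga = normality_gate(a, seed=seed, n_sim=n_sim)
        gb = normality_gate(b, seed=seed, n_sim=n_sim)
        recs = {ga.recommendation, gb.recommendation}
        if recs <= {"none"}:
            use_t = True
        elif "nonparametric" not in recs and np.all(a > 0) and np.all(b > 0):
            a, b = np.log10(a), np.log10(b)
            transform = "log10"
            use_t = True

    if use_t:
        res = stats.ttest_ind(a, b, equal_var=False)
        return TestResult(mirna_id, variable, "t", float(res.statistic),
                          float(res.pvalue), (len(a), len(b)), transform)

    exact = len(a) <= 8 and len(b) <= 8 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return TestResult(mirna_id, variable, "mann_whitney", float(res.statistic),
                      float(res.pvalue), (len(a), len(b)), "none")


def anova_across_levels(values: Sequence[float], factor: Sequence,
                        *, mirna_id: str = "", variable: str = "factor",
                        log10: bool | None = None, seed: int = 0,
                        n_sim: int = 10_000) -> TestResult:
    """One-way fixed-effects ANOVA of expression across factor levels.

    Missing values/levels are dropped pairwise; empty levels are discarded.
    With ``log10=None`` the normality gate on the pooled values decides the
    transform. Exactly two usable levels reduce to the pooled-variance
    special case where F = t².
    """
    x = np.asarray(values, dtype=float)
    f = pd.Series(list(factor)).astype(object).to_numpy()
    ok = ~np.isnan(x) & pd.notna(f) & (f != "missing")
    x, f = x[ok], f[ok]
    groups = [x[f == lev] for lev in pd.unique(f)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 non-empty levels")
    transform = "none"
    if log10 is None:
        gate = normality_gate(x, seed=seed, n_sim=n_sim) if len(x) >= 4 else None
        log10 = gate is not None and gate.recommendation == "log10"
    if log10:
        if np.any(x <= 0):
            raise ValueError("log10 transform requested with non-positive values")
        groups = [np.log10(g) for g in groups]
        transform = "log10"
    stat, p = stats.f_oneway(*groups)
    return TestResult(mirna_id, variable, "anova", float(stat), float(p),
                      tuple(len(g) for g in groups), transform)


def correlate(expression: Sequence[float], covariate: Sequence[float],
              mode: str = "auto", *, mirna_id: str = "",
              variable: str = "covariate", seed: int = 0,
              n_sim: int = 10_000) -> TestResult:
    """Pearson or Spearman correlation on paired observations.

    ``auto`` uses Pearson when both vectors pass the normality gate
    (expression optionally on the log10 scale), else Spearman's rho.
    Missing values are dropped pairwise.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(covariate, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("correlation needs at least 4 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    transform = "none"
    use_pearson = mode == "pearson"
    if mode == "auto":
        gx = normality_gate(x, seed=seed, n_sim=n_sim)
        gy = normality_gate(y, seed=seed, n_sim=n_sim)
        x_ok = gx.normal
        if gx.recommendation == "log10":
            x = np.log10(x)
            transform = "log10"
            x_ok = True
        use_pearson = x_ok and gy.normal
    if use_pearson:
        r, p = stats.pearsonr(x, y)
        return TestResult(mirna_id, variable, "pearson", float(r), float(p),
                          (len(x),), transform)
    rho, p = stats.spearmanr(x, y)
    return TestResult(mirna_id, variable, "spearman", float(rho), float(p),
                      (len(x),), "none")


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (step-up FDR); optional, off by default upstream."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def associate_expression(expression, sample_sheet: pd.DataFrame, *,
                         seed: int = 0, n_sim: int = 2_000,
                         adjust: bool = False) -> pd.DataFrame:
    """Run the standard association battery for every miRNA in a table.

    Per miRNA: case vs control comparison; ANOVA across case grade and
    stage; case-vs-control within nodal strata; correlation with invasive
    and whole tumour size. Returns one tidy row per (miRNA, variable, test).
    """
    from .qpcr import ExpressionTable

    if isinstance(expression, ExpressionTable):
        nrq = expression.nrq.drop(columns=[expression.reference_mirna])
    else:
        nrq = expression
    sheet = sample_sheet.set_index("sample_id")
    common = [s for s in nrq.index if s in sheet.index]
    nrq = nrq.loc[common]
    sheet = sheet.loc[common]
    is_case = sheet["group"] == "case"
    is_ctrl = sheet["group"] == "control"

    results: list[TestResult] = []
    for m in nrq.columns:
        v = nrq[m]
        try:
            results.append(compare_two_groups(v[is_case], v[is_ctrl], "auto",
                                              mirna_id=m, variable="group", seed=seed,
                                              n_sim=n_sim))
        except ValueError:
            pass
        for factor in ("grade", "stage"):
            lv = sheet.loc[is_case, factor]
            vv = v[is_case]
            try:
                results.append(anova_across_levels(vv, lv, mirna_id=m,
                                                   variable=factor, seed=seed,
                                                   n_sim=n_sim))
            except ValueError:
                pass
        for status in ("positive", "negative"):
            sel = is_case & (sheet["nodal_status"] == status)
            try:
                results.append(compare_two_groups(v[sel], v[is_ctrl], "auto",
                                                  mirna_id=m,
                                                  variable=f"nodal_{status}_vs_control",
                                                  seed=seed, n_sim=n_sim))
            except ValueError:
                pass
        for size_col in ("invasive_size_mm", "whole_size_mm"):
            try:
                results.append(correlate(v[is_case], sheet.loc[is_case, size_col],
                                         mirna_id=m, variable=size_col, seed=seed,
                                         n_sim=n_sim))
            except ValueError:
                pass

    frame = pd.DataFrame([r.__dict__ for r in results])
    if adjust and not frame.empty:
        frame["p_adjusted_bh"] = benjamini_hochberg(frame["p_value"].to_numpy())
    return frame
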