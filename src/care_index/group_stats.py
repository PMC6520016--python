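"""Group comparisons and change-score regressions.

Covers the baseline demographic/neuropsychological contrasts (two-sample
t with a Levene equal-variance gate, 2x2 chi-square, Mann-Whitney U on
stage distributions) and multiple linear regressions of longitudinal
change in outcomes on change in the CARE index, Benjamini-Hochberg
corrected across outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupTestResult:
    variable: str
    test: str  # pooled-t | welch-t | chi-square | mann-whitney
    statistic: float
    p_value: float
    summary: dict

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variance_rule: str = "auto",
    variable: str = "",
) -> GroupTestResult:
    """Two-sample t-test; the statistic's sign follows mean(x) - mean(y).

    ``variance_rule="auto"`` runs Levene's test (mean-centered) at alpha
    0.05 and uses the pooled-variance t when it is non-significant, Welch
    otherwise — the gate commonly applied by point-and-click statistics
    packages, and the mix needed to reproduce published tables where some
    rows are pooled and some Welch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if variance_rule == "auto":
        _, lev_p = stats.levene(x, y, center="mean")
        rule = "pooled" if lev_p >= 0.05 else "welch"
    elif variance_rule in ("pooled", "welch"):
        rule = variance_rule
    else:
        raise ValueError(f"unknown variance_rule {variance_rule!r}")
    t, p = stats.ttest_ind(x, y, equal_var=(rule == "pooled"))
    return GroupTestResult(
        variable=variable,
        test=f"{rule}-t",
        statistic=float(t),
        p_value=float(p),
        summary={
            "mean_x": float(np.mean(x)), "sd_x": float(np.std(x, ddof=1)), "n_x": len(x),
            "mean_y": float(np.mean(y)), "sd_y": float(np.std(y, ddof=1)), "n_y": len(y),
        },
    )


def t_from_summary(
    mean_x: float, sd_x: float, n_x: int,
    mean_y: float, sd_y: float, n_y: int,
    variance_rule: str,
    variable: str = "",
) -> GroupTestResult:
    """t-test from published group summaries (mean, sd, n).

    The Levene gate needs raw data, so the caller must choose ``pooled`` or
    ``welch`` explicitly.
    """
    if variance_rule not in ("pooled", "welch"):
        raise ValueError("summary-based t requires variance_rule 'pooled' or 'welch'")
    t, p = stats.ttest_ind_from_stats(
        mean_x, sd_x, n_x, mean_y, sd_y, n_y,
        equal_var=(variance_rule == "pooled"),
    )
    return GroupTestResult(
        variable=variable,
        test=f"{variance_rule}-t",
        statistic=float(t),
        p_value=float(p),
        summary={
            "mean_x": mean_x, "sd_x": sd_x, "n_x": n_x,
            "mean_y": mean_y, "sd_y": sd_y, "n_y": n_y,
        },
    )


def chi_square_2x2(a: int, b: int, c: int, d: int, variable: str = "") -> GroupTestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a margin is zero")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return GroupTestResult(
        variable=variable,
        test="chi-square",
        statistic=float(chi2),
        p_value=float(p),
        summary={"table": [[a, b], [c, d]]},
    )


def mann_whitney(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> GroupTestResult:
    """Mann-Whitney U (U counted for x over y, half credit for ties).

    p-value: exact enumeration when both groups have <= 8 untied
    observations, otherwise the tie-corrected normal approximation (no
    continuity correction).  Fully tied data (zero variance) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    n1, n2 = len(x), len(y)

    u = float(
        np.sum((x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :]))
    )
    if not has_ties and max(n1, n2) <= 8:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        mu = n1 * n2 / 2.0
        all_vals = np.concatenate([x, y])
        _, counts = np.unique(all_vals, return_counts=True)
        n = n1 + n2
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u - mu) / math.sqrt(var)
            p = float(2 * stats.norm.sf(abs(z)))
    return GroupTestResult(
        variable=variable,
        test="mann-whitney",
        statistic=u,
        p_value=min(p, 1.0),
        summary={"n_x": n1, "n_y": n2, "median_x": float(np.median(x)),
                 "median_y": float(np.median(y))},
    )


class RankDeficientDesign(ValueError):
    pass


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    cols: list[str] = []
    kept: list[str] = []
    for c in X.columns:
        trial = kept + [c]
        if np.linalg.matrix_rank(X[trial].to_numpy()) < len(trial):
            cols.append(c)
        else:
            kept.append(c)
    return cols


def change_regressions(
    delta_care: Sequence[float],
    delta_outcomes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-outcome linear model: delta outcome ~ delta CARE (+ covariates).

    Returns one row per outcome with the CARE-change slope, its standard
    error, t, raw p, and the Benjamini-Hochberg q across outcomes.  With
    the package's sign conventions a negative slope means a rising CARE
    index accompanies declining performance.
    """
    dcare = pd.Series(np.asarray(delta_care, dtype=float), name="delta_care")
    n = len(dcare)
    design = pd.DataFrame({"delta_care": dcare.to_numpy()})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        design = pd.concat([design, cov], axis=1)
    if n <= design.shape[1] + 2:
        raise ValueError(
            f"need n > {design.shape[1] + 2} subjects for {design.shape[1]} predictors, got {n}"
        )
    X = add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        bad = _collinear_columns(X)
        raise RankDeficientDesign(f"collinear design columns: {bad}")

    rows = []
    for col in delta_outcomes.columns:
        yv = pd.to_numeric(delta_outcomes[col], errors="coerce").reset_index(drop=True)
        ok = yv.notna() & X.notna().all(axis=1)
        fit = OLS(yv[ok], X[ok]).fit()
        rows.append(
            {
                "outcome": col,
                "slope": float(fit.params["delta_care"]),
                "se": float(fit.bse["delta_care"]),
                "t": float(fit.tvalues["delta_care"]),
                "p": float(fit.pvalues["delta_care"]),
                "n": int(ok.sum()),
            }
        )
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"], alpha=fdr_alpha, method="fdr_bh")
    out["q"] = q
    out["significant"] = out["q"] < fdr_alpha
    return out
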