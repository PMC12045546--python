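"""Statistical machinery for the preference analysis.

Nonparametric tests (Spearman, Wilcoxon signed-rank, Kruskal-Wallis) wrap
scipy for their statistics and asymptotic p-values, but small samples get
exact p-values computed in-package: Spearman and Kruskal-Wallis by full
permutation enumeration (feasible to n = 8), and the Wilcoxon signed-rank
by a convolution over doubled midranks, which unlike the textbook exact
distribution tolerates tied absolute differences.  Zero differences are
dropped before the signed-rank test (classical convention).

Regression model building follows the study's recipe: a univariate screen
retaining covariates with p < 0.2, then backward elimination minimising
AIC, with Wald-type 95% confidence intervals on the survivors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "RegressionModel",
    "ScreenResult",
    "rank_utility_correlation",
    "paired_compare",
    "bmi_compare",
    "univariate_screen",
    "backward_aic",
]

_EXACT_N_PERM = 8  # full enumeration threshold for Spearman / Kruskal-Wallis
_EXACT_N_SIGNRANK = 25


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: int
    paired: bool = False
    grouping: str = ""
    degenerate: bool = False
    note: str = ""


@dataclass
class ScreenResult:
    retained: list[str]
    p_values: dict[str, float]
    excluded: list[str] = field(default_factory=list)


@dataclass
class RegressionModel:
    """Backward-AIC linear model: coefficients, Wald 95% CIs, p-values, AIC."""

    outcome: str
    terms: pd.DataFrame  # index: parameter; columns: coef, ci_low, ci_high, p_value, block
    aic: float
    n: int
    retained: list[str]
    screened: list[str]
    notes: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------- #
# Spearman
# --------------------------------------------------------------------------- #
def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value of Spearman's rho by full enumeration."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    R = ry[perms]
    rx_c = rx - rx.mean()
    R_c = R - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (R_c[0] ** 2).sum())
    rho = R_c @ rx_c / denom
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def rank_utility_correlation(
    x: Sequence[float], y: Sequence[float], method: str = "auto", name: str = "spearman"
) -> TestResult:
    """Spearman rank correlation with midrank ties and a two-sided p-value.

    ``method='auto'`` uses the exact permutation null for n <= 8 and the
    t approximation otherwise.  A constant vector leaves rho undefined:
    the result carries NaNs, a warning is emitted, and ``degenerate`` is
    set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 3:
        raise ValueError(f"need n >= 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return TestResult(name, np.nan, np.nan, len(x), paired=True,
                          degenerate=True, note="constant input")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if method == "exact" or (method == "auto" and len(x) <= _EXACT_N_PERM):
        p = _exact_spearman_p(x, y, rho)
        note = "exact permutation p"
    else:
        p = float(res.pvalue)
        note = "t approximation"
    return TestResult(name, rho, p, len(x), paired=True, note=note)


# --------------------------------------------------------------------------- #
# Wilcoxon signed-rank
# --------------------------------------------------------------------------- #
def _signed_rank_exact_p(ranks: np.ndarray, t_plus: float) -> float:
    """Exact two-sided p for the signed-rank sum via doubled-midrank DP.

    Midranks are doubled to integers; the null distribution of T+ is the
    convolution of independent {0, r} contributions over all 2^n sign
    assignments.  p = min(1, 2 * min(P(T <= t), P(T >= t))).
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    t2 = int(np.rint(2 * t_plus))
    cdf = dist[: t2 + 1].sum()
    sf = dist[t2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def paired_compare(
    x: Sequence[float], y: Sequence[float], method: str = "auto",
    name: str = "wilcoxon_signed_rank", grouping: str = "",
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Zero differences are dropped.  If every difference is zero the result
    is degenerate with p = 1.  n <= 25 uses the exact doubled-midrank
    distribution; larger samples use the normal approximation with tie and
    continuity corrections (scipy).  The statistic is T+, the rank sum of
    positive differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return TestResult(name, 0.0, 1.0, 0, paired=True, grouping=grouping,
                          degenerate=True, note="all differences zero")
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    if method == "exact" or (method == "auto" and n <= _EXACT_N_SIGNRANK):
        p = _signed_rank_exact_p(ranks, t_plus)
        note = "exact (doubled-midrank convolution)"
    else:
        res = sps.wilcoxon(d, correction=True, method="approx")
        p = float(res.pvalue)
        note = "normal approximation, continuity correction"
    return TestResult(name, t_plus, p, n, paired=True, grouping=grouping, note=note)


# --------------------------------------------------------------------------- #
# Kruskal-Wallis
# --------------------------------------------------------------------------- #
def _kw_statistic(ranks: np.ndarray, sizes: list[int], tie_factor: float) -> np.ndarray:
    """Tie-corrected H for (possibly many) permutations of the rank vector.

    ``ranks`` has shape (m, n): m permutations of the pooled midranks, with
    group g occupying the column block given by ``sizes``.
    """
    n = ranks.shape[1]
    h = np.zeros(ranks.shape[0])
    start = 0
    for size in sizes:
        s = ranks[:, start : start + size].sum(axis=1)
        h += s**2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_factor


def bmi_compare(
    values: Sequence[float], groups: Sequence, method: str = "auto",
    name: str = "kruskal_wallis", grouping: str = "",
) -> TestResult:
    """Kruskal-Wallis H test of a score across (BMI) categories.

    Requires at least two non-empty groups.  Identical values in every
    group give the degenerate H = 0, p = 1.  ``method='auto'`` enumerates
    the exact permutation null for pooled n <= 8.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    mask = ~np.isnan(values)
    values, groups = values[mask], groups[mask]
    labels = [g for g in pd.unique(groups)]
    samples = [values[groups == g] for g in labels]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) < 2:
        raise ValueError(f"need >= 2 non-empty groups, got {len(samples)}")
    n = int(sum(len(s) for s in samples))
    if np.ptp(values) == 0:
        return TestResult(name, 0.0, 1.0, n, grouping=grouping,
                          degenerate=True, note="all values identical")
    pooled = np.concatenate(samples)
    sizes = [len(s) for s in samples]
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_factor = 1.0 - ((counts**3 - counts).sum() / (n**3 - n))
    h_obs = float(_kw_statistic(ranks[None, :], sizes, tie_factor)[0])
    if method == "exact" or (method == "auto" and n <= _EXACT_N_PERM):
        perms = np.array(list(itertools.permutations(range(n))))
        h_perm = _kw_statistic(ranks[perms], sizes, tie_factor)
        p = float(np.mean(h_perm >= h_obs - 1e-12))
        note = "exact permutation p"
    else:
        p = float(sps.chi2.sf(h_obs, len(samples) - 1))
        note = "chi-square approximation"
    return TestResult(name, h_obs, p, n, grouping=grouping, note=note)


# --------------------------------------------------------------------------- #
# regression: univariate screen + backward AIC
# --------------------------------------------------------------------------- #
def _dummy_block(series: pd.Series, name: str) -> pd.DataFrame:
    """Indicator columns for a categorical covariate (first level = reference)."""
    dummies = pd.get_dummies(series, prefix=None, drop_first=True, dtype=float)
    dummies.columns = [str(c) for c in dummies.columns]
    if dummies.shape[1] == 0:
        raise ValueError(f"covariate {name!r} has a single level")
    return dummies


def _design_block(covariates: pd.DataFrame, name: str) -> pd.DataFrame:
    col = covariates[name]
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float).to_frame(name)
    return _dummy_block(col, name)


def univariate_screen(
    outcome: Sequence[float],
    covariates: pd.DataFrame,
    candidates: Optional[list[str]] = None,
    alpha: float = 0.2,
) -> ScreenResult:
    """Screen candidate covariates one at a time against the outcome.

    Each candidate enters a single-covariate linear model (categoricals as
    an indicator set tested jointly); covariates with p < ``alpha``
    (default 0.2, the study's threshold) are retained.  Zero-variance
    covariates are excluded with a warning.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), index=covariates.index)
    if candidates is None:
        candidates = [c for c in covariates.columns if c != "participant_id"]
    retained, p_values, excluded = [], {}, []
    for name in candidates:
        sub = pd.concat([y.rename("__y"), covariates[name]], axis=1).dropna()
        if sub[name].nunique(dropna=True) <= 1:
            warnings.warn(f"covariate {name!r} has zero variance; excluded", stacklevel=2)
            excluded.append(name)
            continue
        X = sm.add_constant(_design_block(sub, name))
        res = sm.OLS(sub["__y"], X).fit()
        p = float(res.f_pvalue)
        p_values[name] = p
        if p < alpha:
            retained.append(name)
    return ScreenResult(retained, p_values, excluded)


def _fit_blocks(y: pd.Series, blocks: dict[str, pd.DataFrame], names: list[str]):
    if names:
        X = pd.concat([blocks[n] for n in names], axis=1)
        X = sm.add_constant(X, has_constant="add")
    else:
        X = pd.DataFrame({"const": np.ones(len(y))}, index=y.index)
    return sm.OLS(y, X).fit()


def backward_aic(
    outcome: Sequence[float],
    covariates: pd.DataFrame,
    candidates: Optional[list[str]] = None,
    outcome_name: str = "outcome",
) -> RegressionModel:
    """Backward elimination on AIC from the full screened model.

    Starting from all candidates, repeatedly drops the covariate (as a
    block of columns for categoricals) whose removal most reduces the AIC,
    stopping when no removal helps; AIC ties are broken by dropping the
    covariate with the larger p-value.  Collinear blocks contributing no
    rank are dropped with a warning before selection.  Returns Wald-type
    95% confidence intervals on the surviving coefficients.
    """
    covariates = covariates.copy()
    if candidates is None:
        candidates = [c for c in covariates.columns if c != "participant_id"]
    y_all = pd.Series(np.asarray(outcome, dtype=float), index=covariates.index)
    keep = pd.concat([y_all.rename("__y"), covariates[candidates]], axis=1).dropna()
    y = keep["__y"]
    if len(y) <= len(candidates) + 2:
        raise ValueError(
            f"need n > p + 2 (n={len(y)}, candidates={len(candidates)})"
        )
    blocks = {name: _design_block(keep, name) for name in candidates}
    notes: list[str] = []

    # drop blocks that add no rank (collinearity guard)
    current = list(candidates)

    def _rank(names: list[str]) -> int:
        if not names:
            return 1
        X = sm.add_constant(pd.concat([blocks[n] for n in names], axis=1),
                            has_constant="add")
        return int(np.linalg.matrix_rank(X.to_numpy()))

    full_cols = 1 + sum(blocks[n].shape[1] for n in current)
    while _rank(current) < full_cols:
        for name in reversed(current):
            others = [n for n in current if n != name]
            if _rank(others) == _rank(current):
                warnings.warn(
                    f"covariate {name!r} is collinear with the rest; dropped",
                    stacklevel=2,
                )
                notes.append(f"collinear covariate dropped: {name}")
                current = others
                break
        else:  # pragma: no cover - defensive
            break
        full_cols = 1 + sum(blocks[n].shape[1] for n in current)

    res = _fit_blocks(y, blocks, current)
    while current:
        trials = []
        for name in current:
            others = [n for n in current if n != name]
            res_o = _fit_blocks(y, blocks, others)
            block_p = max(float(res.pvalues[c]) for c in blocks[name].columns)
            trials.append((res_o.aic, -block_p, name, res_o))
        trials.sort()
        best_aic, _, best_name, best_res = trials[0]
        if best_aic < res.aic - 1e-12:
            current = [n for n in current if n != best_name]
            res = best_res
        else:
            break

    ci = res.conf_int(alpha=0.05)
    col_block = {}
    for name in current:
        for c in blocks[name].columns:
            col_block[c] = name
    col_block["const"] = "const"
    terms = pd.DataFrame(
        {
            "coef": res.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": res.pvalues,
            "block": [col_block[c] for c in res.params.index],
        }
    )
    return RegressionModel(
        outcome=outcome_name,
        terms=terms,
        aic=float(res.aic),
        n=int(res.nobs),
        retained=current,
        screened=list(candidates),
        notes=notes,
    )
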