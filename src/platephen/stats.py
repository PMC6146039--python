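"""Shared statistical utilities.

Thin, contract-checked wrappers over scipy/numpy for the standard methods the
screening pipeline reports: descriptive summaries with coefficient of
variation, Pearson correlation with a t-based significance test, ordinary
least squares, Kruskal-Wallis / one-way ANOVA with Dunn's post hoc and Sidak
correction, and a log-linearisation helper for exponential fits.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import AnalysisError

__all__ = [
    "CorrelationResult",
    "pearson",
    "descriptive",
    "cv_percent",
    "linear_fit",
    "log_linear_fit",
    "dunn_posthoc",
    "group_comparison",
]

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r2: float
    n: int
    p: float


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with two-sided p from the t-transform of r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise AnalysisError("pearson needs two equal-length arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("pearson undefined for constant input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, n=int(x.size), p=float(res.pvalue))


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100 * sd / mean (%)."""
    if mean == 0:
        raise AnalysisError("CV undefined for zero mean")
    return 100.0 * sd / mean


def descriptive(values: Sequence[float]) -> tuple[float, float, float, int]:
    """(mean, sample sd, cv %, n) of a list of values (n >= 2)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise AnalysisError("descriptive summary needs n >= 2")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return mean, sd, cv_percent(mean, sd), int(v.size)


def linear_fit(x: Sequence[float], y: Sequence[float]):
    """OLS line y = slope*x + intercept; returns scipy's linregress result."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise AnalysisError("linear fit needs n >= 3")
    if np.ptp(x) == 0:
        raise AnalysisError("linear fit undefined for constant x")
    return sps.linregress(x, y)


def log_linear_fit(x: Sequence[float], y: Sequence[float]):
    """Fit y = a * exp(b x) by OLS on ln(y); returns (a, b, r2).

    Linearisation helper for exponential relationships; all y must be > 0.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise AnalysisError("log-linearisation requires positive y")
    res = linear_fit(x, np.log(y))
    return float(np.exp(res.intercept)), float(res.slope), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    g = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(g) < 2:
        raise AnalysisError("group comparison needs >= 2 groups")
    for k, v in g.items():
        if v.size < 2:
            raise AnalysisError(f"group {k!r} has fewer than 2 observations")
    return g


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    control: str | None = None,
    correction: str = "sidak",
) -> pd.DataFrame:
    """Dunn's rank-based multiple-comparison test.

    Compares all pairs (or each group against ``control``) on the joint
    ranks, with the tie-corrected normal statistic
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))`` and
    Sidak-adjusted two-sided p-values.
    """
    g = _validate_groups(groups)
    names = list(g)
    pooled = np.concatenate([g[k] for k in names])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_rank, sizes, i = {}, {}, 0
    for k in names:
        n = g[k].size
        mean_rank[k] = float(ranks[i:i + n].mean())
        sizes[k] = n
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    if control is not None:
        if control not in g:
            raise AnalysisError(f"control group {control!r} not found")
        pairs = [(control, k) for k in names if k != control]
    else:
        pairs = [(a, b) for idx, a in enumerate(names) for b in names[idx + 1:]]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        if correction == "sidak":
            p_adj = float(1.0 - (1.0 - min(p, 1.0)) ** m)
        elif correction == "none":
            p_adj = float(p)
        else:
            raise AnalysisError(f"unknown correction {correction!r}")
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p": float(p),
                     "p_adj": min(p_adj, 1.0)})
    df = pd.DataFrame(rows)
    for level in SIGNIFICANCE_LEVELS:
        df[f"sig_{level}"] = df["p_adj"] < level
    return df


def group_comparison(
    groups: Mapping[str, Sequence[float]],
    test: str = "kruskal_wallis",
    control: str | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Omnibus test plus post hoc table.

    ``test='kruskal_wallis'``: Kruskal-Wallis H, then Dunn's post hoc with
    Sidak correction.  ``test='anova_dunn_sidak'``: one-way ANOVA F, then
    pairwise pooled-variance t-tests with Sidak correction.
    Returns (statistic, p, posthoc table).
    """
    g = _validate_groups(groups)
    names = list(g)
    if test == "kruskal_wallis":
        pooled = np.concatenate(list(g.values()))
        if np.ptp(pooled) == 0:
            # all observations identical: no evidence of any difference
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.kruskal(*g.values())
        post = dunn_posthoc(g, control=control)
        return float(stat), float(p), post
    if test == "anova_dunn_sidak":
        stat, p = sps.f_oneway(*g.values())
        # pooled-variance pairwise t (the classical multcompare approach)
        n_total = sum(v.size for v in g.values())
        k = len(g)
        mse = sum(((v - v.mean()) ** 2).sum() for v in g.values()) / (n_total - k)
        if control is not None:
            pairs = [(control, nm) for nm in names if nm != control]
        else:
            pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        m = len(pairs)
        rows = []
        for a, b in pairs:
            se = np.sqrt(mse * (1 / g[a].size + 1 / g[b].size))
            t = (g[a].mean() - g[b].mean()) / se if se > 0 else 0.0
            praw = 2 * sps.t.sf(abs(t), n_total - k) if se > 0 else 1.0
            p_adj = min(1.0, 1.0 - (1.0 - min(praw, 1.0)) ** m)
            rows.append({"group_a": a, "group_b": b, "z": float(t), "p": float(praw),
                         "p_adj": p_adj})
        post = pd.DataFrame(rows)
        for level in SIGNIFICANCE_LEVELS:
            post[f"sig_{level}"] = post["p_adj"] < level
        stat = float(stat) if np.isfinite(stat) else 0.0
        p = float(p) if np.isfinite(p) else 1.0
        return stat, p, post
    raise AnalysisError(f"unknown test {test!r}")
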