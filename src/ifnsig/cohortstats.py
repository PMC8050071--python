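"""Cohort-comparison statistics.

The nonparametric toolkit used throughout the analysis: Shapiro-Wilk
normality screening, tie-corrected Kruskal-Wallis omnibus tests with
Dunn's rank-based post hoc pairwise comparisons, Spearman correlation with
a weak / moderate / strong classification, clinical correlation matrices,
and balanced one-way ANOVA power via the noncentral F distribution.

Dunn's z statistic for groups i, j over pooled midranks (N total values,
tie groups of size t):

    z = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - sum(t^3 - t)/(12(N-1)))
                                 * (1/n_i + 1/n_j)]

with two-sided normal p-values and, by default, Bonferroni adjustment
across all pairwise comparisons.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class ConstantInputError(ValueError):
    """A test received values with no variation."""


# -- normality ---------------------------------------------------------------

def normality_test(values) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value; requires 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or x.size > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ConstantInputError("normality test undefined for constant input")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# -- Kruskal-Wallis / Dunn ---------------------------------------------------

def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H, degrees of freedom, chi-square p.

    Degenerate pooled-constant input yields (0, k-1, 1) rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis requires >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("kruskal_wallis requires >= 3 values in total")
    df = len(groups) - 1
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), df, float(p)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def dunn_posthoc(groups, labels=None, adjustment: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post hoc pairwise comparisons after Kruskal-Wallis.

    All pairwise comparisons are computed.  ``adjustment`` is one of
    ``bonferroni`` (default), ``holm`` or ``sidak``.  Returns a DataFrame
    with one row per pair: group_1, group_2, n_1, n_2, mean_rank_1,
    mean_rank_2, z, p_raw, p_adj.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("dunn_posthoc requires >= 2 non-empty groups")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ValueError("labels must match the number of groups")

    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)  # midranks
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0, *sizes])
    mean_ranks = [ranks[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]

    var_core = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))

    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var_core * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_1": labels[i], "group_2": labels[j],
                "n_1": sizes[i], "n_2": sizes[j],
                "mean_rank_1": mean_ranks[i], "mean_rank_2": mean_ranks[j],
                "z": z, "p_raw": min(p_raw, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    method = {"bonferroni": "bonferroni", "holm": "holm", "sidak": "sidak"}.get(adjustment)
    if method is None:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method=method)[1]
    return table


# -- Spearman correlation ----------------------------------------------------

STRONG_R = 0.5
WEAK_R = 0.3


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    r: float
    p: float
    n: int
    strength: str

    @property
    def strong_and_significant(self) -> bool:
        return self.strength == "strong" and self.p < 0.05


def classify_strength(r: float) -> str:
    """strong if |r| > 0.5, weak if |r| < 0.3, else moderate (boundaries moderate)."""
    a = abs(r)
    if a > STRONG_R:
        return "strong"
    if a < WEAK_R:
        return "weak"
    return "moderate"


def spearman(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    The p-value uses the t approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"spearman requires >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("spearman undefined for constant input")
    r, p = stats.spearmanr(x, y)
    return CorrelationResult(x_name, y_name, float(r), float(p), int(x.size), classify_strength(float(r)))


def correlation_table(
    measures: pd.DataFrame, clinical: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Spearman correlations of every measure against each clinical variable.

    ``measures`` (samples x measures) and ``clinical`` (samples x variables)
    are aligned on their index; deletion is pairwise per cell.  Returns a
    tidy DataFrame (measure, variable, r, p, n, strength,
    strong_and_significant) with one row per cell.
    """
    if variables is None:
        variables = list(clinical.columns)
    common = measures.index.intersection(clinical.index)
    if common.empty:
        raise ValueError("no overlapping samples between measures and clinical tables")
    m, c = measures.loc[common], clinical.loc[common]
    rows = []
    for measure in m.columns:
        for var in variables:
            res = spearman(m[measure], c[var], x_name=measure, y_name=var)
            rows.append(
                {
                    "measure": measure, "variable": var,
                    "r": res.r, "p": res.p, "n": res.n,
                    "strength": res.strength,
                    "strong_and_significant": res.strong_and_significant,
                }
            )
    return pd.DataFrame(rows)


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy correlation table to measures x variables, r to 2 decimals."""
    wide = table.pivot(index="measure", columns="variable", values="r")
    return wide.round(2)


# -- ANOVA power -------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    k: int
    n: int
    deltas: tuple[float, ...]
    sigma: float
    alpha: float
    noncentrality: float
    power: float


def anova_power(
    k: int,
    n: int,
    deltas,
    sigma: float = 1.0,
    alpha: float = 0.05,
    convention: str = "textbook",
) -> PowerSpec:
    """Power of a balanced one-way ANOVA via the noncentral F distribution.

    ``deltas`` are the group means (in the units of ``sigma``).  The
    noncentrality is the textbook ``lambda = n * sum((mu_i - mubar)^2) /
    sigma^2``; ``convention="between-var"`` instead multiplies by
    ``k/(k-1)``, matching tools that parameterise power by the
    between-group variance of the means (e.g. R's power.anova.test).
    """
    deltas = tuple(float(d) for d in deltas)
    if k < 2 or len(deltas) != k:
        raise ValueError("k must be >= 2 and match len(deltas)")
    if n < 2:
        raise ValueError("per-group n must be >= 2")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    mu = np.asarray(deltas)
    lam = n * float(np.sum((mu - mu.mean()) ** 2)) / sigma**2
    if lam < 1e-12:  # clear float residue so the null identity power = alpha is exact
        lam = 0.0
    if convention == "between-var":
        lam *= k / (k - 1)
    elif convention != "textbook":
        raise ValueError(f"unknown noncentrality convention {convention!r}")
    df1, df2 = k - 1, k * (n - 1)
    fcrit = stats.f.isf(alpha, df1, df2)
    power = float(stats.ncf.sf(fcrit, df1, df2, lam)) if lam > 0 else alpha
    return PowerSpec(k, n, deltas, sigma, alpha, lam, power)
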