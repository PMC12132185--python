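"""Statistical layer: permutation tests, rank-sum with Bonferroni,
correlation, and linear models for light/species/behavior effects.

The permutation test is an estimation-statistics-style mean-difference
test: labels are shuffled without replacement, the two-sided p-value is
``(1 + #{|Δ_perm| >= |Δ_obs|}) / (n_perm + 1)``, and a bootstrap
percentile CI of the effect is reported alongside.  Everything stochastic
is reproducible from (inputs, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PermutationResult",
    "ModelResult",
    "permutation_test",
    "ranksum_bonferroni",
    "corr_with_p",
    "fit_linear_model",
]


@dataclass
class PermutationResult:
    observed_effect: float  # mean(a) - mean(b)
    p_value: float
    n_permutations: int
    seed: int | None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p must lie in (0, 1]")


@dataclass
class ModelResult:
    response: str
    formula: str
    terms: list[str]
    coefficients: pd.Series
    term_pvalues: pd.Series
    nobs: int
    sm_results: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [f"OLS  {self.formula}   (n = {self.nobs})", ""]
        lines.append("per-term partial F-test p-values:")
        for term, p in self.term_pvalues.items():
            lines.append(f"  {term:<20s} p = {p:.4g}")
        return "\n".join(lines)


def permutation_test(
    a,
    b,
    n_perm: int = 5000,
    seed: int | None = None,
    n_boot: int = 1000,
) -> PermutationResult:
    """Two-sided permutation test on the difference of means.

    Group labels are reshuffled without replacement ``n_perm`` times; the
    p-value uses the add-one convention so it can never be 0.  A seeded
    bootstrap percentile 95% CI of the mean difference is attached
    (``n_boot=0`` disables it).  A fully degenerate pooled sample (all
    values equal) yields p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        warnings.warn("degenerate pooled sample (all values equal); p = 1")
        return PermutationResult(0.0, 1.0, n_perm, seed, 0.0, 0.0)
    rng = np.random.default_rng(seed)
    na, n = len(a), len(pooled)
    # the permutation null depends only on the pooled multiset; sorting makes
    # the seeded draw invariant to input order (and exactly symmetric in a/b
    # for equal group sizes)
    pooled_sorted = np.sort(pooled)
    # vectorised label shuffles: each row of `order` is one permutation
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled_sorted[order]
    diffs = perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1)
    count = int(np.sum(np.abs(diffs) >= abs(observed) - 1e-12))
    p = (1 + count) / (n_perm + 1)
    ci_low = ci_high = None
    if n_boot:
        ia = rng.integers(0, na, size=(n_boot, na))
        ib = rng.integers(0, len(b), size=(n_boot, len(b)))
        boot = a[ia].mean(axis=1) - b[ib].mean(axis=1)
        ci_low, ci_high = (float(q) for q in np.percentile(boot, [2.5, 97.5]))
    return PermutationResult(observed, p, n_perm, seed, ci_low, ci_high)


def ranksum_bonferroni(
    groups: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Wilcoxon rank-sum (Mann-Whitney U) per comparison, Bonferroni-adjusted.

    The exact null distribution is used when both groups have
    ``n <= exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie correction.  Adjusted p = min(1, m * p) with m
    the number of comparisons.
    """
    m = len(comparisons)
    rows = []
    for ga, gb in comparisons:
        x = np.asarray(groups[ga], dtype=float)
        y = np.asarray(groups[gb], dtype=float)
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        exact = len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        p = float(res.pvalue)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "statistic_u": float(res.statistic),
                "p_raw": p,
                "p_adjusted": min(1.0, m * p),
                "method": "exact" if exact else "asymptotic",
            }
        )
    return pd.DataFrame(rows)


def corr_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation with its t-distribution p-value (n − 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must share a length of at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def fit_linear_model(table: pd.DataFrame, formula: str) -> ModelResult:
    """Ordinary least squares with treatment-coded categoricals.

    Per-term p-values come from partial (type-II) F-tests.  The "glm" of
    the assay's analyses is taken as Gaussian-identity, i.e. OLS, since
    the responses are continuous speeds and latencies.  A rank-deficient
    design raises with the aliased columns named.
    """
    model = smf.ols(formula, data=table)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # pivoted QR localises the linearly dependent columns
        _, _, piv = sla.qr(exog, pivoting=True, mode="economic")
        aliased = [model.exog_names[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = model.fit()
    anova = sm.stats.anova_lm(res, typ=2)
    term_p = anova["PR(>F)"].drop(labels=["Residual"], errors="ignore")
    response = formula.split("~")[0].strip()
    return ModelResult(
        response=response,
        formula=formula,
        terms=list(term_p.index),
        coefficients=res.params,
        term_pvalues=term_p,
        nobs=int(res.nobs),
        sm_results=res,
    )
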