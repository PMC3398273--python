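"""Class-level comparative statistics.

Functional-class contrasts (class members vs all other genes) by Wilcoxon
rank-sum tests on a metric or on its residuals after regressing out gene
length or expression level; step-down Holm–Bonferroni correction within test
families; a bootstrap null that re-draws random gene sets of the class's
size; Spearman and partial Spearman correlations; variance F tests and
Fisher exact 2x2 tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    label: str
    statistic: float
    pvalue: float
    method: str
    n_a: int
    n_b: int
    mean_a: float = np.nan
    mean_b: float = np.nan
    se_a: float = np.nan
    se_b: float = np.nan
    pvalue_corrected: Optional[float] = None
    correction: Optional[str] = None
    flag: Optional[str] = None


def wilcoxon_rank_sum(a, b, label: str = "") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null enumeration when min(n_a, n_b) <= 8 and the pooled sample has
    no ties; otherwise the normal approximation with tie and continuity
    corrections.  Identical pooled values give P = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult(label, a.size * b.size / 2.0, 1.0, "wilcoxon-degenerate", a.size, b.size)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        label=label,
        statistic=float(res.statistic),
        pvalue=float(min(res.pvalue, 1.0)),
        method=f"wilcoxon-{method}",
        n_a=a.size,
        n_b=b.size,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        se_a=float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else np.nan,
        se_b=float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else np.nan,
    )


def residuals_on_length(metric, length) -> np.ndarray:
    """Residuals of the OLS regression of a per-gene metric on gene length
    (mean residual 0; constant length degenerates to centring)."""
    y = np.asarray(metric, dtype=float)
    x = np.asarray(length, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.ptp(x) == 0:
        return y - y.mean()
    slope, intercept = np.polyfit(x, y, 1)
    return y - (slope * x + intercept)


def class_vs_rest(
    table: pd.DataFrame,
    class_label: str,
    metric: str,
    correct_for: str = "none",
    length_col: str = "length",
    expression_col: str = "mean_expr",
) -> TestResult:
    """Wilcoxon contrast of a class's genes against all other genes.

    ``correct_for`` in {"none", "length", "expression"} replaces the metric
    by its OLS residuals on gene length or mean expression before testing.
    The result carries group means and standard errors of the tested values.
    """
    if class_label not in table.columns:
        raise ValueError(f"class {class_label!r} absent from table")
    mask = table[class_label].astype(bool).to_numpy()
    values = table[metric].to_numpy(dtype=float)
    ok = np.isfinite(values)
    if correct_for == "length":
        covar = table[length_col].to_numpy(dtype=float)
        ok &= np.isfinite(covar)
    elif correct_for == "expression":
        covar = table[expression_col].to_numpy(dtype=float)
        ok &= np.isfinite(covar)
    elif correct_for != "none":
        raise ValueError("correct_for must be 'none', 'length' or 'expression'")
    mask, values = mask[ok], values[ok]
    if correct_for != "none":
        values = residuals_on_length(values, covar[ok])
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError(f"degenerate split for class {class_label!r}")
    return wilcoxon_rank_sum(
        values[mask], values[~mask], label=f"{class_label}:{metric}:{correct_for}"
    )


def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Step-down Holm–Bonferroni adjusted P values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class BootstrapResult:
    class_label: str
    metric: str
    observed_pvalue: float
    B: int
    fraction_leq: float
    seed: int
    with_replacement: bool = False


def bootstrap_class_null(
    table: pd.DataFrame,
    class_label: str,
    metric: str,
    B: int = 10000,
    seed: int = 0,
    with_replacement: bool = False,
) -> BootstrapResult:
    """How often random gene sets of the class's size beat the observed
    Wilcoxon P.

    Draws B random pseudo-classes (without replacement by default), tests
    each against its complement, and reports the fraction of replicates with
    P <= the observed P.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    observed = class_vs_rest(table, class_label, metric).pvalue
    values = table[metric].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    k = int(table[class_label].astype(bool).sum())
    if k > n // 2:
        warnings.warn(f"class size {k} exceeds half the table ({n})", stacklevel=2)
    rng = np.random.default_rng(seed)
    if with_replacement:
        x = values[rng.integers(0, n, size=(B, k))]
        y = values[rng.integers(0, n, size=(B, n - k))]
    else:
        perm = np.argsort(rng.random((B, n)), axis=1)
        shuffled = values[perm]
        x, y = shuffled[:, :k], shuffled[:, k:]
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", axis=1)
    frac = float(np.mean(res.pvalue <= observed))
    return BootstrapResult(
        class_label=class_label,
        metric=metric,
        observed_pvalue=observed,
        B=B,
        fraction_leq=frac,
        seed=seed,
        with_replacement=with_replacement,
    )


@dataclass
class CorrelationResult:
    variables: tuple
    rho: float
    pvalue: float
    n: int
    partial_given: tuple = ()
    r_squared: float = np.nan


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def spearman(x, y, partial_given: Optional[Sequence] = None, labels=("x", "y")) -> CorrelationResult:
    """Spearman correlation, optionally partial given covariates.

    The partial variant is the partial Pearson correlation on rank-transformed
    variables (covariates regressed out by OLS); P from the t distribution
    with n - 2 - k degrees of freedom.  Also reports the R^2 of the
    accompanying OLS regression of y on x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; correlation undefined", stacklevel=2)
        return CorrelationResult(labels, np.nan, np.nan, x.size)
    with np.errstate(invalid="ignore"):
        r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
    if not partial_given:
        rho, p = stats.spearmanr(x, y)
        return CorrelationResult(labels, float(rho), float(p), x.size, r_squared=r2)
    Z = np.column_stack([np.asarray(z, dtype=float) for z in partial_given])
    rx, ry = _rank(x), _rank(y)
    RZ = np.column_stack([_rank(Z[:, j]) for j in range(Z.shape[1])])
    design = np.column_stack([np.ones(x.size), RZ])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex, ey = rx - design @ bx, ry - design @ by
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom == 0:
        return CorrelationResult(labels, np.nan, np.nan, x.size, tuple(range(Z.shape[1])))
    rho = float((ex * ey).sum() / denom)
    df = x.size - 2 - Z.shape[1]
    t = rho * np.sqrt(df / max(1e-12, 1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(
        labels, rho, p, x.size, partial_given=tuple(f"z{j}" for j in range(Z.shape[1])), r_squared=r2
    )


def variance_f_test(a, b, label: str = "") -> TestResult:
    """Two-sided F test comparing two sample variances (accepts residuals)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        return TestResult(label, np.nan, np.nan, "f-test", a.size, b.size, flag="zero variance")
    F = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2.0 * min(stats.f.sf(F, dfa, dfb), stats.f.cdf(F, dfa, dfb))
    return TestResult(
        label, float(F), float(min(p, 1.0)), "f-test", a.size, b.size,
        mean_a=float(va), mean_b=float(vb),
    )


def fisher_exact_2x2(table, label: str = "") -> TestResult:
    """Two-tailed Fisher exact test on a 2x2 count table (hypergeometric
    enumeration: sum of tables with probability <= observed)."""
    tab = np.asarray(table)
    if tab.shape != (2, 2) or np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab = tab.astype(int)
        if np.any(np.asarray(table, dtype=float) != tab):
            raise ValueError("table must hold non-negative integers")
    odds, p = stats.fisher_exact(tab, alternative="two-sided")
    return TestResult(
        label, float(odds), float(p), "fisher-exact", int(tab[0].sum()), int(tab[1].sum())
    )
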