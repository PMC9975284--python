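"""Shared statistical primitives.

Conventions used throughout the package:

* Standard deviation is the sample SD about the mean (``ddof=1``), even when
  centering is done on the median ("SD-from-median units").
* Two-sample tests are Welch (unequal-variance) t-tests unless a pooled test
  is explicitly requested.
* One-sided enrichment on a 2x2 table uses Fisher's exact test for small
  tables and a signed chi-square otherwise (see :func:`enrichment_test`).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "welch_t_from_moments",
    "welch_t_groups",
    "one_sample_t",
    "fisher_one_sided",
    "chisq_one_sided",
    "enrichment_test",
    "qvalues",
    "pearson_pvalue",
]

#: defaults for the Fisher / chi-square switch, shared by genomics and assoc
CHISQ_MIN_TOTAL = 200
CHISQ_MIN_EXPECTED = 5.0


def welch_t_from_moments(m1, v1, n1, m2, v2, n2):
    """Welch t, degrees of freedom and two-sided p from group moments.

    Vectorized over numpy arrays; variances are sample variances (ddof=1).
    Degenerate inputs (n<2 or both variances zero) yield NaN t and p=1.
    """
    m1, v1, n1 = np.asarray(m1, float), np.asarray(v1, float), np.asarray(n1, float)
    m2, v2, n2 = np.asarray(m2, float), np.asarray(v2, float), np.asarray(n2, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    bad = ~np.isfinite(t) | (n1 < 2) | (n2 < 2)
    t = np.where(bad, np.nan, t)
    p = np.where(bad, 1.0, p)
    # exact separation: zero within-group variance but distinct means
    with np.errstate(invalid="ignore"):
        sep = (se2 == 0) & (m1 != m2)
        t = np.where(sep, np.inf * np.sign(m1 - m2), t)
    p = np.where(sep, 0.0, p)
    return t, df, p


def _nan_moments(x, axis):
    import warnings as _warnings

    n = np.sum(~np.isnan(x), axis=axis)
    with _warnings.catch_warnings(), np.errstate(invalid="ignore"):
        _warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(x, axis=axis)
        v = np.nanvar(x, axis=axis, ddof=1)
    return m, v, n


def welch_t_groups(x_in: np.ndarray, x_out: np.ndarray, axis: int = 1):
    """Row-wise Welch t-test between two groups of columns (NaN-aware)."""
    m1, v1, n1 = _nan_moments(np.asarray(x_in, float), axis)
    m2, v2, n2 = _nan_moments(np.asarray(x_out, float), axis)
    t, df, p = welch_t_from_moments(m1, v1, n1, m2, v2, n2)
    return t, p, m1 - m2


def one_sample_t(x: np.ndarray, popmean: float = 0.0, axis: int = 1):
    """Row-wise one-sample t vs ``popmean`` with NaN-aware, degenerate-safe output.

    All-equal-to-popmean rows give t=NaN, p=1 (no evidence either way);
    constant rows off the popmean give t=+/-inf, p=0.
    """
    x = np.asarray(x, float)
    m, v, n = _nan_moments(x, axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m - popmean) / np.sqrt(v / n)
        p = 2.0 * sps.t.sf(np.abs(t), n - 1)
    zero_var = v == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var & (m != popmean), np.inf * np.sign(m - popmean), t)
    p = np.where(zero_var & (m != popmean), 0.0, p)
    t = np.where(zero_var & (m == popmean), np.nan, t)
    p = np.where(zero_var & (m == popmean), 1.0, p)
    p = np.where(n < 2, 1.0, p)
    t = np.where(n < 2, np.nan, t)
    return t, p


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for the table [[a, b], [c, d]].

    ``a`` counts the doubly-positive cell; the alternative is that ``a`` is
    larger than expected under independence.
    """
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def chisq_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided chi-square p via the signed statistic.

    Halve the two-sided p when the doubly-positive cell exceeds expectation,
    otherwise report 1 - p/2.
    """
    table = np.array([[a, b], [c, d]], float)
    n = table.sum()
    if n == 0:
        return 1.0
    expected_a = table[0].sum() * table[:, 0].sum() / n
    try:
        stat, p2, _, _ = sps.chi2_contingency(table, correction=False)
    except ValueError:  # a zero margin: no association measurable
        return 1.0
    if a > expected_a:
        return float(p2 / 2.0)
    return float(1.0 - p2 / 2.0)


def enrichment_test(a: int, b: int, c: int, d: int, method: str = "auto"):
    """One-sided enrichment p for [[a, b], [c, d]] plus the method used.

    ``auto`` selects Fisher's exact test when any expected cell is below
    CHISQ_MIN_EXPECTED or the total below CHISQ_MIN_TOTAL, and the signed
    chi-square otherwise (exact tests become needless and slow at scale).
    """
    if method == "auto":
        table = np.array([[a, b], [c, d]], float)
        n = table.sum()
        if n < CHISQ_MIN_TOTAL:
            method = "fisher"
        else:
            row = table.sum(axis=1)
            col = table.sum(axis=0)
            expected = np.outer(row, col) / n
            method = "fisher" if (expected < CHISQ_MIN_EXPECTED).any() else "chisq"
    if method == "fisher":
        return fisher_one_sided(a, b, c, d), "fisher"
    if method == "chisq":
        return chisq_one_sided(a, b, c, d), "chisq"
    raise ValueError(f"unknown method {method!r}")


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)


def qvalues(p: np.ndarray, pi0_lambda: float = 0.5) -> np.ndarray:
    """Storey-style q-values from a vector of p-values.

    pi0 is estimated from the fraction of p-values above ``pi0_lambda``;
    q-values are the monotone-smoothed pi0-scaled BH quantities. Reported for
    diagnostics only; selection in this package uses nominal p cutoffs.
    """
    p = np.asarray(p, float)
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    pi0 = min(1.0, np.mean(pv > pi0_lambda) / (1.0 - pi0_lambda))
    pi0 = max(pi0, 1.0 / m)
    order = np.argsort(pv)
    ranked = pv[order]
    qv = pi0 * m * ranked / np.arange(1, m + 1)
    qv = np.minimum.accumulate(qv[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(qv, 1.0)
    q[ok] = out
    return q


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the t transform.

    t = r * sqrt((n-2) / (1-r^2)) referred to Student t with n-2 df.
    """
    if n <= 2 or not np.isfinite(r):
        return 1.0
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), n - 2))
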