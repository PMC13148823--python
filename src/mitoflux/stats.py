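"""Two-sample statistics used throughout the pipeline.

Welch's t-test is the default two-sample comparison (unequal variances are
the norm for tumor-vs-benign contrasts); the pooled-variance Student variant
is available behind a flag.  Effect size is Cohen's d with the (n-1)-weighted
pooled standard deviation, variability is the percent coefficient of
variation, multiplicity is Benjamini–Hochberg, and post hoc power for the
two-sided two-sample t-test comes from the noncentral t distribution with
noncentrality d * sqrt(n/2) and 2n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "welch_t", "cohens_d", "cv", "bh_adjust", "power_two_sample_t",
    "PowerQuery", "pearson",
]


def _check_two_samples(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    return a, b


def welch_t(a, b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t statistic and two-tailed p.

    Welch–Satterthwaite degrees of freedom by default; ``equal_var=True``
    gives the pooled-variance Student variant.
    """
    a, b = _check_two_samples(a, b)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def cohens_d(a, b) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled SD."""
    a, b = _check_two_samples(a, b)
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    if pooled_var == 0:
        raise ValueError("pooled standard deviation is zero")
    return float((np.mean(a) - np.mean(b)) / np.sqrt(pooled_var))


def cv(x) -> float:
    """Percent coefficient of variation: 100 * sample SD / mean."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    m = np.mean(x)
    if m == 0:
        raise ValueError("mean is zero; CV undefined")
    return float(100.0 * np.std(x, ddof=1) / m)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-d")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PowerQuery:
    """Design for a two-sided two-sample t-test power calculation."""

    n_per_group: int
    d: float
    alpha: float = 0.05

    def validate(self) -> "PowerQuery":
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not np.isfinite(self.d):
            raise ValueError("d must be finite")
        return self


def power_two_sample_t(
    q: PowerQuery | None = None,
    *,
    n_per_group: int | None = None,
    d: float | None = None,
    alpha: float = 0.05,
    n2: int | None = None,
) -> float:
    """Power of the two-sided two-sample t-test at effect size d.

    Noncentral-t construction: noncentrality ncp = d * sqrt(n/2) with
    df = 2n - 2 for equal group sizes.  Unequal sizes (``n2``) use the
    harmonic-mean extension n_h = 2 / (1/n1 + 1/n2) with df = n1 + n2 - 2.
    At d = 0 the power equals alpha (both rejection tails).
    """
    if q is None:
        q = PowerQuery(n_per_group=n_per_group, d=d, alpha=alpha)
    q.validate()
    n1 = q.n_per_group
    if n2 is None:
        n_eff, df = n1, 2 * n1 - 2
    else:
        if n2 < 2:
            raise ValueError("n2 must be >= 2")
        n_eff = 2.0 / (1.0 / n1 + 1.0 / n2)
        df = n1 + n2 - 2
    ncp = q.d * np.sqrt(n_eff / 2.0)
    tcrit = scipy.stats.t.ppf(1.0 - q.alpha / 2.0, df)
    upper = scipy.stats.nct.sf(tcrit, df, ncp)
    lower = scipy.stats.nct.cdf(-tcrit, df, ncp)
    # at large |ncp| scipy's nct underflows to nan in the negligible tail
    if np.isnan(upper):
        upper = 1.0 if ncp > tcrit else 0.0
    if np.isnan(lower):
        lower = 1.0 if ncp < -tcrit else 0.0
    return float(min(1.0, upper + lower))


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input; correlation undefined")
    return float(scipy.stats.pearsonr(x, y).statistic)
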