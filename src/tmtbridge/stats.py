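"""Row-wise pooled-variance t tests and Benjamini-Hochberg adjustment.

The t test is the classic two-sample Student form (pooled variance,
two-tailed) applied to log2 abundances, vectorized over proteins. Degenerate
rows where the pooled variance is exactly zero get p = 1 when the group means
are equal and p = 0 otherwise; both situations arise legitimately in the
noiseless simulation limit and are flagged in the output.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def pooled_ttest_rows(
    a: np.ndarray, b: np.ndarray, min_n: int = 2, equal_var: bool = True
) -> pd.DataFrame:
    """Two-tailed two-sample t test per row of ``a`` vs ``b``.

    The default is the classic Student form (pooled variance); pass
    ``equal_var=False`` for Welch's unequal-variance test with
    Welch-Satterthwaite degrees of freedom. NaNs are missing observations;
    rows with fewer than ``min_n`` finite values in either group get NaN
    statistics (excluded from testing). Returns columns log2fc
    (mean(a) - mean(b)), t, df, p_value, n_a, n_b, degenerate (bool: zero
    variance in both groups).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a = np.isfinite(a).sum(axis=1)
    n_b = np.isfinite(b).sum(axis=1)
    valid = (n_a >= min_n) & (n_b >= min_n)

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # all-NaN / single-value rows are flagged invalid below, not warned about
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1)
        mean_b = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=1)
        var_a = _nanvar(a, n_a)
        var_b = _nanvar(b, n_b)

    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            df = (n_a + n_b - 2).astype(float)
            sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
            se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        else:
            va, vb = var_a / n_a, var_b / n_b
            sp2 = va + vb
            se = np.sqrt(sp2)
            df = sp2**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        t = diff / se

    degenerate = valid & (sp2 == 0)
    p = np.full(a.shape[0], np.nan)
    ok = valid & ~degenerate
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df[ok])
    # Zero pooled variance: equal means -> no evidence (p=1); unequal -> p=0.
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    t[degenerate & (diff == 0)] = 0.0
    t[degenerate & (diff != 0)] = np.where(diff[degenerate & (diff != 0)] > 0, np.inf, -np.inf)

    out = pd.DataFrame(
        {
            "log2fc": np.where(valid, diff, np.nan),
            "t": np.where(valid, t, np.nan),
            "df": np.where(valid, df, np.nan),
            "p_value": np.where(valid, p, np.nan),
            "n_a": n_a,
            "n_b": n_b,
            "degenerate": degenerate,
        }
    )
    return out


def _nanvar(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Sample variance (ddof=1) per row, NaN-aware, 0 where n < 2."""
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v = np.nanvar(np.where(np.isfinite(x), x, np.nan), axis=1, ddof=1)
    return np.where(n >= 2, v, np.nan)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one test family).

    adj_p at rank i is min over ranks j >= i of m * p_(j) / j, capped at 1;
    the transform is order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1] with no missing values")
    return multipletests(p, method="fdr_bh")[1]
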