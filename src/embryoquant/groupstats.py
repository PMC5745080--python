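"""Two-group statistics used on the quantification outputs.

Group comparisons are made with the classical Student t-test
(two-sided, homoscedastic — pooled variance) and dispersion is reported
as the standard error of the mean.  A Welch (unequal-variance) variant
is available for sensitivity checks but is not the default.  No
multiple-testing correction is applied: each call is a single pairwise
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GroupComparison", "sem", "two_sample_t"]


@dataclass(frozen=True)
class GroupComparison:
    """Summary of a two-sample comparison."""

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t_stat: float
    df: float
    p_value: float
    degenerate: bool = False


def sem(values: np.ndarray) -> float:
    """Standard error of the mean: sample s.d. (n-1 denominator) / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("SEM requires n >= 2")
    return float(np.std(values, ddof=1) / np.sqrt(n))


def two_sample_t(
    group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = True
) -> GroupComparison:
    """Two-sided two-sample t-test, pooled-variance by default.

    With ``equal_var=True`` (the default) the statistic is

        t = (mean_a - mean_b) / (s_p * sqrt(1/n_a + 1/n_b)),

    with s_p^2 the pooled sample variance and n_a + n_b - 2 degrees of
    freedom.  ``equal_var=False`` gives the Welch variant
    (Satterthwaite degrees of freedom).

    Degenerate inputs: zero pooled variance with equal means gives
    t = 0, p = 1; zero pooled variance with unequal means is flagged
    (``degenerate=True``) and reported as p = 0 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = a.size, b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need n >= 2")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    var_a, var_b = float(a.var(ddof=1)), float(b.var(ddof=1))

    if equal_var:
        df = float(n_a + n_b - 2)
        pooled_var = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        denom = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    else:
        va, vb = var_a / n_a, var_b / n_b
        denom = np.sqrt(va + vb)
        df = (
            (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
            if denom > 0
            else float(n_a + n_b - 2)
        )

    degenerate = False
    if denom == 0.0:
        if mean_a == mean_b:
            t_stat, p_value = 0.0, 1.0
        else:
            warnings.warn(
                "zero within-group variance with unequal means: "
                "t undefined, reporting p = 0",
                RuntimeWarning,
                stacklevel=2,
            )
            t_stat = np.inf if mean_a > mean_b else -np.inf
            p_value = 0.0
            degenerate = True
    else:
        t_stat = (mean_a - mean_b) / denom
        p_value = float(2.0 * stats.t.sf(abs(t_stat), df))

    return GroupComparison(
        mean_a=mean_a,
        mean_b=mean_b,
        sem_a=sem(a),
        sem_b=sem(b),
        n_a=n_a,
        n_b=n_b,
        t_stat=float(t_stat),
        df=df,
        p_value=p_value,
        degenerate=degenerate,
    )
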