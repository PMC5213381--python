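"""Paired statistics for the three-condition within-animal design.

Every test here is implemented from explicit first principles (binomial
sums, sums of squares) so that each quantity can be traced to its
definition; established library implementations serve as independent
cross-checks in the test suite, never as the computation itself.

All tests are two-sided with alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDesignError, InputError

__all__ = [
    "PairedOutcomes",
    "RMANOVAResult",
    "PairedContrast",
    "mcnemar_exact",
    "discordant_counts",
    "nested_discordant_counts",
    "rm_anova",
    "paired_contrast",
    "threshold_ratio",
]


@dataclass(frozen=True)
class PairedOutcomes:
    """Per-pig paired binary outcomes under two conditions."""

    pig_ids: tuple[str, ...]
    outcome_a: tuple[bool, ...]
    outcome_b: tuple[bool, ...]

    def __post_init__(self):
        if not (len(self.pig_ids) == len(self.outcome_a) == len(self.outcome_b)):
            raise InputError("pig_ids and outcomes must have equal lengths")


def discordant_counts(outcomes: PairedOutcomes) -> tuple[int, int]:
    """(b, c): pairs succeeding under A only, and under B only."""
    b = sum(1 for a, bb in zip(outcomes.outcome_a, outcomes.outcome_b) if a and not bb)
    c = sum(1 for a, bb in zip(outcomes.outcome_a, outcomes.outcome_b) if bb and not a)
    return b, c


def nested_discordant_counts(n_success_weak: int, n_success_strong: int) -> tuple[int, int]:
    """Discordant counts when successes are nested (every site succeeding
    at the weaker setting also succeeds at the stronger one): the only
    pair structure consistent with published per-group success counts
    alone."""
    if n_success_weak < 0 or n_success_strong < n_success_weak:
        raise InputError("nested structure requires 0 <= weak successes <= strong successes")
    return 0, n_success_strong - n_success_weak


def mcnemar_exact(discordant_ab: int, discordant_ba: int) -> float:
    """Exact two-sided McNemar p-value.

    Conditional on the number of discordant pairs ``n = b + c``, the split
    is Binomial(n, 1/2) under the null of equal marginal success rates:
    ``p = min(1, 2 * sum_{k <= min(b, c)} C(n, k) / 2^n)``.  With no
    discordant pairs the test carries no information and p = 1.
    """
    b, c = discordant_ab, discordant_ba
    if b < 0 or c < 0:
        raise InputError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return 1.0
    p = 2.0 * float(sps.binom.cdf(min(b, c), n, 0.5))
    return min(1.0, p)


@dataclass(frozen=True)
class RMANOVAResult:
    f_statistic: float
    df_conditions: int
    df_error: int
    p_value: float
    ss_conditions: float
    ss_subjects: float
    ss_error: float
    ss_total: float
    gg_epsilon: float | None = None  # set when the sphericity correction is applied


def rm_anova(data: np.ndarray, greenhouse_geisser: bool = False) -> RMANOVAResult:
    """One-way repeated-measures ANOVA from explicit sums of squares.

    ``data`` is a complete n_subjects x k_conditions matrix.  The
    within-subject decomposition is

        SS_total = SS_conditions + SS_subjects + SS_error,

    with ``F = MS_conditions / MS_error`` on ``(k-1, (k-1)(n-1))`` degrees
    of freedom.  Sphericity is assumed by default (k = 3 conditions);
    ``greenhouse_geisser=True`` deflates both degrees of freedom by the
    Greenhouse-Geisser epsilon estimated from the condition covariance
    matrix.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise InputError("data must be a 2-D subjects x conditions matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InputError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(x)):
        raise InputError("the default analysis requires a complete matrix")

    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_subjects = float(k * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_conditions = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_conditions

    df_c = k - 1
    df_e = (k - 1) * (n - 1)
    ms_error = ss_error / df_e
    if ms_error <= 0:
        if ss_conditions == 0:
            raise DegenerateDesignError("zero error variance and zero condition variance")
        raise DegenerateDesignError("zero error variance: F undefined")
    f = (ss_conditions / df_c) / ms_error

    eps: float | None = None
    if greenhouse_geisser:
        # epsilon from the double-centred condition covariance matrix
        s = np.cov(x, rowvar=False, ddof=1)
        centred = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
        eps = float(np.trace(centred) ** 2 / ((k - 1) * (centred * centred).sum()))
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)
        p = float(sps.f.sf(f, df_c * eps, df_e * eps))
    else:
        p = float(sps.f.sf(f, df_c, df_e))

    return RMANOVAResult(
        f_statistic=float(f),
        df_conditions=df_c,
        df_error=df_e,
        p_value=p,
        ss_conditions=ss_conditions,
        ss_subjects=ss_subjects,
        ss_error=ss_error,
        ss_total=ss_total,
        gg_epsilon=eps,
    )


@dataclass(frozen=True)
class PairedContrast:
    mean_difference: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    degenerate: bool  # all differences identical: CI collapses to a point


def paired_contrast(x, y, confidence: float = 0.95) -> PairedContrast:
    """Paired t procedure on d = x - y: mean difference, CI, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 2:
        raise InputError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedContrast(
            mean_difference=mean,
            ci_low=mean,
            ci_high=mean,
            p_value=1.0 if mean == 0.0 else 0.0,
            n=n,
            degenerate=True,
        )
    se = sd / math.sqrt(n)
    tcrit = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1))
    t = mean / se
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return PairedContrast(
        mean_difference=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
        p_value=p,
        n=n,
        degenerate=False,
    )


def threshold_ratio(single_means: tuple[float, float], serial_mean: float) -> float:
    """Ratio of the pooled single-application mean threshold to the serial
    mean; the study's headline "factor" (reported to one decimal)."""
    if serial_mean <= 0:
        raise InputError("serial mean must be > 0")
    return (single_means[0] + single_means[1]) / 2.0 / serial_mean
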