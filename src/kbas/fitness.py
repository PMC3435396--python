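"""Model fitness: two-sample t comparison of score distributions.

The fitness of a model is the two-sided p-value of a two-sample t-test
between the case and control score distributions — smaller p means a
fitter model.  Welch's unequal-variance form is the default (group sizes
in real cohorts are rarely balanced); the pooled-variance Student form is
available via ``equal_var=True``.  p-values are also kept in natural-log
space so models can still be ranked when p underflows double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special, stats

from .genotypes import CohortPair
from .scoring import DEFAULT_ALPHA, GenotypeFrequencyTable, SnpModel, score_cohorts

_TINY = np.nextafter(0.0, 1.0)


def _log_t_sf(t: np.ndarray | float, df: np.ndarray | float) -> np.ndarray:
    """log of the Student-t survival function, stable far into the tail.

    ``scipy.stats.t.logsf`` underflows to -inf once sf leaves double
    range; extreme t statistics still need a finite ordering key, so the
    deep tail is evaluated through the leading incomplete-beta series
    sf(t) = I_x(a, 1/2)/2, x = df/(df+t^2), a = df/2, with
    log I_x(a,b) = a ln x + b ln(1-x) - ln a - ln B(a,b)
                   + ln 2F1(1, a+b; a+1; x).
    """
    t = np.abs(np.asarray(t, dtype=float))
    df = np.asarray(df, dtype=float)
    out = stats.t.logsf(t, df)
    deep = ~np.isfinite(out) & np.isfinite(t)
    if np.any(deep):
        tt, dd = np.broadcast_arrays(t, df)
        a = dd[deep] / 2.0
        x = dd[deep] / (dd[deep] + tt[deep] ** 2)
        tail = (
            a * np.log(x)
            + 0.5 * np.log1p(-x)
            - np.log(a)
            - special.betaln(a, 0.5)
            + np.log(special.hyp2f1(1.0, a + 0.5, a + 1.0, x))
            - math.log(2.0)
        )
        out = np.array(out, dtype=float)
        out[deep] = tail
    return out


@dataclass(frozen=True)
class FitnessResult:
    """t statistic and two-sided p for a case/control score comparison.

    ``log_p`` is the natural log of the p-value, computed directly in log
    space; when ``p_value`` underflows to 0.0, ``log_p`` still orders
    models.  ``degenerate`` marks comparisons where both samples were
    constant.  Ordering (`sort_key`): smaller p is fitter, ties break by
    larger |t|, then by fewer active SNPs (parsimony).
    """

    t_statistic: float
    p_value: float
    n1: int
    n2: int
    df: float
    log_p: float
    n_active: int = 0
    degenerate: bool = False

    @property
    def sort_key(self) -> tuple[float, float, int]:
        return (self.log_p, -abs(self.t_statistic), self.n_active)

    def is_fitter_than(self, other: "FitnessResult") -> bool:
        return self.sort_key < other.sort_key


def welch_t_test(
    sample1: Sequence[float] | np.ndarray,
    sample2: Sequence[float] | np.ndarray,
    equal_var: bool = False,
    n_active: int = 0,
) -> FitnessResult:
    """Two-sample t-test returning a :class:`FitnessResult`.

    Degenerate inputs are mapped deterministically: both samples constant
    and equal gives ``t = 0, p = 1``; both constant but unequal gives the
    smallest positive double as p (flagged degenerate).
    """
    x = np.asarray(sample1, dtype=float)
    y = np.asarray(sample2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    n1, n2 = x.size, y.size
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return FitnessResult(0.0, 1.0, n1, n2, float(n1 + n2 - 2), 0.0, n_active, True)
        return FitnessResult(
            math.copysign(math.inf, m1 - m2),
            _TINY,
            n1,
            n2,
            float(n1 + n2 - 2),
            math.log(_TINY),
            n_active,
            True,
        )
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = float(n1 + n2 - 2)
    else:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = (m1 - m2) / math.sqrt(se2)
    log_p = math.log(2.0) + float(_log_t_sf(abs(t), df))
    p = min(1.0, math.exp(log_p)) if log_p > math.log(_TINY) else 0.0
    return FitnessResult(float(t), float(p), n1, n2, float(df), log_p, n_active)


def batch_welch_t(
    scores1: np.ndarray, scores2: np.ndarray, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise Welch t and log p for score matrices (n_subjects, n_models).

    Vectorized path used by the GA engine; semantics per column match
    :func:`welch_t_test` (degenerate columns get t=0/log_p=0 when equal,
    log of smallest positive double when unequal).
    """
    n1, n2 = scores1.shape[0], scores2.shape[0]
    m1, m2 = scores1.mean(axis=0), scores2.mean(axis=0)
    v1 = scores1.var(axis=0, ddof=1)
    v2 = scores2.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = np.full_like(se2, float(n1 + n2 - 2))
    else:
        se2 = v1 / n1 + v2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    zero_se = se2 == 0.0
    if zero_se.any():
        equal = zero_se & (m1 == m2)
        t = np.where(equal, 0.0, t)
        t = np.where(zero_se & ~equal, np.copysign(np.inf, m1 - m2), t)
        df = np.where(zero_se, float(n1 + n2 - 2), df)
    log_p = np.log(2.0) + _log_t_sf(np.abs(t), df)
    log_p = np.where(np.isinf(t), math.log(_TINY), log_p)
    log_p = np.where((se2 == 0.0) & (m1 == m2), 0.0, log_p)
    return t, log_p


def model_fitness(
    pair: CohortPair,
    model: SnpModel,
    alpha: float = DEFAULT_ALPHA,
    frozen_tables: tuple[GenotypeFrequencyTable, GenotypeFrequencyTable] | None = None,
    equal_var: bool = False,
) -> FitnessResult:
    """Fitness of ``model`` on ``pair``: score both groups, then t-test.

    Note that with frequencies estimated from the pair being tested the
    fitness is an in-sample quantity and is anti-conservative under the
    null (each group scores its own subjects with probabilities fitted to
    itself); calibrated significance statements come from the permutation
    test and from frozen-model transfer to an independent comparison.
    """
    s1, s2 = score_cohorts(pair, model, alpha=alpha, frozen_tables=frozen_tables)
    return welch_t_test(s1.scores, s2.scores, equal_var=equal_var, n_active=model.n_active)


def bonferroni_threshold(alpha: float, factors: Iterable[int]) -> float:
    """Bonferroni-adjusted significance level: ``alpha / prod(factors)``.

    ``factors`` are the multiplicity sources of the study design (number
    of artificial chromosomes, generations, hypotheses, pairwise
    comparisons, ...); an empty list returns ``alpha`` unchanged.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    prod = 1
    for f in factors:
        if int(f) != f or f < 1:
            raise ValueError(f"factors must be positive integers, got {f}")
        prod *= int(f)
    return alpha / prod
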