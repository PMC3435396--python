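"""Risk quantification from model scores.

Given the per-subject scores of one or more disease-associated models,
this module fits logistic regressions of disease state on the scores
(with optional pairwise interactions and stepwise term selection),
reports Wald statistics, odds ratios, the Hosmer-Lemeshow calibration
test and the c-statistic, and builds the disease-risk/score-class
diagram: the pooled score range is cut into equal-width bins and each
bin's posterior probability of disease is computed with Bayes' rule

    P(D | bin) = P(bin | D) pi / [P(bin | D) pi + P(bin | H) (1 - pi)],

where the prior pi defaults to the sample case fraction.  Because
case/control sampling fractions are design choices rather than disease
prevalence, pi is explicitly overridable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import SnpModel

logger = logging.getLogger(__name__)


@dataclass
class LogisticFit:
    """Coefficients and Wald inference for one logistic regression.

    ``terms`` always starts with "intercept".  ``odds_ratios`` and their
    95% CIs are per-term ``exp(coef)``; intercept included for
    completeness.  ``converged`` is False when the IRLS fit did not
    converge or (quasi-)separation was detected.
    """

    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_chi2: np.ndarray
    p_values: np.ndarray
    odds_ratios: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    log_likelihood: float
    converged: bool
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "std_error": self.standard_errors,
                "wald_chi2": self.wald_chi2,
                "p_value": self.p_values,
                "odds_ratio": self.odds_ratios,
                "or_ci_low": self.or_ci_low,
                "or_ci_high": self.or_ci_high,
            },
            index=self.terms,
        )


@dataclass
class RiskBinTable:
    """Score-class diagram: per-bin case/control counts and Bayes posterior."""

    bin_edges: np.ndarray
    count_case: np.ndarray
    count_control: np.ndarray
    posterior_risk: np.ndarray  # NaN for empty bins
    prior: float

    @property
    def n_bins(self) -> int:
        return len(self.count_case)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count_case": self.count_case,
                "count_control": self.count_control,
                "posterior_risk": self.posterior_risk,
            }
        )


def overall_score_model(models: Sequence[SnpModel]) -> SnpModel:
    """Union of all active SNPs across models, every weight set to 1.

    This is the single "overall" model whose score is regressed against
    disease state and binned for the risk diagram.
    """
    if not models:
        raise ValueError("need at least one model")
    seen: list[str] = []
    have: set[str] = set()
    for m in models:
        for snp in m.active_snp_ids:
            if snp not in have:
                have.add(snp)
                seen.append(snp)
    return SnpModel(seen, [1] * len(seen), bits_per_weight=1)


def fit_logistic(
    X: np.ndarray | pd.DataFrame,
    y: Sequence[int] | np.ndarray,
    term_names: Sequence[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS via statsmodels).

    An intercept column is always prepended.  Perfect separation or
    non-convergence is flagged on the result instead of raising, so
    callers can report the diagnostic.
    """
    import statsmodels.api as sm

    if isinstance(X, pd.DataFrame):
        if term_names is None:
            term_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if term_names is None:
        term_names = [f"x{j+1}" for j in range(X.shape[1])]
    design = sm.add_constant(X, has_constant="add")
    terms = ["intercept"] + list(term_names)

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.ConvergenceWarning)
        try:
            res = sm.Logit(y, design).fit(maxiter=max_iter, tol=tol, disp=False)
            converged = bool(res.mle_retvals.get("converged", True))
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ):
            # refit without the separation guard to still report estimates
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                    maxiter=max_iter, tol=tol
                )
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        chi2 = (coef / se) ** 2
        p = stats.chi2.sf(chi2, df=1)
        z = stats.norm.ppf(0.975)
        odds = np.exp(coef)
        ci_low = np.exp(coef - z * se)
        ci_high = np.exp(coef + z * se)
    return LogisticFit(
        terms=terms,
        coefficients=coef,
        standard_errors=se,
        wald_chi2=chi2,
        p_values=p,
        odds_ratios=odds,
        or_ci_low=ci_low,
        or_ci_high=ci_high,
        log_likelihood=float(res.llf),
        converged=converged,
        n_obs=int(len(y)),
    )


def pairwise_interaction_design(scores: pd.DataFrame) -> pd.DataFrame:
    """Main-effect columns plus all pairwise products ``a*b`` (raw, uncentered)."""
    out = scores.copy()
    cols = list(scores.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            out[f"{cols[i]}*{cols[j]}"] = scores[cols[i]] * scores[cols[j]]
    return out


def stepwise_select(
    design: pd.DataFrame,
    y: Sequence[int] | np.ndarray,
    entry_p: float = 0.05,
    stay_p: float = 0.05,
    max_iter: int = 100,
) -> LogisticFit:
    """Forward stepwise selection with backward checks on Wald p-values.

    At each step the candidate term with the smallest Wald p below
    ``entry_p`` (in a fit together with the current terms) enters; after
    each entry any retained term whose Wald p rises above ``stay_p`` is
    dropped (most recent entry exempt that round).  Deterministic given
    the data; may retain only the intercept.
    """
    y = np.asarray(y, dtype=float)
    remaining = list(design.columns)
    selected: list[str] = []
    while True:
        best_term, best_p = None, entry_p
        for term in remaining:
            trial = selected + [term]
            fit = fit_logistic(design[trial], y, trial, max_iter=max_iter)
            p_term = fit.p_values[fit.terms.index(term)]
            if np.isfinite(p_term) and p_term < best_p:
                best_term, best_p = term, p_term
        if best_term is None:
            break
        selected.append(best_term)
        remaining.remove(best_term)
        # backward purge of terms that lost significance
        while True:
            fit = fit_logistic(design[selected], y, selected, max_iter=max_iter)
            worst_term, worst_p = None, stay_p
            for term in selected:
                if term == best_term:
                    continue
                p_term = fit.p_values[fit.terms.index(term)]
                if not np.isfinite(p_term) or p_term > worst_p:
                    worst_term, worst_p = term, p_term
            if worst_term is None:
                break
            selected.remove(worst_term)
            remaining.append(worst_term)
    if selected:
        return fit_logistic(design[selected], y, selected, max_iter=max_iter)
    return fit_logistic(np.empty((len(y), 0)), y, [], max_iter=max_iter)


def hosmer_lemeshow(
    fitted_probs: Sequence[float] | np.ndarray,
    outcomes: Sequence[int] | np.ndarray,
    n_groups: int = 10,
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration test over deciles of fitted risk.

    Returns ``(chi2, df, p)`` with ``df = n_groups - 2`` (df is kept at
    the nominal group count even if sparsely populated groups had to be
    merged; merges are logged).
    """
    probs = np.asarray(fitted_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if n_groups < 3:
        raise ValueError("n_groups must be >= 3")
    order = np.argsort(probs, kind="stable")
    probs, y = probs[order], y[order]
    edges = (len(probs) * np.arange(1, n_groups + 1)) // n_groups
    start = 0
    groups: list[tuple[float, float, int]] = []  # (observed, expected, n)
    for end in edges:
        if end <= start:
            continue
        seg_p, seg_y = probs[start:end], y[start:end]
        groups.append((float(seg_y.sum()), float(seg_p.sum()), end - start))
        start = end
    # merge groups whose expected count is 0 into the neighbor above
    merged: list[tuple[float, float, int]] = []
    for g in groups:
        if merged and (merged[-1][1] == 0.0 or merged[-1][1] == merged[-1][2]):
            logger.info("hosmer_lemeshow: merging a degenerate risk group")
            prev = merged.pop()
            g = (prev[0] + g[0], prev[1] + g[1], prev[2] + g[2])
        merged.append(g)
    chi2 = 0.0
    for obs, exp, n in merged:
        denom = exp * (1.0 - exp / n)
        if denom == 0.0:
            if obs != exp:
                chi2 = float("inf")
            continue
        chi2 += (obs - exp) ** 2 / denom
    df = n_groups - 2
    return float(chi2), int(df), float(stats.chi2.sf(chi2, df))


def c_statistic(
    scores: Sequence[float] | np.ndarray, outcomes: Sequence[int] | np.ndarray
) -> float:
    """Concordance (AUC): P(random case outranks random control), ties 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    cases = s[y == 1]
    controls = s[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(s)  # midranks handle ties
    rank_sum_cases = ranks[np.asarray(y) == 1].sum()
    n1, n0 = len(cases), len(controls)
    u = rank_sum_cases - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def risk_bin_diagram(
    scores_case: Sequence[float] | np.ndarray,
    scores_control: Sequence[float] | np.ndarray,
    n_bins: int = 12,
    prior: float | None = None,
    equal_frequency: bool = False,
) -> RiskBinTable:
    """Discretize the pooled score range and compute per-bin disease risk.

    Default binning is equal-width over the pooled observed range
    (``equal_frequency=True`` switches to quantile bins of the pooled
    scores).  Empty bins get a NaN posterior.  If every score is
    identical the table degrades to a single bin (logged).
    """
    sc = np.asarray(scores_case, dtype=float)
    sh = np.asarray(scores_control, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if prior is None:
        prior = len(sc) / (len(sc) + len(sh))
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must be in (0, 1)")
    pooled = np.concatenate([sc, sh])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        logger.info("risk_bin_diagram: degenerate score range, single bin")
        edges = np.array([lo, hi])
    elif equal_frequency:
        qs = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(qs)
        if len(edges) < 2:
            edges = np.array([lo, hi])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    nb = len(edges) - 1
    idx_case = np.clip(np.digitize(sc, edges[1:-1], right=False), 0, nb - 1)
    idx_ctrl = np.clip(np.digitize(sh, edges[1:-1], right=False), 0, nb - 1)
    count_case = np.bincount(idx_case, minlength=nb).astype(float)
    count_ctrl = np.bincount(idx_ctrl, minlength=nb).astype(float)
    p_bin_case = count_case / count_case.sum()
    p_bin_ctrl = count_ctrl / count_ctrl.sum()
    num = p_bin_case * prior
    den = num + p_bin_ctrl * (1.0 - prior)
    with np.errstate(invalid="ignore"):
        posterior = np.where(den > 0, num / den, np.nan)
    return RiskBinTable(
        bin_edges=edges,
        count_case=count_case,
        count_control=count_ctrl,
        posterior_risk=posterior,
        prior=float(prior),
    )


def plot_risk_diagram(table: RiskBinTable, path: str) -> None:
    """Bar chart of per-bin posterior disease risk (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (table.bin_edges[:-1] + table.bin_edges[1:])
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(
        np.arange(table.n_bins),
        table.posterior_risk,
        color="#4878a8",
        tick_label=[f"{c:.2g}" for c in centers],
    )
    ax.axhline(table.prior, color="grey", linestyle="--", label=f"prior = {table.prior:.2f}")
    ax.set_xlabel("score class (bin center)")
    ax.set_ylabel("posterior P(disease | score class)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
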