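"""Permutation validation and the three-way association verdict.

The fitness of a trained model is an in-sample quantity, so its nominal
p-value is not taken at face value.  Instead, holding every subject's
score fixed, the case/control labels are shuffled (preserving group
sizes) and the fitness recomputed each round; the empirical p-value is
the fraction of permuted fitnesses at least as extreme as the observed
one, with the (b+1)/(N+1) estimator so it is never exactly zero.  When no
permutation beats the observed fitness the report carries the
conventional upper-bound form "<1/N" (e.g. "<1e-05" at 100,000 rounds).

A model tested against two independent control groups is classified:
significant in both comparisons -> strong association; non-significant in
at least one -> none; anything else -> moderate.  The verdict is flagged
invalid when the model also separates the two control groups from each
other, which a disease-driven model must not do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fitness import batch_welch_t, welch_t_test

SIGNIFICANT = "significant"
BORDERLINE = "borderline"
NON_SIGNIFICANT = "non_significant"

STRONG = "strong"
MODERATE = "moderate"
NONE = "none"


@dataclass(frozen=True)
class PermutationResult:
    observed_p: float
    observed_log_p: float
    n_rounds: int
    n_as_extreme: int
    empirical_p: float
    upper_bound_string: str
    seed: int


@dataclass(frozen=True)
class AssociationVerdict:
    verdict: str  # strong | moderate | none
    statuses: tuple[str, str]
    ctrl_vs_ctrl_p: float | None
    invalid: bool
    sig_threshold: float
    borderline_ceiling: float


def permutation_test(
    scores: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    n_rounds: int,
    seed: int = 0,
    equal_var: bool = False,
) -> PermutationResult:
    """Label-permutation test of a fitness value with scores held constant.

    ``labels`` is binary (1 = group 1 / case, 0 = group 2 / control); the
    observed fitness is the Welch p of group1-vs-group2 scores.  Each
    round permutes the labels while preserving the two group sizes; a
    round counts as "as extreme" when its fitness p (compared in log
    space) is <= the observed one.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be parallel")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must contain exactly two groups")
    mask1 = labels == uniq.max()
    n1 = int(mask1.sum())
    observed = welch_t_test(scores[mask1], scores[~mask1], equal_var=equal_var)

    rng = np.random.default_rng(seed)
    n = len(scores)
    # permute in blocks to bound memory at large round counts
    block = max(1, min(n_rounds, 4_000_000 // max(n, 1)))
    n_as_extreme = 0
    done = 0
    while done < n_rounds:
        b = min(block, n_rounds - done)
        perm_scores = np.empty((n, b))
        for k in range(b):
            perm_scores[:, k] = scores[rng.permutation(n)]
        _t, log_p = batch_welch_t(
            perm_scores[:n1], perm_scores[n1:], equal_var=equal_var
        )
        n_as_extreme += int((log_p <= observed.log_p).sum())
        done += b
    empirical_p = (n_as_extreme + 1) / (n_rounds + 1)
    if n_as_extreme == 0:
        bound = f"<{1.0 / n_rounds:.6g}"
    else:
        bound = f"{empirical_p:.6g}"
    return PermutationResult(
        observed_p=observed.p_value,
        observed_log_p=observed.log_p,
        n_rounds=n_rounds,
        n_as_extreme=n_as_extreme,
        empirical_p=empirical_p,
        upper_bound_string=bound,
        seed=seed,
    )


def classify_comparison(
    p: float, sig_threshold: float, borderline_ceiling: float = 0.05
) -> str:
    """Three-band status of one comparison's p-value.

    ``p < sig_threshold`` -> significant; up to ``borderline_ceiling``
    (inclusive) -> borderline; above -> non-significant.
    """
    if not sig_threshold < borderline_ceiling:
        raise ValueError("sig_threshold must be below borderline_ceiling")
    if p < sig_threshold:
        return SIGNIFICANT
    if p <= borderline_ceiling:
        return BORDERLINE
    return NON_SIGNIFICANT


def classify_model(
    status_vs_ctrl1: str,
    status_vs_ctrl2: str,
    ctrl_vs_ctrl_p: float | None = None,
    sig_threshold: float = 0.00104,
    borderline_ceiling: float = 0.05,
) -> AssociationVerdict:
    """Combine the two case-vs-control statuses into a verdict.

    Both significant -> strong; any non-significant -> none; otherwise
    moderate.  When ``ctrl_vs_ctrl_p`` is given and itself significant the
    verdict is additionally flagged invalid: a model that separates the
    two control groups is learning cohort structure, not disease.
    """
    statuses = (status_vs_ctrl1, status_vs_ctrl2)
    for s in statuses:
        if s not in (SIGNIFICANT, BORDERLINE, NON_SIGNIFICANT):
            raise ValueError(f"unknown status {s!r}")
    if all(s == SIGNIFICANT for s in statuses):
        verdict = STRONG
    elif any(s == NON_SIGNIFICANT for s in statuses):
        verdict = NONE
    else:
        verdict = MODERATE
    invalid = (
        ctrl_vs_ctrl_p is not None
        and classify_comparison(ctrl_vs_ctrl_p, sig_threshold, borderline_ceiling)
        == SIGNIFICANT
    )
    return AssociationVerdict(
        verdict=verdict,
        statuses=statuses,
        ctrl_vs_ctrl_p=ctrl_vs_ctrl_p,
        invalid=invalid,
        sig_threshold=sig_threshold,
        borderline_ceiling=borderline_ceiling,
    )
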