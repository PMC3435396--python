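"""Self-contained evaluation benchmarks for the whole pipeline.

Each function builds its own synthetic study conditions, runs the
relevant pipeline stage, and returns plain numbers, so the same code
backs both the test suite and the reproduction script.

Benchmark conditions
--------------------
* Planted-marker search: 200 SNPs, 5 causal markers at control MAF 0.20
  shifted by +0.09 in cases (single-SNP Welch p around 1e-10 at 1000
  subjects per group), search with the default GA configuration.
* Matched null search: the same cohort sizes and SNP count with no
  planted effect, asking how often the search reaches the study-wide
  6.944e-9 significance level.
* Permutation calibration: iid (exchangeable) scores for both groups;
  the empirical permutation p-value must be uniform.
* Genetic heterogeneity: three loci at MAF 0.3, disease requires any two
  of the three risk genotypes (penetrances 0.9 / 0.05); the joint
  3-locus model must dominate every single-locus model.
* Risk diagram: a planted multi-SNP effect scored with the true model,
  binned into 12 score classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fitness import bonferroni_threshold, model_fitness
from .ga import GaConfig, run_ga
from .association import permutation_test
from .risk import c_statistic, risk_bin_diagram
from .scoring import SnpModel, score_cohorts
from .simulate import (
    SimulationSpec,
    simulate_heterogeneous_pair,
    simulate_null_pair,
    simulate_shifted_pair,
)

#: study-wide significance level from the canonical study design:
#: 0.05 / (200 chromosomes x 500 generations x 24 hypotheses x 3 comparisons)
GENOME_THRESHOLD = bonferroni_threshold(0.05, [200, 500, 24, 3])

PLANTED_N_SNPS = 200
PLANTED_N_CAUSAL = 5
PLANTED_BASE_MAF = 0.20
PLANTED_DELTA = 0.09
PLANTED_N_PER_GROUP = 1000


def _planted_spec(seed: int) -> SimulationSpec:
    return SimulationSpec(
        n_case=PLANTED_N_PER_GROUP,
        n_control=PLANTED_N_PER_GROUP,
        n_snps=PLANTED_N_SNPS,
        causal_snps={j: PLANTED_DELTA for j in range(PLANTED_N_CAUSAL)},
        causal_base_maf=PLANTED_BASE_MAF,
        seed=seed,
    )


def planted_recovery_benchmark(n_seeds: int = 20, seed0: int = 1) -> dict:
    """Fraction of seeded searches whose best model contains >= 4 of the 5
    planted SNPs, plus model-size statistics."""
    recovered, n_active, single_log10 = [], [], []
    for k in range(n_seeds):
        spec = _planted_spec(seed0 + k)
        pair = simulate_shifted_pair(spec)
        causal_ids = [pair.snp_ids[j] for j in range(PLANTED_N_CAUSAL)]
        res = run_ga(pair, pair.snp_ids, GaConfig(rng_seed=seed0 + k))
        hits = sum(1 for s in causal_ids if s in set(res.best_model.active_snp_ids))
        recovered.append(hits)
        n_active.append(res.best_model.n_active)
        single_log10.append(
            float(
                np.median(
                    [
                        model_fitness(pair, SnpModel([s], [1])).log_p / math.log(10)
                        for s in causal_ids
                    ]
                )
            )
        )
    return {
        "n_seeds": n_seeds,
        "recovered_counts": recovered,
        "fraction_with_4_of_5": sum(r >= 4 for r in recovered) / n_seeds,
        "median_model_size": float(np.median(n_active)),
        "median_single_snp_log10_p": float(np.median(single_log10)),
    }


def null_threshold_benchmark(n_seeds: int = 20, seed0: int = 1001) -> dict:
    """How often the search on matched null data reaches the study-wide
    threshold (the search stops as soon as it does)."""
    reached = []
    for k in range(n_seeds):
        spec = SimulationSpec(
            n_case=PLANTED_N_PER_GROUP,
            n_control=PLANTED_N_PER_GROUP,
            n_snps=PLANTED_N_SNPS,
            seed=seed0 + k,
        )
        pair = simulate_null_pair(spec)
        res = run_ga(
            pair,
            pair.snp_ids,
            GaConfig(rng_seed=seed0 + k, desired_fitness=GENOME_THRESHOLD),
        )
        reached.append(res.best_fitness.log_p <= math.log(GENOME_THRESHOLD))
    return {
        "n_seeds": n_seeds,
        "n_reached": int(sum(reached)),
        "rate_reached": sum(reached) / n_seeds,
        "threshold": GENOME_THRESHOLD,
    }


def permutation_calibration_benchmark(
    n_replicates: int = 500,
    n_rounds: int = 199,
    n_per_group: int = 50,
    seed: int = 7,
) -> dict:
    """KS uniformity of the empirical permutation p under an exchangeable
    null (iid scores, labels carry no information)."""
    rng = np.random.default_rng(seed)
    labels = np.concatenate(
        [np.ones(n_per_group, int), np.zeros(n_per_group, int)]
    )
    ps = []
    for rep in range(n_replicates):
        scores = rng.normal(size=2 * n_per_group)
        res = permutation_test(
            scores, labels, n_rounds=n_rounds, seed=int(rng.integers(2**31))
        )
        ps.append(res.empirical_p)
    ks = stats.kstest(ps, "uniform")
    return {
        "n_replicates": n_replicates,
        "n_rounds": n_rounds,
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "mean_empirical_p": float(np.mean(ps)),
    }


def heterogeneity_benchmark(
    seed: int = 3, n_per_group: int = 1000, n_snps: int = 50
) -> dict:
    """Joint-vs-marginal contrast in the 2-of-3-loci disease model.

    Returns the log10 fitness p of the joint 3-locus model and the median
    log10 p of the three single-locus models; the gap (median single
    minus joint) is the order-of-magnitude advantage of modeling the
    loci jointly.
    """
    spec = SimulationSpec(
        n_case=n_per_group,
        n_control=n_per_group,
        n_snps=n_snps,
        maf_range=(0.3, 0.3),
        causal_snps={0: 0.0, 1: 0.0, 2: 0.0},
        penetrance_high=0.9,
        penetrance_low=0.05,
        seed=seed,
    )
    pair = simulate_heterogeneous_pair(spec)
    causal_ids = pair.snp_ids[:3]
    joint = model_fitness(pair, SnpModel(causal_ids, [1, 1, 1]))
    singles = [model_fitness(pair, SnpModel([s], [1])) for s in causal_ids]
    joint_log10 = joint.log_p / math.log(10)
    single_log10 = float(np.median([s.log_p / math.log(10) for s in singles]))
    return {
        "n_per_group": n_per_group,
        "joint_log10_p": joint_log10,
        "median_single_log10_p": single_log10,
        "log10_gap": single_log10 - joint_log10,
    }


def risk_diagram_benchmark(
    seed: int = 5, n_per_group: int = 2000, n_causal: int = 8
) -> dict:
    """Score a planted multi-SNP effect with the true model and check the
    12-bin diagram: exact total-probability conservation and a monotone
    rising posterior (Spearman of posterior vs bin index)."""
    spec = SimulationSpec(
        n_case=n_per_group,
        n_control=n_per_group,
        n_snps=50,
        causal_snps={j: 0.1 for j in range(n_causal)},
        causal_base_maf=0.25,
        seed=seed,
    )
    pair = simulate_shifted_pair(spec)
    model = SnpModel(pair.snp_ids[:n_causal], [1] * n_causal)
    s1, s2 = score_cohorts(pair, model)
    table = risk_bin_diagram(s1.scores, s2.scores, n_bins=12)
    occupied = np.isfinite(table.posterior_risk)
    p_bin = (table.count_case + table.count_control) / (
        table.count_case.sum() + table.count_control.sum()
    )
    conservation_error = abs(
        float(np.nansum(p_bin[occupied] * table.posterior_risk[occupied]))
        - table.prior
    )
    idx = np.arange(table.n_bins)[occupied]
    rho = stats.spearmanr(idx, table.posterior_risk[occupied]).statistic
    y = np.concatenate([np.ones(len(s1.scores)), np.zeros(len(s2.scores))])
    auc = c_statistic(np.concatenate([s1.scores, s2.scores]), y)
    return {
        "n_per_group": n_per_group,
        "spearman_bin_vs_posterior": float(rho),
        "conservation_error": conservation_error,
        "c_statistic": float(auc),
        "prior": table.prior,
        "posterior_low": float(table.posterior_risk[occupied][0]),
        "posterior_high": float(table.posterior_risk[occupied][-1]),
    }
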