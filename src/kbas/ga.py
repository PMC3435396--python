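"""Genetic-algorithm search over binary weight chromosomes.

Each candidate model is an artificial chromosome: a bit vector of length
``n_snps * bits_per_weight`` encoding one unsigned integer weight per SNP
(most-significant bit first; with one bit per weight, a bit simply marks
whether the SNP is in the model).  Each generation the population is
ranked by fitness (the two-sided t-test p of the case/control score
separation, smaller = fitter), the bottom half is discarded, and the
surviving half is refilled with offspring produced by uniform crossover
of two distinct survivors followed by per-bit mutation — the truncation
variant of an elitist (CHC-family) scheme.  Canonical CHC ingredients
(HUX crossover, incest prevention, cataclysmic restarts) are available
behind config flags for users who want the stricter variant.

The number of active SNPs is free to drift up or down under crossover and
mutation; offspring that decode to an all-zero (unscoreable) model are
re-mutated until at least one weight is nonzero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .fitness import FitnessResult, batch_welch_t, welch_t_test
from .genotypes import CohortPair
from .scoring import (
    DEFAULT_ALPHA,
    SnpModel,
    estimate_genotype_frequencies,
    log_ratio_table,
    _contributions,
)


@dataclass
class GaConfig:
    """Tunable parameters of the search.

    Defaults mirror a typical run: 200 chromosomes evolved for 500
    generations, one bit per SNP weight, about 10 active SNPs per initial
    chromosome.  ``desired_fitness`` (a p-value, usually the
    Bonferroni-adjusted level) enables early stopping when set; when
    ``None`` the search always runs ``max_generations`` and reports the
    best chromosome seen.  ``mutation_rate_per_bit=None`` means 1/L where
    L is the chromosome length.
    """

    population_size: int = 200
    max_generations: int = 500
    bits_per_weight: int = 1
    init_active_snps: int = 10
    crossover_rate: float = 1.0
    mutation_rate_per_bit: float | None = None
    desired_fitness: float | None = None
    rng_seed: int = 0
    equal_var: bool = False
    # canonical-CHC extras (off by default; the default scheme is plain
    # truncation selection with uniform crossover + mutation)
    hux_crossover: bool = False
    incest_threshold: int | None = None
    cataclysm: bool = False

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.bits_per_weight < 1:
            raise ValueError("bits_per_weight must be >= 1")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.mutation_rate_per_bit is not None and not (
            0.0 <= self.mutation_rate_per_bit <= 1.0
        ):
            raise ValueError("mutation_rate_per_bit must be in [0, 1]")


@dataclass
class Chromosome:
    """A bit vector plus (optionally) its evaluated fitness."""

    bits: np.ndarray
    fitness: FitnessResult | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)


@dataclass
class GaRunResult:
    best_model: SnpModel
    best_fitness: FitnessResult
    generations_run: int
    fitness_trajectory: list[dict]
    seed: int
    stop_reason: str
    n_evaluations: int


def decode_chromosome(
    bits: np.ndarray | Chromosome, snp_ids: Sequence[str], bits_per_weight: int = 1
) -> SnpModel:
    """Decode a bit vector into a :class:`SnpModel` (MSB-first per weight)."""
    if isinstance(bits, Chromosome):
        bits = bits.bits
    bits = np.asarray(bits, dtype=bool)
    n = len(snp_ids)
    if bits.shape != (n * bits_per_weight,):
        raise ValueError(
            f"bit vector length {bits.shape} inconsistent with "
            f"{n} SNPs x {bits_per_weight} bits"
        )
    groups = bits.reshape(n, bits_per_weight)
    place = 1 << np.arange(bits_per_weight - 1, -1, -1)
    weights = (groups * place).sum(axis=1)
    return SnpModel(list(snp_ids), weights.tolist(), bits_per_weight)


def encode_weights(weights: Sequence[int], bits_per_weight: int = 1) -> np.ndarray:
    """Inverse of :func:`decode_chromosome` for a weight vector."""
    out = np.zeros(len(weights) * bits_per_weight, dtype=bool)
    for j, w in enumerate(weights):
        if not 0 <= w < (1 << bits_per_weight):
            raise ValueError(f"weight {w} does not fit in {bits_per_weight} bits")
        for b in range(bits_per_weight):
            out[j * bits_per_weight + b] = bool((w >> (bits_per_weight - 1 - b)) & 1)
    return out


def initialize_population(
    config: GaConfig, n_snps: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """(population_size, n_snps * bits_per_weight) boolean population.

    Each chromosome activates ``init_active_snps`` distinct random SNPs
    with a uniformly drawn nonzero weight; all other weights are 0.
    """
    if n_snps < config.init_active_snps:
        raise ValueError(
            f"n_snps={n_snps} smaller than init_active_snps={config.init_active_snps}"
        )
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    L = n_snps * config.bits_per_weight
    pop = np.zeros((config.population_size, L), dtype=bool)
    cap = 1 << config.bits_per_weight
    for i in range(config.population_size):
        snps = rng.choice(n_snps, size=config.init_active_snps, replace=False)
        for j in snps:
            w = int(rng.integers(1, cap))
            for b in range(config.bits_per_weight):
                pop[i, j * config.bits_per_weight + b] = bool(
                    (w >> (config.bits_per_weight - 1 - b)) & 1
                )
    return pop


def _weights_matrix(pop: np.ndarray, n_snps: int, bits_per_weight: int) -> np.ndarray:
    """(n_chromosomes, n_snps) float weight matrix decoded from bits."""
    groups = pop.reshape(pop.shape[0], n_snps, bits_per_weight)
    place = 1 << np.arange(bits_per_weight - 1, -1, -1)
    return (groups * place).sum(axis=2).astype(float)


def _offspring(
    survivors: np.ndarray, config: GaConfig, rng: np.random.Generator, n_snps: int
) -> np.ndarray:
    """Produce ``len(survivors)`` offspring by crossover + mutation."""
    n, L = survivors.shape
    mut = config.mutation_rate_per_bit if config.mutation_rate_per_bit is not None else 1.0 / L
    out = np.empty_like(survivors)
    for k in range(n):
        pa, pb = rng.choice(n, size=2, replace=False)
        a, b = survivors[pa], survivors[pb]
        if config.incest_threshold is not None and int(np.sum(a ^ b)) <= config.incest_threshold:
            child = a.copy()  # too-similar parents: clone, rely on mutation
        elif rng.random() < config.crossover_rate:
            if config.hux_crossover:
                # HUX: swap exactly half of the differing bits
                diff = np.where(a ^ b)[0]
                child = a.copy()
                if len(diff) > 1:
                    take = rng.choice(diff, size=len(diff) // 2, replace=False)
                    child[take] = b[take]
            else:
                mask = rng.random(L) < 0.5
                child = np.where(mask, a, b)
        else:
            child = a.copy()
        child = child ^ (rng.random(L) < mut)
        # an all-zero model is unscoreable: re-mutate until active
        while not child.any():
            child = child ^ (rng.random(L) < max(mut, 1.0 / L))
        out[k] = child
    return out


def evolve_generation(
    population: np.ndarray,
    sort_keys: Sequence[tuple],
    config: GaConfig,
    rng: np.random.Generator,
    n_snps: int,
) -> np.ndarray:
    """One truncation-selection cycle: keep the fitter half, refill with
    offspring of the survivors.  ``sort_keys`` must order chromosomes
    fittest-first when sorted ascending (see ``FitnessResult.sort_key``)."""
    order = sorted(range(len(population)), key=lambda i: sort_keys[i])
    half = len(population) // 2
    survivors = population[order[:half]]
    children = _offspring(survivors, config, rng, n_snps)
    return np.vstack([survivors, children])


def run_ga(
    pair: CohortPair,
    snp_set: Sequence[str],
    config: GaConfig | None = None,
    alpha: float = DEFAULT_ALPHA,
    log_callback: Callable[[str], None] | None = None,
) -> GaRunResult:
    """Search for the SNP-weight model that best separates the two groups.

    The cohorts are restricted to ``snp_set``; per-group genotype
    frequencies are estimated once (they do not depend on the weights), so
    each chromosome evaluation reduces to a weighted sum of precomputed
    per-SNP log-ratio contributions followed by a t-test.  Identical bit
    patterns are evaluated once per run (fitness cache).  The returned
    ``best_model`` is the best-ever chromosome; ``fitness_trajectory``
    records per-generation best/median log-p and best active-SNP count.
    """
    config = config or GaConfig()
    snp_set = list(snp_set)
    if not snp_set:
        raise ValueError("snp_set must be nonempty")
    sub = pair.subset_snps(snp_set)
    n_snps = len(snp_set)
    rng = np.random.default_rng(config.rng_seed)

    f1 = estimate_genotype_frequencies(sub.group1, alpha)
    f2 = estimate_genotype_frequencies(sub.group2, alpha)
    lr = log_ratio_table(f1, f2)
    C1 = _contributions(sub.group1.values, lr, snp_set)
    C2 = _contributions(sub.group2.values, lr, snp_set)

    pop = initialize_population(config, n_snps, rng)
    cache: dict[bytes, tuple[float, float, int]] = {}  # bits -> (t, log_p, n_active)
    n_evaluations = 0
    best_key: tuple | None = None
    best_bits: np.ndarray | None = None
    trajectory: list[dict] = []
    threshold_log_p = (
        math.log(config.desired_fitness) if config.desired_fitness else None
    )
    stop_reason = "max_generations"
    gen = 0

    for gen in range(config.max_generations):
        keys = np.array([pop[i].tobytes() for i in range(len(pop))])
        fresh = [i for i in range(len(pop)) if keys[i] not in cache]
        if fresh:
            W = _weights_matrix(pop[fresh], n_snps, config.bits_per_weight)
            t, log_p = batch_welch_t(C1 @ W.T, C2 @ W.T, equal_var=config.equal_var)
            n_active = (W > 0).sum(axis=1)
            n_evaluations += len(fresh)
            for pos, i in enumerate(fresh):
                cache[keys[i]] = (float(t[pos]), float(log_p[pos]), int(n_active[pos]))
        sort_keys = []
        for i in range(len(pop)):
            t_i, lp_i, na_i = cache[keys[i]]
            sort_keys.append((lp_i, -abs(t_i), na_i))
        gen_best = min(range(len(pop)), key=lambda i: sort_keys[i])
        if best_key is None or sort_keys[gen_best] < best_key:
            best_key = sort_keys[gen_best]
            best_bits = pop[gen_best].copy()
        trajectory.append(
            {
                "generation": gen,
                "best_log10_p": sort_keys[gen_best][0] / math.log(10),
                "median_log10_p": float(
                    np.median([k[0] for k in sort_keys]) / math.log(10)
                ),
                "best_n_active": sort_keys[gen_best][2],
            }
        )
        if log_callback is not None:
            rec = trajectory[-1]
            log_callback(
                f"gen {rec['generation']}\tbest_log10_p {rec['best_log10_p']:.3f}\t"
                f"median_log10_p {rec['median_log10_p']:.3f}\t"
                f"best_n_active {rec['best_n_active']}"
            )
        if threshold_log_p is not None and best_key[0] <= threshold_log_p:
            stop_reason = "desired_fitness"
            break
        if gen < config.max_generations - 1:
            pop = evolve_generation(pop, sort_keys, config, rng, n_snps)
            if config.cataclysm and len({k for k in keys}) == 1:
                # population fully converged: keep the best, re-randomize the rest
                pop[1:] = initialize_population(
                    replace(config, population_size=config.population_size),
                    n_snps,
                    rng,
                )[1:]

    best_model = decode_chromosome(best_bits, snp_set, config.bits_per_weight)
    # re-evaluate the winner through the scalar path: bit-reproducible check
    w = np.asarray(best_model.weights, dtype=float)
    best_fitness = welch_t_test(
        C1 @ w, C2 @ w, equal_var=config.equal_var, n_active=best_model.n_active
    )
    return GaRunResult(
        best_model=best_model,
        best_fitness=best_fitness,
        generations_run=gen + 1,
        fitness_trajectory=trajectory,
        seed=config.rng_seed,
        stop_reason=stop_reason,
        n_evaluations=n_evaluations,
    )
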