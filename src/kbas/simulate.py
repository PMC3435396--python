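"""Synthetic case/control genotype cohorts with known structure.

Three generators cover the situations the pipeline has to handle:

* ``simulate_null_pair`` — both groups drawn from identical
  Hardy-Weinberg genotype distributions (no association anywhere).
* ``simulate_shifted_pair`` — planted marginal effects: at each causal
  SNP the case group's minor-allele frequency is shifted by ``delta``
  (HWE proportions re-derived), directly controlling the per-SNP
  genotype-frequency difference the score formula responds to.
* ``simulate_heterogeneous_pair`` — a three-locus heterogeneity model:
  an individual is at risk when at least two of three causal loci carry
  the risk genotype ([A and B] or [A and C] or [B and C]); affected with
  ``penetrance_high`` if at risk, else ``penetrance_low``.  Sampling from
  the population continues until the requested numbers of cases and
  controls are collected.

SNPs are independent (no linkage disequilibrium) and genotypes follow
HWE within each generating group; minor-allele frequencies are drawn
uniformly from ``maf_range``.  Every generator is deterministic given
``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotypes import MISSING, CohortPair, GenotypeMatrix


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationSpec:
    """Parameters of one synthetic cohort pair.

    ``causal_snps`` maps SNP index -> effect parameter; its meaning
    depends on the generator (MAF shift ``delta`` for
    :func:`simulate_shifted_pair`; membership in the risk predicate for
    :func:`simulate_heterogeneous_pair`, where exactly three causal
    indices are required).
    """

    n_case: int = 1000
    n_control: int = 1000
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snps: dict[int, float] = field(default_factory=dict)
    penetrance_high: float = 0.9
    penetrance_low: float = 0.05
    missing_rate: float = 0.0
    causal_base_maf: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range bounds must satisfy 0 < low <= high <= 0.5")
        if any(i < 0 or i >= self.n_snps for i in self.causal_snps):
            raise ValueError("causal SNP indices must lie in [0, n_snps)")
        for rate in (self.missing_rate,):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not (0.0 <= self.penetrance_low <= 1.0 and 0.0 <= self.penetrance_high <= 1.0):
            raise ValueError("penetrances must be in [0, 1]")


def _hwe_genotypes(rng: np.random.Generator, n: int, maf: np.ndarray) -> np.ndarray:
    """Draw (n, len(maf)) genotypes under HWE: P(0)=p^2, P(1)=2pq, P(2)=q^2
    with q the minor-allele frequency."""
    q = np.asarray(maf, dtype=float)
    p0 = (1.0 - q) ** 2
    p1 = 2.0 * q * (1.0 - q)
    u = rng.random((n, len(q)))
    return ((u > p0).astype(np.int8) + (u > p0 + p1).astype(np.int8)).astype(np.int8)


def _apply_missing(
    rng: np.random.Generator, values: np.ndarray, rate: float
) -> np.ndarray:
    if rate > 0.0:
        mask = rng.random(values.shape) < rate
        values = values.copy()
        values[mask] = MISSING
    return values


def _snp_ids(n: int) -> list[str]:
    return [f"snp{j:05d}" for j in range(n)]


def _subject_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def draw_mafs(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.maf_range
    return rng.uniform(lo, hi, spec.n_snps)


def simulate_shifted_pair(spec: SimulationSpec) -> CohortPair:
    """Cohort pair with planted per-SNP MAF shifts in the case group.

    Controls are HWE at MAF ``q``; cases at ``q + delta`` for each causal
    SNP (``delta`` may be negative).  Non-causal SNPs have identical
    generating distributions in both groups.  With an empty causal map
    this is exactly the null generator (bit-identical for equal seeds).
    """
    rng = np.random.default_rng(spec.seed)
    maf = draw_mafs(spec, rng)
    if spec.causal_base_maf is not None:
        for idx in spec.causal_snps:
            maf[idx] = spec.causal_base_maf
    maf_case = maf.copy()
    for idx, delta in spec.causal_snps.items():
        shifted = maf[idx] + delta
        if not 0.0 < shifted <= 0.5:
            raise ValueError(
                f"shifted MAF {shifted:.3f} at SNP index {idx} outside (0, 0.5]"
            )
        maf_case[idx] = shifted
    g_case = _hwe_genotypes(rng, spec.n_case, maf_case)
    g_ctrl = _hwe_genotypes(rng, spec.n_control, maf)
    g_case = _apply_missing(rng, g_case, spec.missing_rate)
    g_ctrl = _apply_missing(rng, g_ctrl, spec.missing_rate)
    snps = _snp_ids(spec.n_snps)
    return CohortPair(
        GenotypeMatrix(_subject_ids("case", spec.n_case), snps, g_case),
        GenotypeMatrix(_subject_ids("ctrl", spec.n_control), snps, g_ctrl),
    )


def simulate_null_pair(spec: SimulationSpec) -> CohortPair:
    """Both groups from identical HWE distributions (no causal SNPs allowed)."""
    if spec.causal_snps:
        raise ValueError("null pair must not declare causal SNPs")
    return simulate_shifted_pair(spec)


def simulate_heterogeneous_pair(
    spec: SimulationSpec,
    min_risk_loci: int = 2,
    risk_genotype_min_minor: int = 1,
    max_batches: int = 10_000,
) -> CohortPair:
    """Genetic-heterogeneity cohort: risk requires >= ``min_risk_loci`` of
    the three causal loci to carry the risk genotype.

    The risk genotype at a locus is carrying at least
    ``risk_genotype_min_minor`` minor alleles.  Individuals are drawn from
    the population under HWE, assigned affected status with probability
    ``penetrance_high`` when at risk and ``penetrance_low`` otherwise,
    and accumulated until ``n_case`` cases and ``n_control`` controls are
    available; exceeding ``max_batches`` population batches raises
    :class:`SimulationError`.
    """
    if len(spec.causal_snps) != 3:
        raise ValueError("heterogeneous model needs exactly 3 causal loci")
    if not spec.penetrance_high > spec.penetrance_low:
        raise ValueError("penetrance_high must exceed penetrance_low")
    rng = np.random.default_rng(spec.seed)
    maf = draw_mafs(spec, rng)
    causal = np.asarray(sorted(spec.causal_snps), dtype=int)
    batch = max(1024, spec.n_case + spec.n_control)
    cases: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    need_case, need_ctrl = spec.n_case, spec.n_control
    for _ in range(max_batches):
        if need_case <= 0 and need_ctrl <= 0:
            break
        g = _hwe_genotypes(rng, batch, maf)
        carries = (g[:, causal] >= risk_genotype_min_minor).sum(axis=1)
        at_risk = carries >= min_risk_loci
        affected = rng.random(batch) < np.where(
            at_risk, spec.penetrance_high, spec.penetrance_low
        )
        if need_case > 0:
            take = g[affected][:need_case]
            cases.append(take)
            need_case -= len(take)
        if need_ctrl > 0:
            take = g[~affected][:need_ctrl]
            ctrls.append(take)
            need_ctrl -= len(take)
    if need_case > 0 or need_ctrl > 0:
        raise SimulationError(
            "could not collect the requested cases/controls; penetrances or "
            "allele frequencies make a group too rare"
        )
    g_case = _apply_missing(rng, np.vstack(cases), spec.missing_rate)
    g_ctrl = _apply_missing(rng, np.vstack(ctrls), spec.missing_rate)
    snps = _snp_ids(spec.n_snps)
    return CohortPair(
        GenotypeMatrix(_subject_ids("case", spec.n_case), snps, g_case),
        GenotypeMatrix(_subject_ids("ctrl", spec.n_control), snps, g_ctrl),
    )


def delta_for_odds_ratio(maf: float, odds_ratio: float) -> float:
    """Convenience: case-group MAF shift equivalent to a per-allele odds
    ratio under a logistic model with a rare-ish disease baseline.

    Solves ``odds_case(q') / odds_ctrl(q) = odds_ratio`` on allele odds:
    ``q'/(1-q') = OR * q/(1-q)``, returning ``q' - q``.
    """
    if not 0.0 < maf < 1.0:
        raise ValueError("maf must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    odds = odds_ratio * maf / (1.0 - maf)
    return odds / (1.0 + odds) - maf


def write_truth_file(spec: SimulationSpec, path: str | Path) -> None:
    """TSV of snp_id, is_causal, parameter for scoring recovery."""
    snps = _snp_ids(spec.n_snps)
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("snp_id\tis_causal\tparameter\n")
        for j, snp in enumerate(snps):
            if j in spec.causal_snps:
                fh.write(f"{snp}\t1\t{spec.causal_snps[j]!r}\n")
            else:
                fh.write(f"{snp}\t0\t0\n")
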