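"""Per-group genotype frequencies and the per-subject model score.

A model is a set of SNPs with nonnegative integer weights.  The score of
subject *i* is the log-ratio of the probability of the subject's
multi-SNP genotype under the two phenotype states,

    S_i = sum_j w_j * [ln P1(g_ij) - ln P2(g_ij)],

treating SNPs as conditionally independent given the state (naive-Bayes
factorization), so the Bayes-factor-style log-ratio is a weighted sum of
per-SNP log frequency ratios.  Genotype-class probabilities are estimated
per group with an additive pseudocount ``alpha`` (default 0.5) so every
log-ratio is finite; a missing genotype contributes 0 (a likelihood ratio
of 1: no evidence either way).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotypes import MISSING, CohortPair, GenotypeMatrix

DEFAULT_ALPHA = 0.5


class ZeroProbabilityError(ValueError):
    """A zero genotype probability was hit while scoring (alpha = 0 tables)."""


@dataclass
class SnpModel:
    """Ordered SNP IDs with parallel nonnegative integer weights."""

    snp_ids: list[str]
    weights: list[int]
    bits_per_weight: int = 1

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.weights = [int(w) for w in self.weights]
        if len(self.snp_ids) != len(self.weights):
            raise ValueError("snp_ids and weights must be parallel")
        if self.bits_per_weight < 1:
            raise ValueError("bits_per_weight must be >= 1")
        cap = 2**self.bits_per_weight
        if any(w < 0 or w >= cap for w in self.weights):
            raise ValueError(f"weights must lie in [0, {cap})")

    @property
    def active_snp_ids(self) -> list[str]:
        return [s for s, w in zip(self.snp_ids, self.weights) if w > 0]

    @property
    def n_active(self) -> int:
        return sum(1 for w in self.weights if w > 0)

    @property
    def is_active(self) -> bool:
        return self.n_active > 0

    def weight_of(self, snp_id: str) -> int:
        return self.weights[self.snp_ids.index(snp_id)]


def write_model(model: SnpModel, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a model file: optional ``#`` metadata lines, then snp_id/weight TSV."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("snp_id\tweight\n")
        for snp, w in zip(model.snp_ids, model.weights):
            fh.write(f"{snp}\t{w}\n")


def read_model(path: str | Path, bits_per_weight: int | None = None) -> SnpModel:
    snp_ids, weights = [], []
    with Path(path).open("r", encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#") or ln.startswith("snp_id\t"):
                continue
            snp, w = ln.split("\t")
            snp_ids.append(snp)
            weights.append(int(w))
    if bits_per_weight is None:
        bits_per_weight = max(1, int(max(weights, default=0)).bit_length())
    return SnpModel(snp_ids, weights, bits_per_weight)


@dataclass
class GenotypeFrequencyTable:
    """Per-SNP smoothed probabilities of the three genotype classes.

    ``probs[j]`` is ``(P(g=0), P(g=1), P(g=2))`` for SNP ``snp_ids[j]``.
    ``has_zero`` flags tables built with ``pseudocount == 0`` that contain
    an exact zero; scoring against such a table raises when the zero is
    actually looked up.
    """

    snp_ids: list[str]
    probs: np.ndarray
    pseudocount: float
    n_subjects: int
    has_zero: bool = field(init=False)

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.snp_ids), 3):
            raise ValueError("probs must be (n_snps, 3)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each probability triple must sum to 1")
        self.has_zero = bool((self.probs == 0).any())

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeFrequencyTable":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise KeyError(f"SNPs absent from frequency table: {missing}")
        rows = [index[s] for s in snp_ids]
        return GenotypeFrequencyTable(
            list(snp_ids), self.probs[rows], self.pseudocount, self.n_subjects
        )


@dataclass
class ScoreVector:
    """Per-subject scores (natural-log units) for one group."""

    subject_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = list(self.subject_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.subject_ids),):
            raise ValueError("scores must be parallel to subject_ids")


def genotype_class_counts(matrix: GenotypeMatrix) -> np.ndarray:
    """(n_snps, 3) counts of non-missing genotype classes per SNP."""
    v = matrix.values
    return np.stack([(v == g).sum(axis=0) for g in (0, 1, 2)], axis=1).astype(float)


def estimate_genotype_frequencies(
    matrix: GenotypeMatrix, alpha: float = DEFAULT_ALPHA
) -> GenotypeFrequencyTable:
    """Smoothed per-SNP genotype-class probabilities.

    ``P(g) = (count_g + alpha) / (n_nonmissing + 3 alpha)``.  With
    ``alpha = 0`` this is the MLE; a SNP with no non-missing subjects and
    ``alpha > 0`` degrades gracefully to the uniform (1/3, 1/3, 1/3).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    counts = genotype_class_counts(matrix)
    denom = counts.sum(axis=1, keepdims=True) + 3 * alpha
    with np.errstate(invalid="ignore"):
        probs = (counts + alpha) / denom
    # alpha == 0 and a SNP entirely missing: keep a valid (uniform) row
    probs[~np.isfinite(probs).all(axis=1)] = 1.0 / 3.0
    return GenotypeFrequencyTable(matrix.snp_ids, probs, alpha, matrix.n_subjects)


def log_ratio_table(
    freq_state1: GenotypeFrequencyTable, freq_state2: GenotypeFrequencyTable
) -> np.ndarray:
    """(n_snps, 3) per-genotype ``ln P1 - ln P2``, with -inf/inf where a
    probability is exactly zero (unsmoothed tables)."""
    if freq_state1.snp_ids != freq_state2.snp_ids:
        raise ValueError("frequency tables must cover the same SNPs in the same order")
    with np.errstate(divide="ignore"):
        return np.log(freq_state1.probs) - np.log(freq_state2.probs)


def _contributions(
    values: np.ndarray, log_ratios: np.ndarray, snp_ids: Sequence[str]
) -> np.ndarray:
    """(n_subjects, n_snps) per-SNP score contributions; MISSING -> 0."""
    filled = np.where(values == MISSING, 0, values)
    contrib = log_ratios[np.arange(values.shape[1])[None, :], filled]
    contrib = np.where(values == MISSING, 0.0, contrib)
    if not np.isfinite(contrib).all():
        bad = [snp_ids[j] for j in sorted(set(np.where(~np.isfinite(contrib))[1]))]
        raise ZeroProbabilityError(
            f"zero probability looked up for SNPs {bad}; use alpha > 0"
        )
    return contrib


def score_subject(
    genotypes: np.ndarray | Sequence[int],
    model: SnpModel,
    freq_state1: GenotypeFrequencyTable,
    freq_state2: GenotypeFrequencyTable,
) -> float:
    """Score one subject's genotype row (ordered as ``model.snp_ids``)."""
    if not model.is_active:
        raise ValueError("model has no active SNPs")
    f1 = freq_state1.subset(model.snp_ids)
    f2 = freq_state2.subset(model.snp_ids)
    row = np.asarray(genotypes, dtype=np.int8).reshape(1, -1)
    if row.shape[1] != len(model.snp_ids):
        raise ValueError("genotype row length must match model SNPs")
    contrib = _contributions(row, log_ratio_table(f1, f2), model.snp_ids)
    return float((contrib @ np.asarray(model.weights, dtype=float))[0])


def score_cohorts(
    pair: CohortPair,
    model: SnpModel,
    alpha: float = DEFAULT_ALPHA,
    frozen_tables: tuple[GenotypeFrequencyTable, GenotypeFrequencyTable] | None = None,
) -> tuple[ScoreVector, ScoreVector]:
    """Score every subject of both groups under ``model``.

    By default the genotype frequencies defining the score are estimated
    from ``pair.group1`` (state 1) and ``pair.group2`` (state 2).  In
    transfer/replication mode pass ``frozen_tables`` estimated on the
    discovery cohorts: the supplied tables are used unchanged.
    """
    if not model.is_active:
        raise ValueError("model has no active SNPs")
    sub1 = pair.group1.subset_snps(model.snp_ids)
    sub2 = pair.group2.subset_snps(model.snp_ids)
    if frozen_tables is None:
        f1 = estimate_genotype_frequencies(sub1, alpha)
        f2 = estimate_genotype_frequencies(sub2, alpha)
    else:
        f1 = frozen_tables[0].subset(model.snp_ids)
        f2 = frozen_tables[1].subset(model.snp_ids)
    lr = log_ratio_table(f1, f2)
    w = np.asarray(model.weights, dtype=float)
    s1 = _contributions(sub1.values, lr, model.snp_ids) @ w
    s2 = _contributions(sub2.values, lr, model.snp_ids) @ w
    return ScoreVector(sub1.subject_ids, s1), ScoreVector(sub2.subject_ids, s2)


def write_scores(
    group_scores: Sequence[tuple[str, ScoreVector]], path: str | Path
) -> None:
    """Write score TSV: subject_id, group, score."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("subject_id\tgroup\tscore\n")
        for group, vec in group_scores:
            for sid, s in zip(vec.subject_ids, vec.scores):
                fh.write(f"{sid}\t{group}\t{float(s)!r}\n")


def read_scores(path: str | Path) -> list[tuple[str, ScoreVector]]:
    groups: dict[str, tuple[list[str], list[float]]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["subject_id", "group", "score"]:
            raise ValueError(f"{path}: unexpected score file header {header}")
        for ln in fh:
            if not ln.strip():
                continue
            sid, group, score = ln.rstrip("\n").split("\t")
            groups.setdefault(group, ([], []))
            groups[group][0].append(sid)
            groups[group][1].append(float(score))
    return [(g, ScoreVector(ids, np.asarray(vals))) for g, (ids, vals) in groups.items()]
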