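"""End-to-end study orchestration.

A study: train the GA on case vs a designated training control group,
freeze the successful model, test it on the remaining comparisons
(case vs the second control, and control vs control when a second
control group is supplied), permutation-test each comparison, classify
the association (strong / moderate / none), and optionally fit the risk
models.  Every artifact is written with the seed and the echoed
configuration so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .association import classify_comparison, classify_model, permutation_test
from .fitness import bonferroni_threshold, model_fitness
from .ga import GaConfig, run_ga
from .genotypes import CohortPair, read_genotype_table
from .risk import fit_logistic, risk_bin_diagram
from .scoring import (
    estimate_genotype_frequencies,
    score_cohorts,
    write_model,
    write_scores,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat key-value run configuration (YAML mapping on disk).

    ``threshold_factors`` are the multiplicity sources fed to the
    Bonferroni correction for the *fitness* threshold (e.g. chromosomes,
    generations, hypotheses, comparisons); ``permutation_factors``
    likewise for the randomization-test threshold.  Both are explicit
    study-design choices, never inferred.
    """

    case_file: str = ""
    control_file: str = ""
    control2_file: str | None = None
    snp_set_file: str | None = None
    dialect: str = "numeric"
    alpha_pseudocount: float = 0.5
    significance_alpha: float = 0.05
    threshold_factors: list[int] = field(default_factory=list)
    permutation_factors: list[int] = field(default_factory=list)
    permutation_rounds: int = 10_000
    borderline_ceiling: float = 0.05
    fit_risk: bool = True
    risk_bins: int = 12
    output_dir: str = "kbas_out"
    seed: int = 0
    # GA block
    population_size: int = 200
    max_generations: int = 500
    bits_per_weight: int = 1
    init_active_snps: int = 10
    crossover_rate: float = 1.0
    mutation_rate_per_bit: float | None = None
    desired_fitness: float | None = None
    equal_var: bool = False

    def ga_config(self) -> GaConfig:
        return GaConfig(
            population_size=self.population_size,
            max_generations=self.max_generations,
            bits_per_weight=self.bits_per_weight,
            init_active_snps=self.init_active_snps,
            crossover_rate=self.crossover_rate,
            mutation_rate_per_bit=self.mutation_rate_per_bit,
            desired_fitness=self.desired_fitness,
            rng_seed=self.seed,
            equal_var=self.equal_var,
        )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> list[str]:
        """Collect every validation problem at once (fail-fast contract)."""
        problems = []
        for name, p, required in (
            ("case_file", self.case_file, True),
            ("control_file", self.control_file, True),
            ("control2_file", self.control2_file, False),
            ("snp_set_file", self.snp_set_file, False),
        ):
            if required and not p:
                problems.append(f"{name} is required")
            elif p and not Path(p).exists():
                problems.append(f"{name}: file not found: {p}")
        if self.permutation_rounds < 1:
            problems.append("permutation_rounds must be >= 1")
        try:
            self.ga_config()
        except ValueError as exc:
            problems.append(f"GA config: {exc}")
        return problems


def read_snp_set(path: str | Path) -> list[str]:
    """One SNP ID per line; '#' comments and blanks ignored."""
    out = []
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            out.append(ln.split("\t")[0])
    return out


def _permute(pair: CohortPair, model, cfg: RunConfig, seed: int, frozen=None):
    s1, s2 = score_cohorts(
        pair, model, alpha=cfg.alpha_pseudocount, frozen_tables=frozen
    )
    scores = np.concatenate([s1.scores, s2.scores])
    labels = np.concatenate([np.ones(len(s1.scores), int), np.zeros(len(s2.scores), int)])
    return permutation_test(
        scores, labels, cfg.permutation_rounds, seed=seed, equal_var=cfg.equal_var
    )


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the study report (also written
    as JSON to the output directory along with the model and score files).

    Exit conditions: raises ``ValueError`` listing all validation
    problems before any computation; scientific verdicts never raise.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    case = read_genotype_table(config.case_file, config.dialect)
    ctrl1 = read_genotype_table(config.control_file, config.dialect)
    ctrl2 = (
        read_genotype_table(config.control2_file, config.dialect)
        if config.control2_file
        else None
    )
    snp_set = (
        read_snp_set(config.snp_set_file) if config.snp_set_file else case.snp_ids
    )
    missing = [s for s in snp_set if s not in set(case.snp_ids)]
    if missing:
        raise ValueError(f"SNP set entries absent from genotype data: {missing[:10]}")

    train_pair = CohortPair(case, ctrl1, ("case", "control1"))
    fitness_threshold = bonferroni_threshold(
        config.significance_alpha, config.threshold_factors
    )
    perm_threshold = bonferroni_threshold(
        config.significance_alpha, config.permutation_factors
    )

    log_lines: list[str] = []
    result = run_ga(
        train_pair,
        snp_set,
        config.ga_config(),
        alpha=config.alpha_pseudocount,
        log_callback=log_lines.append,
    )
    (out / "ga_trace.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    model = result.best_model
    write_model(
        model,
        out / "successful_model.tsv",
        header_lines=[
            f"seed: {config.seed}",
            f"stopping: {result.stop_reason} after {result.generations_run} generations",
            f"fitness_p: {result.best_fitness.p_value:.6g}",
            f"fitness_log10_p: {result.best_fitness.log_p / math.log(10):.4f}",
        ],
    )

    comparisons: dict[str, dict] = {}
    # the score function is frozen from the training pair: transfer
    # comparisons test the *same model* (same frequencies), which keeps
    # the control-vs-control check free of refitting bias
    model_snps = model.snp_ids
    frozen = (
        estimate_genotype_frequencies(
            case.subset_snps(model_snps), config.alpha_pseudocount
        ),
        estimate_genotype_frequencies(
            ctrl1.subset_snps(model_snps), config.alpha_pseudocount
        ),
    )

    def add_comparison(
        name: str, pair: CohortPair, seed_offset: int, freeze: bool
    ) -> None:
        tables = frozen if freeze else None
        fit = model_fitness(pair, model, alpha=config.alpha_pseudocount,
                            frozen_tables=tables, equal_var=config.equal_var)
        perm = _permute(pair, model, config, seed=config.seed + seed_offset,
                        frozen=tables)
        s1, s2 = score_cohorts(
            pair, model, alpha=config.alpha_pseudocount, frozen_tables=tables
        )
        write_scores(
            [(pair.labels[0], s1), (pair.labels[1], s2)],
            out / f"scores_{name}.tsv",
        )
        comparisons[name] = {
            "fitness_t": fit.t_statistic,
            "fitness_p": fit.p_value,
            "fitness_log10_p": fit.log_p / math.log(10),
            "permutation_empirical_p": perm.empirical_p,
            "permutation_report": perm.upper_bound_string,
            "permutation_rounds": perm.n_rounds,
        }

    add_comparison("case_vs_control1", train_pair, 1, freeze=False)
    if ctrl2 is not None:
        add_comparison(
            "case_vs_control2", CohortPair(case, ctrl2, ("case", "control2")), 2,
            freeze=True,
        )
        add_comparison(
            "control1_vs_control2",
            CohortPair(ctrl1, ctrl2, ("control1", "control2")), 3,
            freeze=True,
        )

    report: dict = {
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if v is not None
        },
        "snp_set_size": len(snp_set),
        "model": {
            "snp_ids": model.active_snp_ids,
            "weights": [model.weight_of(s) for s in model.active_snp_ids],
            "n_active": model.n_active,
        },
        "ga": {
            "generations_run": result.generations_run,
            "stop_reason": result.stop_reason,
            "n_evaluations": result.n_evaluations,
            "best_fitness_p": result.best_fitness.p_value,
            "best_fitness_log10_p": result.best_fitness.log_p / math.log(10),
        },
        "thresholds": {
            "fitness_significance": fitness_threshold,
            "permutation_significance": perm_threshold,
            "borderline_ceiling": config.borderline_ceiling,
        },
        "comparisons": comparisons,
    }

    if ctrl2 is not None:
        s1 = classify_comparison(
            comparisons["case_vs_control1"]["permutation_empirical_p"],
            perm_threshold,
            config.borderline_ceiling,
        )
        s2 = classify_comparison(
            comparisons["case_vs_control2"]["permutation_empirical_p"],
            perm_threshold,
            config.borderline_ceiling,
        )
        # the two controls must not separate: their *fitness* p is held to
        # the study-wide fitness threshold (no randomization test here)
        verdict = classify_model(
            s1,
            s2,
            comparisons["control1_vs_control2"]["fitness_p"],
            fitness_threshold,
            config.borderline_ceiling,
        )
        report["verdict"] = {
            "association": verdict.verdict,
            "statuses": list(verdict.statuses),
            "control_separation_invalid": verdict.invalid,
        }

    if config.fit_risk:
        s1, s2 = score_cohorts(train_pair, model, alpha=config.alpha_pseudocount)
        y = np.concatenate([np.ones(len(s1.scores)), np.zeros(len(s2.scores))])
        x = np.concatenate([s1.scores, s2.scores])
        fit = fit_logistic(x[:, None], y, ["score"])
        table = risk_bin_diagram(s1.scores, s2.scores, n_bins=config.risk_bins)
        table.to_frame().to_csv(out / "risk_bins.tsv", sep="\t", index=False)
        report["risk"] = {
            "logistic": {
                "terms": fit.terms,
                "coefficients": fit.coefficients.tolist(),
                "standard_errors": fit.standard_errors.tolist(),
                "odds_ratios": fit.odds_ratios.tolist(),
                "converged": fit.converged,
            },
            "prior": table.prior,
            "posterior_risk": [
                None if not np.isfinite(v) else float(v) for v in table.posterior_risk
            ],
        }

    report["runtime_seconds"] = round(time.time() - t0, 2)
    (out / "report.json").write_text(
        json.dumps(report, indent=2) + "\n", encoding="utf-8"
    )
    return report
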