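"""End-to-end analysis workflows: simulator/PSA -> VOI ranking -> reports.

An :class:`AnalysisConfig` points at either a PSA CSV (in the documented
schema) or a simulator YAML config, never both.  Workflows write a
full-precision CSV plus a human-readable Markdown table whose rounding
follows convention for these reports: EVPPI to 2 d.p., metrics to 1 d.p.,
semielasticities to 4 d.p.  All randomness flows from the single config
seed, so two runs with equal config are identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import markov_case_study as mcs
from .owsa import SemielasticityTable, fit_semielasticity_metamodel
from .psa_core import PSADomainError, PSAResult, compute_inb, read_psa_csv
from .ranking import Candidate, RankingTable, conditional_evppi_ranking
from .voi import evpi

__all__ = ["AnalysisConfig", "load_psa", "default_candidates",
           "run_update_workflow", "run_adapt_workflow",
           "render_ranking_report", "render_semielasticity_report"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    psa_path: str | None = None
    simulator_config_path: str | None = None
    k: float = 13_000.0
    incident_population: float = 1.0
    comparator: str = "A"
    intervention: str = "B"
    candidates: list | None = None
    tol: float | str = "auto"
    seed: int = 0
    n_draws: int = 10_000
    group_correlated: bool = True
    out_csv: str | None = None
    out_report: str | None = None

    def __post_init__(self):
        if bool(self.psa_path) == bool(self.simulator_config_path):
            raise PSADomainError(
                "exactly one of psa_path / simulator_config_path must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise PSADomainError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**doc)


def load_psa(config: AnalysisConfig) -> PSAResult:
    """Load the PSA from file, or simulate it from the model config."""
    if config.psa_path:
        return read_psa_csv(config.psa_path, k=config.k,
                            incident_population=config.incident_population,
                            comparator=config.comparator,
                            intervention=config.intervention)
    model = mcs.config_from_yaml(config.simulator_config_path)
    specs = mcs.default_parameter_specs(model)
    logger.info("simulating %d PSA draws (seed=%s)", config.n_draws, config.seed)
    return mcs.sample_psa(model, specs, n_draws=config.n_draws, seed=config.seed)


def default_candidates(psa: PSAResult, group_correlated: bool = True) -> list:
    """One candidate per column, with the correlated AE-probability columns
    offered as a single pre-grouped candidate (individually on request)."""
    ae = [n for n in psa.param_names if n.startswith("prob_ae_")]
    if not group_correlated or len(ae) < 2:
        return list(psa.param_names)
    rest = [n for n in psa.param_names if n not in ae]
    return rest + [Candidate("short_term_ae_probabilities", tuple(ae))]


def _fmt_pct(x: float) -> str:
    return f"{x:.1f}%"


def render_ranking_report(table: RankingTable, seed) -> str:
    lines = [
        "# Update-priority ranking (conditional EVPPI)",
        "",
        f"EVPI: {table.evpi:.2f} population QALYs "
        f"({table.evpi_per_person:.3e} per person; population "
        f"{table.incident_population:g}; seed {seed})",
        f"Stopping tolerance: {table.tolerance:.3e} per-person QALYs"
        + ("; stopped early" if table.stopped_early else ""),
        "",
        "| Input | Rank | Cumulative EVPPI | Marginal EVPPI | Update Metric |",
        "|---|---|---|---|---|",
    ]
    for r in table.rows:
        lines.append(f"| {r.parameter} | {r.rank} | {r.cumulative_evppi:.2f} | "
                     f"{r.marginal_evppi:.2f} | {_fmt_pct(r.update_metric)} |")
    if table.excluded:
        lines += ["", f"Excluded (marginal EVPPI below tolerance): "
                      f"{', '.join(table.excluded)}"]
    return "\n".join(lines) + "\n"


def render_semielasticity_report(table: SemielasticityTable, seed) -> str:
    lines = [
        "# Adaptation-priority ranking (1% semielasticities)",
        "",
        f"Metamodel R-squared: {table.r_squared:.3f} (n = {table.n_draws}; seed {seed})",
        "",
        "| Input | Rank | Semielasticity | Normalized Proportion | Standard Error | Adaptation Metric |",
        "|---|---|---|---|---|---|",
    ]
    for r in table.rows:
        lines.append(
            f"| {r.parameter} | {r.rank} | {r.semielasticity:.4f} | "
            f"{r.normalized_proportion:.4f} | {r.standard_error:.4f} | "
            f"{_fmt_pct(r.adaptation_metric)} |")
    if table.excluded:
        lines += ["", f"Excluded from metamodel: {', '.join(table.excluded)}"]
    return "\n".join(lines) + "\n"


def _write_outputs(config: AnalysisConfig, df, report: str) -> None:
    if config.out_csv:
        df.to_csv(config.out_csv, index=False, float_format="%.17g")
        logger.info("wrote %s", config.out_csv)
    if config.out_report:
        Path(config.out_report).write_text(report)
        logger.info("wrote %s", config.out_report)


def run_update_workflow(config: AnalysisConfig) -> tuple[RankingTable, str]:
    """PSA -> INB -> EVPI -> greedy conditional-EVPPI ranking -> report."""
    psa = load_psa(config)
    inb = compute_inb(psa)
    evpi_est = evpi(inb, incident_population=psa.incident_population)
    logger.info("EVPI: %.6g per person (SE %.2g), %.4g population-scaled",
                evpi_est.per_person, evpi_est.standard_error,
                evpi_est.population_scaled)
    candidates = config.candidates or default_candidates(psa, config.group_correlated)
    table = conditional_evppi_ranking(psa, candidates, tol=config.tol,
                                      seed=config.seed)
    report = render_ranking_report(table, config.seed)
    _write_outputs(config, table.to_dataframe(), report)
    return table, report


def run_adapt_workflow(config: AnalysisConfig) -> tuple[SemielasticityTable, str]:
    """PSA -> INB -> percent-rescaled OLS metamodel -> report."""
    psa = load_psa(config)
    table = fit_semielasticity_metamodel(psa)
    report = render_semielasticity_report(table, config.seed)
    _write_outputs(config, table.to_dataframe(), report)
    return table, report
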