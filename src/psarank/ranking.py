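"""Greedy conditional-EVPPI ranking and the update metric.

The algorithm ranks candidate parameters (or pre-grouped parameter sets) by
forward selection on joint EVPPI:

1. compute EVPPI for every candidate independently; the largest is rank 1;
2. at each later step, compute the EVPPI of the already-ranked set joined
   with each remaining candidate; the candidate giving the largest joint
   EVPPI is appended;
3. stop when the best marginal gain falls to (within tolerance of) zero or
   candidates are exhausted.

The update metric for the set ranked so far is ``100 * cumulative EVPPI /
EVPI``.  Because regression EVPPI has an upward bias, the metric can exceed
100%; such values are flagged, never altered.

Every step re-uses the one fixed PSA sample — no re-simulation — matching
post-hoc use of a standard PSA.  Correlated parameter groups should be
offered as a single candidate (see :func:`Candidate`): the value of jointly
learning a correlated set differs from learning its members one at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .psa_core import INBVector, PSADomainError, PSAResult, compute_inb
from .voi import VOIEstimate, evpi, evppi

__all__ = ["Candidate", "RankingRow", "RankingTable",
           "conditional_evppi_ranking", "update_metric"]

logger = logging.getLogger(__name__)


def update_metric(cumulative_evppi: float, evpi_value: float) -> float:
    """Share (%) of total decision uncertainty covered by an updated set.

    Values above 100% are permitted — the EVPPI estimator is upward-biased —
    and are flagged at WARNING level rather than truncated.
    """
    if evpi_value <= 0:
        raise PSADomainError(
            "EVPI must be > 0 to apportion decision uncertainty: this model "
            "has no decision uncertainty to update against")
    metric = 100.0 * cumulative_evppi / evpi_value
    if metric > 100.0:
        logger.warning(
            "update metric %.1f%% exceeds 100%%: EVPPI is estimated with "
            "uncertainty and carries an upward bias", metric)
    return metric


@dataclass(frozen=True)
class Candidate:
    """A rankable unit: one parameter, or a named group learned jointly."""

    label: str
    params: tuple[str, ...]

    @classmethod
    def coerce(cls, item) -> "Candidate":
        if isinstance(item, Candidate):
            return item
        if isinstance(item, str):
            return cls(item, (item,))
        label, params = item
        return cls(str(label), tuple(params))


@dataclass(frozen=True)
class RankingRow:
    parameter: str
    rank: int
    cumulative_evppi: float  # population-scaled QALYs
    marginal_evppi: float
    update_metric: float  # percent
    params: tuple[str, ...] = ()


@dataclass(frozen=True)
class RankingTable:
    """Machine twin of a ranked update-priority table."""

    rows: tuple[RankingRow, ...]
    evpi: float  # population-scaled QALYs
    evpi_per_person: float
    stopped_early: bool
    tolerance: float  # per-person QALYs
    incident_population: float
    excluded: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"Input": r.parameter, "Rank": r.rank,
              "Cumulative EVPPI": r.cumulative_evppi,
              "Marginal EVPPI": r.marginal_evppi,
              "Update Metric": r.update_metric} for r in self.rows]
        )


def _resolve_tol(tol, evpi_est: VOIEstimate) -> float:
    # "marginal gains gone to zero" is unattainable under Monte-Carlo noise;
    # default to max(2 * SE(EVPI), 0.1% of EVPI) on the per-person scale.
    if tol == "auto" or tol is None:
        return max(2.0 * evpi_est.standard_error, 1e-3 * evpi_est.per_person)
    tol = float(tol)
    if tol < 0:
        raise PSADomainError(f"tolerance must be >= 0, got {tol}")
    return tol


def conditional_evppi_ranking(
    psa: PSAResult,
    candidates: Sequence | None = None,
    tol: float | str | None = "auto",
    *,
    seed: int | None = None,
    n_boot: int = 0,
    max_steps: int | None = None,
) -> RankingTable:
    """Rank candidates by greedy forward selection on joint EVPPI.

    ``candidates`` may mix parameter names and ``(label, [names])`` groups;
    by default every PSA column is an individual candidate.  Ties in the
    arg-max are broken by larger independent EVPPI, then lexicographic
    label, so the result never depends on candidate input order.
    """
    if candidates is None:
        candidates = list(psa.param_names)
    cands = [Candidate.coerce(c) for c in candidates]
    if not cands:
        raise PSADomainError("candidates must be non-empty")
    labels = [c.label for c in cands]
    if len(set(labels)) != len(labels):
        raise PSADomainError(f"duplicate candidate labels: {sorted(labels)}")
    for c in cands:
        for p in c.params:
            if p not in psa.param_names:
                raise KeyError(f"unknown parameter {p!r} in candidate {c.label!r}")

    inb = compute_inb(psa)
    pop = psa.incident_population
    evpi_est = evpi(inb, incident_population=pop)
    if evpi_est.per_person <= 0:
        # every draw favours the same strategy: nothing to apportion
        logger.warning("EVPI is 0 in this PSA: no decision uncertainty, "
                       "no parameters to rank for updating")
        return RankingTable(
            rows=(), evpi=0.0, evpi_per_person=0.0, stopped_early=False,
            tolerance=0.0, incident_population=pop,
            excluded=tuple(sorted(c.label for c in cands)),
            metadata={"independent_evppi_per_person": {},
                      "evpi_se_per_person": evpi_est.standard_error,
                      "final_set_se_per_person": float("nan"), "seed": seed,
                      "no_decision_uncertainty": True},
        )
    tol_pp = _resolve_tol(tol, evpi_est)

    def joint(params: tuple[str, ...]) -> float:
        est = evppi(psa, params, n_boot=0, seed=seed, allow_large=True, inb=inb)
        return est.per_person

    # step 1: independent EVPPI of every candidate
    indep = {c.label: joint(c.params) for c in cands}
    logger.info("independent EVPPI (per person): %s",
                {k: round(v, 6) for k, v in sorted(indep.items(), key=lambda kv: -kv[1])})

    remaining = sorted(cands, key=lambda c: c.label)
    ranked_params: tuple[str, ...] = ()
    rows: list[RankingRow] = []
    cumulative = 0.0
    stopped_early = False

    while remaining:
        if max_steps is not None and len(rows) >= max_steps:
            stopped_early = True
            break
        scored = []
        for c in remaining:
            value = indep[c.label] if not ranked_params else joint(ranked_params + c.params)
            scored.append((c, value))
        # arg-max with deterministic tie-breaking
        best, best_value = min(scored, key=lambda cv: (-cv[1], -indep[cv[0].label], cv[0].label))
        marginal = best_value - cumulative
        logger.info("step %d: best candidate %r, joint EVPPI %.6g, marginal %.6g "
                    "(tol %.3g, per person)", len(rows) + 1, best.label,
                    best_value, marginal, tol_pp)
        # rank 1 is assigned unconditionally (steps 1-2 of the algorithm);
        # the gone-to-zero stopping rule governs steps 3 onward
        if rows and marginal <= tol_pp:
            stopped_early = True
            break
        cumulative = best_value
        ranked_params = ranked_params + best.params
        rows.append(RankingRow(
            parameter=best.label,
            rank=len(rows) + 1,
            cumulative_evppi=cumulative * pop,
            marginal_evppi=marginal * pop,
            update_metric=update_metric(cumulative, evpi_est.per_person),
            params=best.params,
        ))
        remaining = [c for c in remaining if c.label != best.label]

    if n_boot > 0 and rows:  # SE of the final ranked set, on request
        final = evppi(psa, ranked_params, n_boot=n_boot, seed=seed,
                      allow_large=True, inb=inb)
        final_se = final.standard_error
    else:
        final_se = float("nan")

    return RankingTable(
        rows=tuple(rows),
        evpi=evpi_est.population_scaled,
        evpi_per_person=evpi_est.per_person,
        stopped_early=stopped_early,
        tolerance=tol_pp,
        incident_population=pop,
        excluded=tuple(c.label for c in remaining),
        metadata={"independent_evppi_per_person": indep,
                  "evpi_se_per_person": evpi_est.standard_error,
                  "final_set_se_per_person": final_se,
                  "seed": seed},
    )
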