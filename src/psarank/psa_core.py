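"""Core data model for probabilistic sensitivity analysis (PSA) output.

A PSA jointly samples every uncertain model input and records, per draw,
the discounted costs and QALYs of each strategy.  Everything downstream
(EVPI/EVPPI, greedy ranking, semielasticity metamodels) consumes the
:class:`PSAResult` defined here, together with the incremental net benefit
(INB) arithmetic::

    INB_i = (QALY_B_i - QALY_A_i) - (Cost_B_i - Cost_A_i) / k

with ``A`` the comparator, ``B`` the intervention and ``k`` the
cost-effectiveness threshold (GBP per QALY).  INB is measured in QALY
(health) units throughout; net monetary benefit is ``INB * k`` and is only
ever a presentation transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrategyOutcomes",
    "PSAResult",
    "INBVector",
    "compute_inb",
    "probability_cost_effective",
    "read_psa_csv",
    "write_psa_csv",
]


class PSAStructureError(ValueError):
    """Raised when PSA inputs are structurally inconsistent (shape/labels)."""


class PSADomainError(ValueError):
    """Raised when a PSA quantity is outside its valid domain (e.g. k <= 0)."""


def _as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise PSAStructureError(f"{name} must be 1-dimensional, got shape {arr.shape}")
    if arr.size < 1:
        raise PSAStructureError(f"{name} must contain at least one draw")
    if not np.all(np.isfinite(arr)):
        raise PSAStructureError(
            f"{name} contains missing or non-finite values; PSA rows are jointly "
            "sampled and cannot be partially dropped or imputed"
        )
    return arr


@dataclass(frozen=True)
class StrategyOutcomes:
    """Per-draw discounted outcomes for one strategy."""

    strategy_label: str
    qalys: np.ndarray
    costs: np.ndarray

    def __post_init__(self):
        q = _as_1d_float(self.qalys, f"{self.strategy_label}.qalys")
        c = _as_1d_float(self.costs, f"{self.strategy_label}.costs")
        if q.shape != c.shape:
            raise PSAStructureError(
                f"{self.strategy_label}: qalys ({q.size}) and costs ({c.size}) "
                "must have identical length"
            )
        object.__setattr__(self, "qalys", q)
        object.__setattr__(self, "costs", c)

    @property
    def n_draws(self) -> int:
        return self.qalys.size


@dataclass(frozen=True)
class PSAResult:
    """Matrix of parameter draws aligned with per-draw strategy outcomes.

    Exactly two strategies are supported: ``outcomes[0]`` is the comparator
    and ``outcomes[1]`` the intervention.  More than two arms is rejected.
    """

    draws: np.ndarray
    param_names: tuple[str, ...]
    outcomes: tuple[StrategyOutcomes, StrategyOutcomes]
    k: float
    incident_population: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        draws = np.asarray(self.draws, dtype=float)
        if draws.ndim != 2:
            raise PSAStructureError(f"draws must be 2-D, got shape {draws.shape}")
        if not np.all(np.isfinite(draws)):
            raise PSAStructureError("draws contain missing or non-finite values")
        names = tuple(str(n) for n in self.param_names)
        if len(names) != draws.shape[1]:
            raise PSAStructureError(
                f"{len(names)} param_names for {draws.shape[1]} draw columns"
            )
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PSAStructureError(f"duplicate parameter names: {dupes}")
        if len(self.outcomes) != 2:
            raise PSAStructureError(
                f"exactly 2 strategies (comparator, intervention) are supported, "
                f"got {len(self.outcomes)}"
            )
        for o in self.outcomes:
            if o.n_draws != draws.shape[0]:
                raise PSAStructureError(
                    f"strategy {o.strategy_label!r} has {o.n_draws} draws but "
                    f"parameter matrix has {draws.shape[0]} rows"
                )
        if not (self.k > 0):
            raise PSADomainError(f"threshold k must be > 0, got {self.k}")
        if self.incident_population < 0:
            raise PSADomainError(
                f"incident_population must be >= 0, got {self.incident_population}"
            )
        object.__setattr__(self, "draws", draws)
        object.__setattr__(self, "param_names", names)
        object.__setattr__(self, "outcomes", tuple(self.outcomes))

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    @property
    def n_params(self) -> int:
        return self.draws.shape[1]

    @property
    def comparator(self) -> StrategyOutcomes:
        return self.outcomes[0]

    @property
    def intervention(self) -> StrategyOutcomes:
        return self.outcomes[1]

    def column(self, name: str) -> np.ndarray:
        """Draws for a single named parameter."""
        try:
            idx = self.param_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown parameter {name!r}; known: {list(self.param_names)}"
            ) from None
        return self.draws[:, idx]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        """Draw matrix restricted to ``names`` (order preserved)."""
        idx = []
        for n in names:
            if n not in self.param_names:
                raise KeyError(
                    f"unknown parameter {n!r}; known: {list(self.param_names)}"
                )
            idx.append(self.param_names.index(n))
        return self.draws[:, idx]


@dataclass(frozen=True)
class INBVector:
    """Per-draw incremental net benefit in QALY units (intervention minus comparator)."""

    values: np.ndarray
    k: float
    orientation: str = "intervention_minus_comparator"

    def __post_init__(self):
        object.__setattr__(self, "values", _as_1d_float(self.values, "INB"))

    @property
    def n_draws(self) -> int:
        return self.values.size

    def mean(self) -> float:
        return float(np.mean(self.values))

    def net_monetary(self) -> np.ndarray:
        """Presentation transform only: INB expressed in GBP (INB * k)."""
        return self.values * self.k


def compute_inb(psa: PSAResult) -> INBVector:
    """Per-draw incremental net benefit, ``dQALYs - dCosts / k``, in QALYs.

    Orientation is fixed: intervention (``outcomes[1]``) minus comparator
    (``outcomes[0]``); it is recorded in the output so downstream reports
    cannot silently flip sign.
    """
    comp, interv = psa.outcomes
    d_qalys = interv.qalys - comp.qalys
    d_costs = interv.costs - comp.costs
    return INBVector(values=d_qalys - d_costs / psa.k, k=psa.k)


def probability_cost_effective(inb: INBVector | np.ndarray) -> float:
    """Fraction of draws with strictly positive INB.

    Draws at exactly zero count as *not* cost-effective: a deterministic tie
    rule for what is a zero-measure event under any continuous PSA.
    """
    values = inb.values if isinstance(inb, INBVector) else np.asarray(inb, dtype=float)
    if values.size == 0:
        raise PSADomainError("cannot compute probability cost-effective of an empty vector")
    return float(np.mean(values > 0))


# ---------------------------------------------------------------------------
# CSV schema: header `draw`, one column per parameter, then
# `cost_A,qaly_A,cost_B,qaly_B`.  A = comparator, B = intervention.
# ---------------------------------------------------------------------------

_OUTCOME_COLS = ("cost_A", "qaly_A", "cost_B", "qaly_B")


def write_psa_csv(psa: PSAResult, path: str | Path) -> None:
    """Write a PSAResult in the documented CSV schema (full float precision)."""
    df = pd.DataFrame(psa.draws, columns=list(psa.param_names))
    df.insert(0, "draw", np.arange(psa.n_draws))
    df["cost_A"] = psa.comparator.costs
    df["qaly_A"] = psa.comparator.qalys
    df["cost_B"] = psa.intervention.costs
    df["qaly_B"] = psa.intervention.qalys
    df.to_csv(path, index=False, float_format="%.17g")


def read_psa_csv(
    path: str | Path,
    k: float,
    incident_population: float = 1.0,
    comparator: str = "A",
    intervention: str = "B",
) -> PSAResult:
    """Read a PSA CSV written in the documented schema.

    Raises a structural error naming the offending column when the schema is
    violated or values are missing.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("draw", *_OUTCOME_COLS) if c not in df.columns]
    if missing:
        raise PSAStructureError(f"PSA CSV {path} lacks required columns {missing}")
    bad = df.columns[df.isna().any()].tolist()
    if bad:
        raise PSAStructureError(
            f"PSA CSV {path} has missing values in columns {bad}; "
            "PSA rows cannot be partially dropped"
        )
    param_cols = [c for c in df.columns if c not in ("draw", *_OUTCOME_COLS)]
    outcomes = (
        StrategyOutcomes(comparator, df["qaly_A"].to_numpy(), df["cost_A"].to_numpy()),
        StrategyOutcomes(intervention, df["qaly_B"].to_numpy(), df["cost_B"].to_numpy()),
    )
    return PSAResult(
        draws=df[param_cols].to_numpy(dtype=float),
        param_names=tuple(param_cols),
        outcomes=outcomes,
        k=k,
        incident_population=incident_population,
        metadata={"source": str(path)},
    )
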