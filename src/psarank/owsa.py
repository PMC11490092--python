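"""Percent-rescaled OLS semielasticities, ranking, and the adaptation metric.

For an approximately linear model the one-at-a-time impact of a 1% change
in each input on INB can be read off a single OLS fit to the PSA output:
each input column is rescaled to percentage differences from its sample
mean, ``z = 100 * (x - mean) / mean``, and INB is regressed on all rescaled
inputs; the coefficients are the 1% semielasticities.  Parameters are
ranked by absolute semielasticity; normalizing the absolute values to sum
to one gives each parameter's share of total one-way-sensitivity
variation, and the cumulative share over the top-ranked parameters is the
adaptation metric.

Only parameters with sampling variation can enter the regression, so
deterministic inputs are excluded (their columns have zero variance), as
are parameters whose sample mean is numerically zero (percent-of-mean
rescaling is undefined there).  A direct one-at-a-time perturbation
(:func:`manual_owsa`) is provided as an independent cross-check: on an
exactly linear model it reproduces the regression coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla

from .psa_core import PSADomainError, PSAResult, compute_inb

__all__ = ["SemielasticityRow", "SemielasticityTable",
           "fit_semielasticity_metamodel", "manual_owsa", "adaptation_metric"]

#: parameters with |mean| below this multiple of their sd are excluded
ZERO_MEAN_EPS = 1e-6


class CollinearityError(np.linalg.LinAlgError):
    """Raised when the rescaled design matrix is rank deficient."""


@dataclass(frozen=True)
class SemielasticityRow:
    parameter: str
    rank: int
    semielasticity: float  # change in INB (QALYs) per +1% in the parameter
    standard_error: float
    normalized_proportion: float
    adaptation_metric: float  # cumulative percent


@dataclass(frozen=True)
class SemielasticityTable:
    """Machine twin of a ranked adaptation-priority table."""

    rows: tuple[SemielasticityRow, ...]
    r_squared: float
    n_draws: int
    excluded: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    @property
    def proportions(self) -> np.ndarray:
        return np.array([r.normalized_proportion for r in self.rows])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"Input": r.parameter, "Rank": r.rank,
              "Semielasticity": r.semielasticity,
              "Normalized Proportion": r.normalized_proportion,
              "Standard Error": r.standard_error,
              "Adaptation Metric": r.adaptation_metric} for r in self.rows]
        )


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    # rank-revealing QR; pivots beyond the numerical rank name the culprits
    _, r, piv = sla.qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < design.shape[1]:
        labeled = ["<intercept>"] + names
        bad = sorted(labeled[j] for j in piv[rank:])
        raise CollinearityError(
            f"rescaled design matrix is rank deficient; collinear columns: {bad}")


def fit_semielasticity_metamodel(
    psa: PSAResult,
    params: Sequence[str] | None = None,
    *,
    linearity_threshold: float = 0.8,
) -> SemielasticityTable:
    """Fit the percent-rescaled linear metamodel and rank all inputs.

    A warning is emitted when the metamodel R-squared falls below
    ``linearity_threshold``: semielasticities from a poorly fitting linear
    surface are unreliable.
    """
    names = list(params) if params is not None else list(psa.param_names)
    if not names:
        raise PSADomainError("no parameters to fit")
    X = psa.columns(names)
    y = compute_inb(psa).values
    if psa.n_draws <= len(names) + 1:
        raise PSADomainError(
            f"need more draws ({psa.n_draws}) than parameters + 1 ({len(names) + 1})")

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    excluded: list[str] = []
    keep: list[int] = []
    for j, name in enumerate(names):
        if sds[j] == 0:
            excluded.append(name)
            warnings.warn(f"parameter {name!r} is constant across draws "
                          "(deterministic); excluded from the metamodel",
                          stacklevel=2)
        elif abs(means[j]) < ZERO_MEAN_EPS * sds[j]:
            excluded.append(name)
            warnings.warn(f"parameter {name!r} has a sample mean of ~0; "
                          "percent-of-mean rescaling is undefined, excluded",
                          stacklevel=2)
        else:
            keep.append(j)

    kept_names = [names[j] for j in keep]
    if not kept_names or float(np.var(y)) == 0.0:
        if float(np.var(y)) == 0.0:
            warnings.warn("INB is constant across draws; all semielasticities "
                          "are zero and R-squared is undefined", stacklevel=2)
        return SemielasticityTable(rows=(), r_squared=float("nan"),
                                   n_draws=psa.n_draws, excluded=tuple(excluded),
                                   metadata={"degenerate": True})

    Z = 100.0 * (X[:, keep] - means[keep]) / means[keep]
    design = sm.add_constant(Z)
    _check_full_rank(design, kept_names)
    fit = sm.OLS(y, design).fit()
    coefs = fit.params[1:]
    ses = fit.bse[1:]

    order = sorted(range(len(kept_names)),
                   key=lambda j: (-abs(coefs[j]), kept_names[j]))
    abs_total = float(np.sum(np.abs(coefs)))
    rows = []
    cum = 0.0
    for rank, j in enumerate(order, start=1):
        prop = abs(coefs[j]) / abs_total
        cum += prop
        rows.append(SemielasticityRow(
            parameter=kept_names[j], rank=rank,
            semielasticity=float(coefs[j]), standard_error=float(ses[j]),
            normalized_proportion=float(prop),
            adaptation_metric=100.0 * cum,
        ))

    r2 = float(fit.rsquared)
    if r2 < linearity_threshold:
        warnings.warn(
            f"metamodel R-squared {r2:.3f} is below {linearity_threshold}: the "
            "model is materially nonlinear and 1% semielasticities may be "
            "unreliable", stacklevel=2)
    return SemielasticityTable(
        rows=tuple(rows), r_squared=r2, n_draws=psa.n_draws,
        excluded=tuple(excluded),
        metadata={"abs_semielasticity_total": abs_total,
                  "n_params_fit": len(kept_names)},
    )


def manual_owsa(model_runner: Callable[[object, Mapping], float], config,
                parameter: str, delta_pct: float = 1.0) -> float:
    """Direct one-at-a-time OWSA: change in INB from a ``delta_pct`` % bump.

    ``model_runner(config, overrides)`` must evaluate INB with every input
    at its expected value except those in ``overrides``.  Domain violations
    of the perturbed value (e.g. a probability above 1) are rejected.
    """
    values = getattr(config, "values", config)
    if parameter not in values:
        raise KeyError(f"unknown parameter {parameter!r}")
    base_value = values[parameter]
    new_value = base_value * (1.0 + delta_pct / 100.0)
    if parameter.startswith("prob_") and not 0.0 <= new_value <= 1.0:
        raise PSADomainError(
            f"perturbed {parameter}={new_value} leaves the probability domain [0, 1]")
    if parameter.startswith("utility_") and not -1.0 <= new_value <= 1.0:
        raise PSADomainError(
            f"perturbed {parameter}={new_value} leaves the utility domain [-1, 1]")
    base = model_runner(config, {})
    perturbed = model_runner(config, {parameter: new_value})
    return perturbed - base


def adaptation_metric(table: SemielasticityTable, top_r: int) -> float:
    """Cumulative share (%) of OWSA variation covered by the top ``top_r`` rows."""
    if not 0 <= top_r <= len(table.rows):
        raise PSADomainError(
            f"top_r must lie in [0, {len(table.rows)}], got {top_r}")
    return 100.0 * float(np.sum(table.proportions[:top_r]))
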