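"""Value-of-information estimation from PSA draws.

EVPI is the expected gain from resolving *all* parameter uncertainty before
choosing between the two strategies; with two arms and INB in QALYs it
reduces to::

    EVPI = mean(max(0, INB_i)) - max(0, mean(INB))

EVPPI for a parameter subset S is estimated by regression metamodelling:
a flexible smooth g(phi_S) of per-draw INB on the subset's draws is fitted,
and ``EVPPI(S) = mean(max(0, g_hat_i)) - max(0, mean(INB))``.  The smooth
is a penalized-spline basis — full tensor-product interaction for up to two
parameters, additive beyond that (basis dimension ``4 * ceil(n ** 0.2)``
per smooth, capped by the data).  The estimator carries a known upward
bias, so downstream "update metrics" can legitimately exceed 100%; raw
(unclipped) estimates are always retained in metadata.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.preprocessing import SplineTransformer

from .psa_core import INBVector, PSADomainError, PSAResult, compute_inb

__all__ = ["VOIEstimate", "evpi", "evppi"]

logger = logging.getLogger(__name__)

#: default subset-size cap; nonparametric regression is unreliable in high
#: dimensions, so larger subsets must be requested explicitly
MAX_SUBSET = 5


@dataclass(frozen=True)
class VOIEstimate:
    """A per-person and population-scaled EVPI or EVPPI value."""

    per_person: float
    population_scaled: float
    standard_error: float
    subset: tuple[str, ...]
    n_draws: int
    metadata: dict = field(default_factory=dict)

    @property
    def standard_error_population(self) -> float:
        pop = self.metadata.get("incident_population", 1.0)
        return self.standard_error * pop


def evpi(inb: INBVector, incident_population: float = 1.0) -> VOIEstimate:
    """EVPI from per-draw INB, with a delta-method standard error.

    The statistic is ``mean(max(0, INB)) - max(0, mean(INB))``; depending on
    the sign of the mean it equals the mean of either ``max(0, INB)`` or
    ``max(0, -INB)``, whose sampling SE is ``sd/sqrt(n)``.
    """
    x = inb.values
    if x.size < 2:
        raise PSADomainError("EVPI needs at least 2 draws")
    gains = np.maximum(0.0, x)
    mean_inb = float(np.mean(x))
    raw = float(np.mean(gains)) - max(0.0, mean_inb)
    loss = gains - x if mean_inb > 0 else gains
    se = float(np.std(loss, ddof=1) / np.sqrt(x.size))
    return VOIEstimate(
        per_person=max(0.0, raw),
        population_scaled=max(0.0, raw) * incident_population,
        standard_error=se,
        subset=(),
        n_draws=x.size,
        metadata={"raw": raw, "mean_inb": mean_inb,
                  "incident_population": incident_population},
    )


# ---------------------------------------------------------------------------
# spline regression engine
# ---------------------------------------------------------------------------

def _basis_dim(n: int) -> int:
    return int(4 * np.ceil(n ** 0.2))


def _column_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Cubic B-spline basis (quantile knots) for one column, ~df columns.

    Falls back to a low-order polynomial basis when the column has too few
    distinct values to place knots.
    """
    n_unique = np.unique(x).size
    if n_unique < 5 or df < 5:
        degree = min(3, n_unique - 1, max(1, df))
        return np.column_stack([x ** p for p in range(1, degree + 1)])
    n_knots = max(2, min(df - 1, n_unique - 1))
    st = SplineTransformer(n_knots=n_knots, degree=3, knots="quantile",
                           include_bias=False)
    return st.fit_transform(x[:, None])


def _design_matrix(cols: np.ndarray, n: int) -> np.ndarray:
    """Smooth design matrix for the subset draws (without intercept).

    One marginal spline per parameter, plus low-rank tensor-product
    interactions for every pair (coarser as the subset grows, to keep the
    column count well below n).  Joint EVPPI of interacting parameters is
    systematically underestimated by a purely additive basis, so the
    pairwise smooths are not optional.
    """
    d = cols.shape[1]
    if d == 1:
        return _column_basis(cols[:, 0], _basis_dim(n))
    per_dim = min(_basis_dim(n), 10)
    blocks = [_column_basis(cols[:, j], per_dim) for j in range(d)]
    pair_df = 6 if d <= 3 else (4 if d <= 6 else 3)
    small = [_column_basis(cols[:, j], pair_df) for j in range(d)]
    for i in range(d):
        for j in range(i + 1, d):
            tensor = (small[i][:, :, None] * small[j][:, None, :]).reshape(n, -1)
            blocks.append(tensor)
    return np.column_stack(blocks)


def _fit_values(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return design @ beta


def _evppi_stat(ghat: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.maximum(0.0, ghat)) - max(0.0, float(np.mean(y))))


def _bootstrap_se(design: np.ndarray, y: np.ndarray, n_boot: int,
                  seed: int | None) -> float:
    """Nonparametric bootstrap over draws, refitting the smooth each time."""
    rng = np.random.default_rng(seed)
    n, p = design.shape
    ridge = 1e-10 * n * np.eye(p + 1)
    D = np.column_stack([np.ones(n), design])
    stats_ = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Db, yb = D[idx], y[idx]
        beta = np.linalg.solve(Db.T @ Db + ridge, Db.T @ yb)
        stats_[b] = _evppi_stat(Db @ beta, yb)
    return float(np.std(stats_, ddof=1))


def evppi(psa: PSAResult, subset: Sequence[str], *, n_boot: int = 200,
          seed: int | None = None, max_subset: int = MAX_SUBSET,
          allow_large: bool = False, inb: INBVector | None = None) -> VOIEstimate:
    """Regression-based EVPPI for a parameter subset.

    Negative raw estimates (pure estimation noise) are clipped to zero in
    ``per_person``; the raw value is kept in ``metadata['raw']``.  Constant
    (deterministic) columns in the subset are dropped with a warning; a
    subset that is entirely constant has EVPPI exactly 0.
    """
    subset = tuple(subset)
    if len(subset) == 0:
        raise PSADomainError("subset must contain at least one parameter")
    if len(set(subset)) != len(subset):
        raise PSADomainError(f"duplicate names in subset: {subset}")
    if psa.n_draws < 100:
        raise PSADomainError(
            f"EVPPI regression needs >= 100 draws, got {psa.n_draws}")
    if len(subset) > max_subset and not allow_large:
        raise PSADomainError(
            f"subset of size {len(subset)} exceeds the cap of {max_subset}; "
            "nonparametric regression in high dimensions is unreliable — "
            "pass allow_large=True to override")

    cols = psa.columns(subset)  # raises KeyError for unknown names
    y = (inb if inb is not None else compute_inb(psa)).values
    n = psa.n_draws
    pop = psa.incident_population

    keep = cols.std(axis=0) > 0
    dropped = [name for name, k in zip(subset, keep) if not k]
    if dropped:
        warnings.warn(
            f"constant (deterministic) parameters {dropped} carry no "
            "uncertainty and contribute 0 to EVPPI", stacklevel=2)
    if not keep.any():
        return VOIEstimate(0.0, 0.0, 0.0, subset, n,
                           metadata={"raw": 0.0, "dropped_constant": dropped,
                                     "incident_population": pop})

    design = _design_matrix(cols[:, keep], n)
    ghat = _fit_values(np.column_stack([np.ones(n), design]), y)
    raw = _evppi_stat(ghat, y)
    se = _bootstrap_se(design, y, n_boot, seed) if n_boot > 0 else float("nan")
    logger.debug("EVPPI(%s): raw=%.6g se=%.3g basis=%d", subset, raw, se,
                 design.shape[1])
    return VOIEstimate(
        per_person=max(0.0, raw),
        population_scaled=max(0.0, raw) * pop,
        standard_error=se,
        subset=subset,
        n_draws=n,
        metadata={"raw": raw, "dropped_constant": dropped,
                  "basis_columns": int(design.shape[1]),
                  "n_boot": n_boot, "incident_population": pop},
    )
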