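"""Four-state oncology Markov cohort simulator and PSA sampler.

The bundled model compares current practice (treatment A) against a
higher-intensity, new-modality treatment (B) in a cohort moving through
``well -> local recurrence -> metastasis -> dead``.  All survival functions
are exponential; per-year rates are converted to per-cycle probabilities by
competing-risks apportionment.  Conventions (documented, configurable where
sensible):

* annual cycles, no half-cycle correction, cycle 0 undiscounted;
* both relative treatment effects multiply the local-recurrence rate from
  cycle 0 until the configured effect duration, then expire together;
* background mortality is an additive age-indexed (Gompertz-like) rate from
  every alive state;
* utilities decline linearly with age; the metastatic decrement applies on
  top of the recurrence utility;
* recurrence costs distinguish the first year in the state from later years
  via an internal tunnel compartment (reported occupancy is 4-state);
* intervention costs and short-term adverse-event (AE) costs/disutilities
  are one-off at cycle 0.

Short-term AE class probabilities (classes 0, 2a, 2b, 3) are the only
correlated inputs: each arm's class vector is Dirichlet, and the two arms
are coupled through shared underlying uniform draws per class.  Class 0
("no event") is the residual category and is not a recorded PSA column —
recording the full simplex would make the design matrix of any downstream
regression exactly rank-deficient.

The module also provides :func:`linear_gaussian_toy`, a linear-Gaussian
decision model whose EVPI/EVPPI have closed forms (normal partial
expectation); it is the analytic oracle used to validate the VOI
estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .psa_core import PSADomainError, PSAResult, StrategyOutcomes

__all__ = [
    "MarkovConfig",
    "ParameterSpec",
    "CohortTrace",
    "rates_to_cycle_probabilities",
    "run_cohort",
    "sample_psa",
    "linear_gaussian_toy",
    "toy_evpi",
    "toy_evppi",
    "default_config",
    "default_parameter_specs",
    "config_to_yaml",
    "config_from_yaml",
    "AE_CLASSES",
    "AE_GROUP",
]

STATES = ("well", "local_recurrence", "metastasis", "dead")
AE_CLASSES = ("class0", "class2a", "class2b", "class3")
#: correlation-group tag shared by every AE-probability parameter
AE_GROUP = "short_term_ae"

# internal compartments: recurrence is split into a first-year tunnel
_WELL, _LR1, _LR2, _MET, _DEAD = range(5)


@dataclass(frozen=True)
class ParameterSpec:
    """Sampling specification for one model input.

    ``distribution`` is a mapping with a ``family`` key: ``beta`` (alpha,
    beta), ``gamma`` (shape, scale), ``lognormal`` (mu, sigma of log), or
    ``ae_dirichlet`` (arm, ae_class; alphas live in the MarkovConfig).
    Deterministic specs carry no distribution.
    """

    name: str
    kind: str = "probabilistic"  # probabilistic | deterministic
    distribution: Mapping | None = None
    correlation_group: str | None = None

    def __post_init__(self):
        if self.kind not in ("probabilistic", "deterministic"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "probabilistic" and not self.distribution:
            raise ValueError(f"probabilistic parameter {self.name!r} needs a distribution")


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy history plus total discounted outcomes for one arm."""

    occupancy: np.ndarray  # (horizon, 4) proportions, start-of-cycle
    discounted_qalys: float
    discounted_costs: float


@dataclass(frozen=True)
class MarkovConfig:
    """Full configuration of the case-study model.

    ``values`` holds every scalar model parameter (probabilistic means and
    deterministic constants) keyed by canonical name; ``ae_alpha`` holds the
    per-arm Dirichlet concentration parameters for AE class probabilities.
    """

    values: dict
    ae_alpha: dict  # {"A": {class: alpha}, "B": {...}}
    start_age: float = 60.0
    horizon: int = 45
    cycle_length: float = 1.0
    discount_rate_qalys: float = 0.035
    discount_rate_costs: float = 0.035
    k: float = 13_000.0
    incident_population: float = 24_799.0
    states: tuple = STATES

    def __post_init__(self):
        if self.horizon < 1:
            raise PSADomainError(f"horizon must be >= 1, got {self.horizon}")
        if self.cycle_length <= 0:
            raise PSADomainError("cycle_length must be > 0")
        v = self.values
        for name in ("baseline_rate_local_recurrence", "baseline_rate_metastatic",
                     "rate_metastatic_after_recurrence", "mortality_rate_metastatic",
                     "bg_mortality_rate_40"):
            if v[name] < 0:
                raise PSADomainError(f"rate {name} must be >= 0, got {v[name]}")
        for name in ("utility_well", "utility_local_recurrence"):
            if not -1.0 <= v[name] <= 1.0:
                raise PSADomainError(f"{name} must lie in [-1, 1], got {v[name]}")
        for arm in ("A", "B"):
            probs = [v[f"prob_ae_{c}_{arm}"] for c in AE_CLASSES[1:]]
            if any(p < 0 or p > 1 for p in probs) or sum(probs) > 1.0 + 1e-12:
                raise PSADomainError(
                    f"AE probabilities for arm {arm} must lie in [0,1] and sum <= 1"
                )

    def ae_probabilities(self, arm: str, values: Mapping | None = None) -> dict:
        """AE class probabilities for an arm; class 0 is the residual."""
        v = values if values is not None else self.values
        probs = {c: v[f"prob_ae_{c}_{arm}"] for c in AE_CLASSES[1:]}
        probs["class0"] = 1.0 - sum(probs.values())
        return probs


def rates_to_cycle_probabilities(rate_matrix: np.ndarray, cycle_length: float) -> np.ndarray:
    """Convert per-year transition rates to a per-cycle stochastic matrix.

    ``rate_matrix[..., i, j]`` is the rate out of state ``i`` into ``j``
    (diagonal ignored).  Competing exponential risks: total exit
    probability ``1 - exp(-sum(r) * dt)`` apportioned across destinations
    proportional to their rates.  Supports leading batch dimensions.
    """
    r = np.asarray(rate_matrix, dtype=float)
    if cycle_length <= 0:
        raise PSADomainError("cycle_length must be > 0")
    if r.shape[-1] != r.shape[-2]:
        raise PSADomainError(f"rate matrix must be square, got shape {r.shape}")
    off = r.copy()
    idx = np.arange(r.shape[-1])
    off[..., idx, idx] = 0.0
    if np.any(off < 0):
        raise PSADomainError("transition rates must be >= 0")
    total = off.sum(axis=-1)  # (..., S)
    p_exit = -np.expm1(-total * cycle_length)
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total[..., None] > 0, off / total[..., None], 0.0)
    p = share * p_exit[..., None]
    p[..., idx, idx] = 1.0 - p.sum(axis=-1)
    return p


def _age_rate(v: Mapping, age):
    """Background mortality rate at a given age (Gompertz-like)."""
    return v["bg_mortality_rate_40"] * np.exp(v["bg_mortality_log_slope"] * (age - 40.0))


def _broadcast_values(config: MarkovConfig, overrides: Mapping | None):
    v = dict(config.values)
    n = 1
    if overrides:
        for name, val in overrides.items():
            if name not in v:
                raise KeyError(f"unknown model parameter {name!r}")
            arr = np.asarray(val, dtype=float)
            if arr.ndim > 0:
                n = max(n, arr.shape[0])
            v[name] = arr
    return v, n


def _simulate_arm(config: MarkovConfig, treatment: str, overrides: Mapping | None = None,
                  record_trace: bool = False):
    """Core cohort engine, vectorized over an optional draw dimension.

    Every entry of ``overrides`` may be a scalar or an (n,) array; outputs
    are (n,) arrays of discounted QALYs and costs (scalars collapse to n=1).
    """
    if treatment not in ("A", "B"):
        raise PSADomainError(f"unknown treatment label {treatment!r}; expected 'A' or 'B'")
    v, n = _broadcast_values(config, overrides)
    dt = config.cycle_length
    horizon = config.horizon

    ones = np.ones(n)
    occ = np.zeros((n, 5))
    occ[:, _WELL] = 1.0

    rr = np.asarray(v["relative_effect_treatment_intensity"]
                    * v["relative_effect_new_modality"]) * ones if treatment == "B" else ones
    duration = np.asarray(v["treatment_effect_duration"]) * ones

    qalys = np.zeros(n)
    costs = np.zeros(n)

    # cycle-0 one-offs: intervention cost, AE costs and disutilities
    ae = config.ae_probabilities(treatment, v)
    costs += np.asarray(v[f"intervention_cost_{treatment}"]) * ones
    for c in AE_CLASSES:
        costs += np.asarray(ae[c]) * np.asarray(v[f"cost_ae_{c}"]) * ones
        qalys -= np.asarray(ae[c]) * np.asarray(v[f"disutility_ae_{c}"]) * ones

    trace = np.zeros((horizon, 4)) if record_trace else None

    r_lr = np.asarray(v["baseline_rate_local_recurrence"]) * ones
    r_met = np.asarray(v["baseline_rate_metastatic"]) * ones
    r_met_lr = np.asarray(v["rate_metastatic_after_recurrence"]) * ones
    r_death_met = np.asarray(v["mortality_rate_metastatic"]) * ones
    du_age = np.asarray(v["utility_change_per_year_age"]) * ones

    for t in range(horizon):
        age = config.start_age + t * dt
        years = t * dt
        df_q = (1.0 + config.discount_rate_qalys) ** (-years)
        df_c = (1.0 + config.discount_rate_costs) ** (-years)

        if record_trace:
            trace[t, 0] = occ[0, _WELL]
            trace[t, 1] = occ[0, _LR1] + occ[0, _LR2]
            trace[t, 2] = occ[0, _MET]
            trace[t, 3] = occ[0, _DEAD]

        # rewards for the cycle, based on start-of-cycle occupancy
        age_adj = du_age * (age - config.start_age)
        u_well = np.asarray(v["utility_well"]) * ones + age_adj
        u_lr = np.asarray(v["utility_local_recurrence"]) * ones + age_adj
        u_met = u_lr - np.asarray(v["utility_decrement_metastatic"]) * ones
        qalys += df_q * dt * (occ[:, _WELL] * u_well
                              + (occ[:, _LR1] + occ[:, _LR2]) * u_lr
                              + occ[:, _MET] * u_met)

        c_well = np.asarray(v["cost_well_yearly"]) * ones
        cycle_cost = dt * (occ[:, _WELL] * c_well
                           + occ[:, _LR1] * np.asarray(v["cost_recurrence_first_year"])
                           + occ[:, _LR2] * np.asarray(v["cost_recurrence_later_years"])
                           + occ[:, _MET] * np.asarray(v["cost_metastatic_yearly"]))
        if t == 0:  # one-off extra cost of the first year in the well state
            cycle_cost = cycle_cost + occ[:, _WELL] * np.asarray(
                v["cost_well_first_year_additional"]) * ones
        costs += df_c * cycle_cost

        # transition rates for this cycle
        bg = _age_rate(v, age) * ones
        effect = np.where(years < duration, rr, 1.0)
        rates = np.zeros((n, 5, 5))
        rates[:, _WELL, _LR1] = r_lr * effect
        rates[:, _WELL, _MET] = r_met
        rates[:, _WELL, _DEAD] = bg
        rates[:, _LR1, _MET] = r_met_lr
        rates[:, _LR1, _DEAD] = bg
        rates[:, _LR2, _MET] = r_met_lr
        rates[:, _LR2, _DEAD] = bg
        rates[:, _MET, _DEAD] = r_death_met + bg
        p = rates_to_cycle_probabilities(rates, dt)
        # tunnel: recurrence survivors of their first year move to the later-year state
        p[:, _LR1, _LR2] = p[:, _LR1, _LR1]
        p[:, _LR1, _LR1] = 0.0
        occ = np.einsum("ns,nsj->nj", occ, p)

    return qalys, costs, trace


def run_cohort(config: MarkovConfig, treatment: str,
               overrides: Mapping | None = None) -> CohortTrace:
    """Run the cohort model for one arm and return its trace and outcomes."""
    if overrides:
        for val in overrides.values():
            if np.ndim(val) > 0:
                raise PSADomainError("run_cohort takes scalar overrides; "
                                     "use sample_psa for batched draws")
    q, c, trace = _simulate_arm(config, treatment, overrides, record_trace=True)
    return CohortTrace(occupancy=trace, discounted_qalys=float(q[0]),
                       discounted_costs=float(c[0]))


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------

def _sample_independent(rng: np.random.Generator, dist: Mapping, n: int) -> np.ndarray:
    family = dist.get("family")
    if family == "beta":
        a, b = float(dist["alpha"]), float(dist["beta"])
        if a <= 0 or b <= 0:
            raise PSADomainError(f"beta hyperparameters must be > 0, got ({a}, {b})")
        return rng.beta(a, b, size=n)
    if family == "gamma":
        shape, scale = float(dist["shape"]), float(dist["scale"])
        if shape <= 0 or scale <= 0:
            raise PSADomainError(f"gamma hyperparameters must be > 0, got ({shape}, {scale})")
        return rng.gamma(shape, scale, size=n)
    if family == "lognormal":
        sigma = float(dist["sigma"])
        if sigma < 0:
            raise PSADomainError(f"lognormal sigma must be >= 0, got {sigma}")
        return rng.lognormal(float(dist["mu"]), sigma, size=n)
    raise PSADomainError(f"unknown distribution family {family!r}")


def _sample_ae_group(rng: np.random.Generator, config: MarkovConfig, n: int) -> dict:
    """Correlated AE-class probabilities for both arms.

    Per arm the class vector is exactly Dirichlet(alpha_arm) (normalized
    independent gammas); the arms share one uniform draw per class, which
    couples them positively while preserving the marginals and the simplex
    constraint.
    """
    u = rng.uniform(size=(n, len(AE_CLASSES)))
    out = {}
    for arm in ("A", "B"):
        alphas = np.array([config.ae_alpha[arm][c] for c in AE_CLASSES])
        if np.any(alphas <= 0):
            raise PSADomainError(f"Dirichlet alphas for arm {arm} must be > 0")
        g = stats.gamma.ppf(u, alphas[None, :])
        p = g / g.sum(axis=1, keepdims=True)
        for j, c in enumerate(AE_CLASSES):
            out[f"prob_ae_{c}_{arm}"] = p[:, j]
    return out


def sample_psa(config: MarkovConfig, specs: Sequence[ParameterSpec],
               n_draws: int, seed: int | None = None) -> PSAResult:
    """Draw a full PSA from the model: one row per joint parameter draw.

    Deterministic parameters stay at their configured values.  Recorded
    columns are the probabilistic parameters in spec order (for AE
    probabilities: every class except the residual class 0).
    """
    if n_draws < 1:
        raise PSADomainError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    prob_specs = [s for s in specs if s.kind == "probabilistic"]

    overrides: dict[str, np.ndarray] = {}
    ae_drawn = False
    for spec in prob_specs:
        if spec.name not in config.values:
            raise KeyError(f"spec {spec.name!r} matches no model parameter")
        if spec.correlation_group == AE_GROUP:
            if not ae_drawn:
                ae = _sample_ae_group(rng, config, n_draws)
                overrides.update({k: val for k, val in ae.items()
                                  if not k.startswith("prob_ae_class0")})
                ae_drawn = True
            continue
        overrides[spec.name] = _sample_independent(rng, spec.distribution, n_draws)

    recorded = [s.name for s in prob_specs]
    draws = np.column_stack([overrides[name] for name in recorded]) if recorded \
        else np.empty((n_draws, 0))

    qa, ca, _ = _simulate_arm(config, "A", overrides)
    qb, cb, _ = _simulate_arm(config, "B", overrides)
    if qa.size == 1 and n_draws > 1:  # fully deterministic model
        qa, ca, qb, cb = (np.repeat(x, n_draws) for x in (qa, ca, qb, cb))
    return PSAResult(
        draws=draws,
        param_names=tuple(recorded),
        outcomes=(StrategyOutcomes("A", qa, ca), StrategyOutcomes("B", qb, cb)),
        k=config.k,
        incident_population=config.incident_population,
        metadata={"seed": seed, "n_draws": n_draws, "model": "markov_case_study"},
    )


# ---------------------------------------------------------------------------
# Linear-Gaussian oracle model
# ---------------------------------------------------------------------------

def linear_gaussian_toy(means: Sequence[float], sds: Sequence[float],
                        n_draws: int, seed: int | None = None) -> PSAResult:
    """Toy decision model with closed-form VOI: ``INB = sum_j theta_j``.

    The theta_j are independent normals, realized as the intervention's
    QALY gain with zero costs, so the analytic EVPI/EVPPI of
    :func:`toy_evpi` / :func:`toy_evppi` apply exactly.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != sds.shape or means.ndim != 1:
        raise PSADomainError("means and sds must be 1-D with equal length")
    if np.any(sds < 0):
        raise PSADomainError("sds must be >= 0")
    rng = np.random.default_rng(seed)
    draws = means[None, :] + sds[None, :] * rng.standard_normal((n_draws, means.size))
    inb = draws.sum(axis=1)
    zero = np.zeros(n_draws)
    names = tuple(f"theta_{j + 1}" for j in range(means.size))
    return PSAResult(
        draws=draws,
        param_names=names,
        outcomes=(StrategyOutcomes("A", zero, zero), StrategyOutcomes("B", inb, zero)),
        k=1.0,
        incident_population=1.0,
        metadata={"seed": seed, "model": "linear_gaussian_toy",
                  "means": means.tolist(), "sds": sds.tolist()},
    )


def _normal_voi(mu: float, sigma: float) -> float:
    # E[max(0, X)] - max(0, E[X]) for X ~ N(mu, sigma^2)
    if sigma == 0:
        return 0.0
    return float(sigma * stats.norm.pdf(mu / sigma) - abs(mu) * stats.norm.cdf(-abs(mu) / sigma))


def toy_evpi(means: Sequence[float], sds: Sequence[float]) -> float:
    """Exact per-person EVPI of the linear-Gaussian toy."""
    mu = float(np.sum(means))
    sigma = float(np.sqrt(np.sum(np.square(sds))))
    return _normal_voi(mu, sigma)


def toy_evppi(means: Sequence[float], sds: Sequence[float],
              subset: Sequence[int]) -> float:
    """Exact per-person EVPPI of the toy for a subset of parameter indices."""
    mu = float(np.sum(means))
    sigma_s = float(np.sqrt(np.sum(np.square(np.asarray(sds, dtype=float)[list(subset)]))))
    return _normal_voi(mu, sigma_s)


# ---------------------------------------------------------------------------
# Bundled default configuration
# ---------------------------------------------------------------------------

def _beta_from_moments(mean: float, sd: float) -> dict:
    nu = mean * (1 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise PSADomainError(f"beta moments infeasible: mean={mean}, sd={sd}")
    return {"family": "beta", "alpha": mean * nu, "beta": (1 - mean) * nu}


def _gamma_from_moments(mean: float, sd: float) -> dict:
    return {"family": "gamma", "shape": (mean / sd) ** 2, "scale": sd**2 / mean}


def _lognormal_from_mean(mean: float, sigma: float) -> dict:
    # mu chosen so that the distribution mean equals `mean`
    return {"family": "lognormal", "mu": float(np.log(mean) - sigma**2 / 2), "sigma": sigma}


_DEFAULT_AE_ALPHA = {
    "A": {"class0": 70.0, "class2a": 18.0, "class2b": 9.0, "class3": 3.0},
    "B": {"class0": 160.0, "class2a": 24.0, "class2b": 12.0, "class3": 4.0},
}

# Stand-in parameter values for the bundled breast-cancer-like case study.
# These are plausible UK oncology magnitudes chosen so that the qualitative
# behaviour holds (B dominates with little decision uncertainty); every
# value is overridable via the YAML config for anyone holding the original
# model's inputs.
_DEFAULT_VALUES = {
    # probabilistic (means)
    "baseline_rate_local_recurrence": 0.005,
    "baseline_rate_metastatic": 0.004,
    "rate_metastatic_after_recurrence": 0.06,
    "mortality_rate_metastatic": 0.35,
    "relative_effect_treatment_intensity": 0.90,
    "relative_effect_new_modality": 0.97,
    "utility_well": 0.85,
    "utility_local_recurrence": 0.72,
    "utility_decrement_metastatic": 0.25,
    "cost_well_yearly": 250.0,
    "cost_well_first_year_additional": 600.0,
    "cost_recurrence_first_year": 6000.0,
    "cost_recurrence_later_years": 1200.0,
    "cost_metastatic_yearly": 18000.0,
    # deterministic
    "treatment_effect_duration": 10.0,
    "utility_change_per_year_age": -0.002,
    "intervention_cost_A": 3500.0,
    "intervention_cost_B": 1900.0,
    "cost_ae_class0": 0.0,
    "cost_ae_class2a": 250.0,
    "cost_ae_class2b": 900.0,
    "cost_ae_class3": 3500.0,
    "disutility_ae_class0": 0.0,
    "disutility_ae_class2a": 0.005,
    "disutility_ae_class2b": 0.012,
    "disutility_ae_class3": 0.04,
    "bg_mortality_rate_40": 0.0015,
    "bg_mortality_log_slope": 0.085,
}

_DEFAULT_SDS = {
    "baseline_rate_local_recurrence": 0.0015,
    "baseline_rate_metastatic": 0.001,
    "rate_metastatic_after_recurrence": 0.015,
    "mortality_rate_metastatic": 0.06,
    "utility_well": 0.02,
    "utility_local_recurrence": 0.04,
    "utility_decrement_metastatic": 0.04,
    "cost_well_yearly": 50.0,
    "cost_well_first_year_additional": 150.0,
    "cost_recurrence_first_year": 1200.0,
    "cost_recurrence_later_years": 300.0,
    "cost_metastatic_yearly": 3000.0,
}

_LOG_SIGMAS = {
    "relative_effect_treatment_intensity": 0.18,
    "relative_effect_new_modality": 0.10,
}


def _ae_mean_values(ae_alpha: Mapping) -> dict:
    out = {}
    for arm in ("A", "B"):
        total = sum(ae_alpha[arm].values())
        for c in AE_CLASSES:
            out[f"prob_ae_{c}_{arm}"] = ae_alpha[arm][c] / total
    return out


def default_config() -> MarkovConfig:
    """Bundled case-study configuration (stand-in values, fully overridable)."""
    values = dict(_DEFAULT_VALUES)
    values.update(_ae_mean_values(_DEFAULT_AE_ALPHA))
    return MarkovConfig(values=values, ae_alpha={a: dict(d) for a, d in _DEFAULT_AE_ALPHA.items()})


def default_parameter_specs(config: MarkovConfig | None = None) -> list[ParameterSpec]:
    """The 20 probabilistic parameter specs of the bundled case study.

    14 independent inputs plus the 6 recorded AE-class probabilities
    (classes 2a/2b/3 per arm; class 0 is the simplex residual).
    """
    if config is None:
        config = default_config()
    v = config.values
    specs = []
    for name in ("baseline_rate_local_recurrence", "baseline_rate_metastatic",
                 "rate_metastatic_after_recurrence", "mortality_rate_metastatic",
                 "cost_well_yearly", "cost_well_first_year_additional",
                 "cost_recurrence_first_year", "cost_recurrence_later_years",
                 "cost_metastatic_yearly"):
        specs.append(ParameterSpec(name, distribution=_gamma_from_moments(v[name], _DEFAULT_SDS[name])))
    for name in ("utility_well", "utility_local_recurrence", "utility_decrement_metastatic"):
        specs.append(ParameterSpec(name, distribution=_beta_from_moments(v[name], _DEFAULT_SDS[name])))
    for name, sigma in _LOG_SIGMAS.items():
        specs.append(ParameterSpec(name, distribution=_lognormal_from_mean(v[name], sigma)))
    for arm in ("A", "B"):
        for c in AE_CLASSES[1:]:
            specs.append(ParameterSpec(
                f"prob_ae_{c}_{arm}",
                distribution={"family": "ae_dirichlet", "arm": arm, "ae_class": c},
                correlation_group=AE_GROUP,
            ))
    return specs


def expected_value_inb(config: MarkovConfig, overrides: Mapping | None = None) -> float:
    """Deterministic INB (QALYs) with every input at its expected value.

    ``overrides`` perturbs named inputs; this is the model runner used by
    one-at-a-time OWSA cross-checks.
    """
    qa, ca, _ = _simulate_arm(config, "A", overrides)
    qb, cb, _ = _simulate_arm(config, "B", overrides)
    return float((qb[0] - qa[0]) - (cb[0] - ca[0]) / config.k)


def config_to_yaml(config: MarkovConfig, path: str | Path) -> None:
    doc = {
        "start_age": config.start_age,
        "horizon": config.horizon,
        "cycle_length": config.cycle_length,
        "discount_rate_qalys": config.discount_rate_qalys,
        "discount_rate_costs": config.discount_rate_costs,
        "k": config.k,
        "incident_population": config.incident_population,
        "values": {k: float(val) for k, val in config.values.items()},
        "ae_alpha": {a: {c: float(x) for c, x in d.items()} for a, d in config.ae_alpha.items()},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def config_from_yaml(path: str | Path) -> MarkovConfig:
    doc = yaml.safe_load(Path(path).read_text())
    base = default_config()
    values = dict(base.values)
    values.update(doc.get("values", {}))
    ae_alpha = {a: dict(d) for a, d in base.ae_alpha.items()}
    for arm, d in doc.get("ae_alpha", {}).items():
        ae_alpha[arm].update(d)
    values.update(_ae_mean_values(ae_alpha))
    kwargs = {key: doc[key] for key in
              ("start_age", "horizon", "cycle_length", "discount_rate_qalys",
               "discount_rate_costs", "k", "incident_population") if key in doc}
    return MarkovConfig(values=values, ae_alpha=ae_alpha, **kwargs)
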