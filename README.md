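# psarank

Parameter prioritization for health-economic decision models, driven
entirely by standard probabilistic sensitivity analysis (PSA) output.
Given per-draw parameter values and per-strategy discounted costs and
QALYs for two strategies, `psarank` answers two distinct questions:

* **Which parameters should be updated first when new evidence arrives?**
  Greedy forward selection on joint EVPPI (expected value of partial
  perfect information): the next-ranked parameter is the one that, joined
  with the already-ranked set, has the largest joint EVPPI. The **update
  metric** is the ranked set's cumulative EVPPI as a share of EVPI.
* **Which parameters matter most when adapting a model to subgroup
  (distributional) analysis?** One-way sensitivity importance via a
  percent-rescaled OLS metamodel: each input is rescaled to percent
  differences from its mean and INB is regressed on all of them; the
  coefficients are 1% semielasticities. The **adaptation metric** is the
  cumulative share of normalized absolute semielasticities covered by the
  adapted set.

Both analyses operate on incremental net benefit in health units,
`INB = dQALYs - dCosts / k`, with `k` the cost-effectiveness threshold.

The package bundles a 4-state oncology Markov cohort simulator (well /
local recurrence / metastasis / dead; exponential transitions; 20
probabilistic parameters including correlated short-term adverse-event
probabilities; k = £13,000/QALY; 24,799 incident patients/year) that
emulates the structure of a published breast-cancer case study, and a
linear-Gaussian toy model whose EVPI/EVPPI have closed forms, used as the
analytic oracle for the estimators.

## Command line

```sh
# simulate a PSA from the bundled case-study model (CSV schema below)
voi simulate --n-draws 10000 --seed 1 --out psa.csv

# value of information
voi evpi  --psa psa.csv --k 13000 --population 24799
voi evppi --psa psa.csv --k 13000 \
    --params "relative_effect_treatment_intensity,relative_effect_new_modality"

# update-priority ranking (greedy conditional EVPPI + update metric)
voi update-rank --psa psa.csv --k 13000 --population 24799 \
    --tol auto --out table1.csv --report table1.md

# adaptation-priority ranking (1% semielasticities + adaptation metric)
voi adapt-rank --psa psa.csv --k 13000 --out table2.csv --report table2.md
```

`voi simulate --config model.yaml` accepts a YAML model configuration
(see `psarank.markov_case_study.config_to_yaml` for the full schema);
every parameter of the bundled model can be overridden, so anyone holding
the original case study's inputs can reproduce it exactly.

**PSA CSV schema**: header `draw`, one column per parameter, then
`cost_A,qaly_A,cost_B,qaly_B` (A = comparator, B = intervention), full
float precision, no missing values.

## Python API

```python
import psarank as pr
from psarank import markov_case_study as mcs

config = mcs.default_config()
psa = mcs.sample_psa(config, mcs.default_parameter_specs(config),
                     n_draws=10_000, seed=1)
inb = pr.compute_inb(psa)
pr.probability_cost_effective(inb)
pr.evpi(inb, incident_population=psa.incident_population)
pr.conditional_evppi_ranking(psa, tol="auto")
pr.fit_semielasticity_metamodel(psa)
```

## Conventions and caveats

* Annual cycles, no half-cycle correction, cycle 0 undiscounted; both
  relative treatment effects multiply the local-recurrence rate until the
  configured effect duration; background mortality is an additive
  age-indexed rate; intervention and adverse-event costs/disutilities are
  one-off at cycle 0.
* Regression EVPPI uses a spline basis (tensor-product interactions per
  pair of parameters, additive marginals) fitted by least squares; the
  estimator carries a known upward bias, so update metrics can exceed
  100% — such values are flagged, never truncated. Subsets larger than 5
  parameters require an explicit override.
* The bundled case-study parameter values are documented stand-ins (the
  original model's appendix inputs are not redistributable); they
  reproduce the qualitative decision regime, and all values are
  config-overridable.
* Exactly two strategies are supported; exactly-zero INB draws count as
  not cost-effective (a zero-measure tie rule under continuous PSA).
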